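"""One-at-a-time sensitivity of the holding angle and correlation prediction.

The dimensionless sensitivity of the holding angle to a parameter ``p`` is
``S_p = (Δθ/θ_ref)/(Δp/p_ref)``, estimated by central differences from two
solves at ``p_ref (1 ± step)``.  Geometric parameters rebuild the section
(and its holding-angle landmarks — when ``H_side`` moves the measurement
line, the line moves with it); swelling factors only change the load
vector.  Predicted correlations between θ and co-varying geometric
parameters follow from first-order (delta-method) propagation through the
sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fem import solve_reference_state
from .geometry import build_reference_geometry
from .params import GeometryParams, MaterialParams

GEOMETRY_PARAMETERS = ("D", "H", "R", "H_pod", "H_side", "W_side",
                       "W_vasc", "D_cavity", "d_vasc")
SWELLING_PARAMETERS = ("s_cort", "s_pod", "s_side", "s_vasc")
ALL_PARAMETERS = GEOMETRY_PARAMETERS + SWELLING_PARAMETERS


@dataclass
class SensitivityResult:
    """Per-parameter dimensionless sensitivities and the sweeps behind them."""

    theta_ref: float
    sensitivity: dict[str, float]
    sweeps: dict[str, pd.DataFrame] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"parameter": list(self.sensitivity),
             "sensitivity": list(self.sensitivity.values())}
        )


def _theta(geometry: GeometryParams, materials: MaterialParams,
           target_edge: float) -> float:
    return solve_reference_state(geometry, materials,
                                 target_edge=target_edge).theta


def oat_sensitivity(geometry: GeometryParams | None = None,
                    materials: MaterialParams | None = None,
                    parameters: tuple[str, ...] = ALL_PARAMETERS,
                    rel_step: float = 0.05,
                    target_edge: float = 3.0,
                    sweep: tuple[float, ...] = (),
                    theta_fn=None) -> SensitivityResult:
    """Central-difference OAT sensitivities of θ at the reference point.

    Parameters
    ----------
    parameters : tuple of str
        Names among the nine geometric lengths and the four swelling
        factors.
    rel_step : float
        Relative perturbation used for the central difference, in (0, 0.2].
    sweep : tuple of float
        Extra relative offsets at which θ is also evaluated and recorded
        (for sweep plots); the reference point is always included.
    theta_fn : callable, optional
        ``theta_fn(geometry, materials) -> float`` override, used to drive
        the machinery with a surrogate model in tests.
    """
    if not 0 < rel_step <= 0.2:
        raise ValueError("rel_step must lie in (0, 0.2]")
    geometry = geometry or GeometryParams()
    materials = materials or MaterialParams()
    fn = theta_fn or (lambda g, m: _theta(g, m, target_edge))
    theta_ref = fn(geometry, materials)
    if theta_ref == 0:
        raise ValueError("theta at the reference point is zero; sensitivity undefined")

    result = SensitivityResult(theta_ref=theta_ref, sensitivity={})
    for name in parameters:
        try:
            points = sorted(set((-rel_step, 0.0, rel_step) + tuple(sweep)))
            thetas = {}
            for rel in points:
                if rel == 0.0:
                    thetas[rel] = theta_ref
                    continue
                g, m = _perturbed(geometry, materials, name, rel)
                thetas[rel] = fn(g, m)
            num = (thetas[rel_step] - thetas[-rel_step]) / theta_ref
            result.sensitivity[name] = num / (2 * rel_step)
            result.sweeps[name] = pd.DataFrame(
                {"rel_change": list(thetas), "theta": list(thetas.values())})
        except Exception as exc:  # per-parameter failure; continue with others
            result.failures[name] = f"{type(exc).__name__}: {exc}"
    return result


def _perturbed(geometry: GeometryParams, materials: MaterialParams,
               name: str, rel: float):
    if name in GEOMETRY_PARAMETERS:
        value = getattr(geometry, name) * (1 + rel)
        return geometry.replace(**{name: value}), materials
    if name in SWELLING_PARAMETERS:
        value = getattr(materials, name) * (1 + rel)
        return geometry, materials.replace(**{name: value})
    raise ValueError(f"unknown parameter {name!r}")


@dataclass
class ParameterCovariation:
    """Coefficients of variation and correlation matrix of parameters."""

    names: tuple[str, ...]
    cv: dict[str, float]
    corr: np.ndarray

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.names)
        if self.corr.shape != (n, n):
            raise ValueError("correlation matrix shape does not match names")
        if not np.allclose(self.corr, self.corr.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.corr), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(self.corr).min() < -1e-10:
            raise ValueError("correlation matrix must be positive semi-definite")
        for nm in self.names:
            if self.cv.get(nm, 0) <= 0:
                raise ValueError(f"coefficient of variation for {nm} must be > 0")

    @classmethod
    def from_csv(cls, corr_path, cv_path) -> "ParameterCovariation":
        corr = pd.read_csv(corr_path, index_col=0)
        cv = pd.read_csv(cv_path)
        names = tuple(corr.index)
        return cls(names=names, cv=dict(zip(cv.iloc[:, 0], cv.iloc[:, 1])),
                   corr=corr.to_numpy())


def predict_correlations(result: SensitivityResult,
                         cov: ParameterCovariation,
                         geometry: GeometryParams | None = None) -> pd.DataFrame:
    """First-order predicted correlations between θ and each parameter.

    With gradients ``g_j = S_j θ_ref / p_j`` and ``σ_j = CV_j p_j``:
    ``cov(θ, p_i) = Σ_j g_j σ_j σ_i ρ_ij`` and
    ``var(θ) = Σ_jk g_j g_k σ_j σ_k ρ_jk``, hence
    ``corr(θ, p_i) = cov(θ, p_i) / (sqrt(var θ) σ_i)``; all predictions lie
    in [−1, 1].
    """
    geometry = geometry or GeometryParams()
    missing = [n for n in cov.names if n not in result.sensitivity]
    if missing:
        raise ValueError(f"no sensitivity available for parameters {missing}")
    p = np.array([getattr(geometry, n) for n in cov.names])
    S = np.array([result.sensitivity[n] for n in cov.names])
    sig = np.array([cov.cv[n] for n in cov.names]) * p
    g = S * result.theta_ref / p
    a = g * sig  # contribution vector; var(theta) = a^T rho a
    var_theta = float(a @ cov.corr @ a)
    if var_theta <= 0:
        raise ValueError("propagated var(theta) is zero; correlations undefined")
    cov_tp = cov.corr @ a * sig  # elementwise: sigma_i * sum_j rho_ij a_j
    corr = cov_tp / (np.sqrt(var_theta) * sig)
    return pd.DataFrame({"parameter": cov.names, "sensitivity": S,
                         "predicted_correlation": corr})
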