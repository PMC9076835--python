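"""Calibration of the four intrinsic swelling factors.

The swelling factors cannot be measured directly; they are fitted by
minimizing the mismatch between the model's coupled regional area changes
and target (measured) regional expansions, expressed in the wet/dry
convention.  The stiffness matrix does not depend on the swelling factors,
so its factorization is reused across objective evaluations, making each
evaluation a load-vector assembly plus a triangular solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fem import SwellingProblem, regional_area_change
from .geometry import build_reference_geometry
from .mesh import mesh_domain
from .params import REGIONS, GeometryParams, MaterialParams


@dataclass(frozen=True)
class ExpansionTargets:
    """Per-region target area change, wet/dry ratio (> 1 means expansion)."""

    ratio: dict[str, float]
    sd: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for r in REGIONS:
            if r not in self.ratio:
                raise ValueError(f"missing target for region {r}")
            if not self.ratio[r] > 0:
                raise ValueError(f"target ratio for {r} must be positive")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpansionTargets":
        df = pd.read_csv(path)
        ratio = dict(zip(df["region"], df["ratio"]))
        sd = dict(zip(df["region"], df["sd"])) if "sd" in df else None
        return cls(ratio=ratio, sd=sd)

    def to_csv(self, path: str | Path) -> None:
        rows = {"region": list(self.ratio), "ratio": list(self.ratio.values())}
        if self.sd:
            rows["sd"] = [self.sd.get(r, np.nan) for r in self.ratio]
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class SwellingFit:
    """Result of the swelling-factor calibration."""

    swelling: dict[str, float]
    objective: float
    initial_objective: float
    n_evaluations: int
    converged: bool
    at_bounds: list[str]
    restarts: list[float] = field(default_factory=list)

    @property
    def materials(self) -> MaterialParams:
        return MaterialParams().with_swelling(self.swelling)


class FitNonConvergenceError(RuntimeError):
    pass


def fit_swelling_factors(geometry: GeometryParams | None = None,
                         materials: MaterialParams | None = None,
                         targets: ExpansionTargets | None = None,
                         initial_s: dict[str, float] | None = None,
                         bounds: tuple[float, float] = (0.01, 0.95),
                         target_edge: float = 6.0,
                         n_restarts: int = 3,
                         jitter: float = 0.05,
                         seed: int = 0,
                         max_iter: int = 400) -> SwellingFit:
    """Fit (s_cort, s_pod, s_side, s_vasc) to target regional expansions.

    The loss is the sum over regions of squared differences between the
    model's wet/dry area ratio and the target ratio, inverse-variance
    weighted when target standard deviations are supplied.  A
    derivative-free simplex search is restarted from ``n_restarts``
    jittered initial points (seeded); the best optimum is returned.
    """
    geometry = geometry or GeometryParams()
    materials = materials or MaterialParams()
    if targets is None:
        raise ValueError("targets are required")
    lo, hi = bounds
    if not 0 < lo < hi < 1:
        raise ValueError("bounds must satisfy 0 < lo < hi < 1")

    domain = build_reference_geometry(geometry)
    mesh = mesh_domain(domain, target_edge=target_edge, half_model=True)
    problem = SwellingProblem(mesh, materials, geometry.d_vasc, domain=domain)
    problem._factorize()  # single factorization reused by every evaluation

    t = np.array([targets.ratio[r] for r in REGIONS])
    if targets.sd:
        w = np.array([1.0 / max(targets.sd[r], 1e-6) ** 2 for r in REGIONS])
    else:
        w = np.ones(4)

    n_eval = 0

    def objective(s_vec: np.ndarray) -> float:
        nonlocal n_eval
        n_eval += 1
        s = dict(zip(REGIONS, np.clip(s_vec, lo, hi)))
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            field_ = problem.solve(s)
        change = regional_area_change(mesh, field_)
        model = np.array([change[r]["wet_over_dry"] for r in REGIONS])
        return float(np.sum(w * (model - t) ** 2))

    if initial_s is None:
        initial_s = {r: 0.5 for r in REGIONS}
    x0 = np.array([initial_s[r] for r in REGIONS])
    f0 = objective(x0)

    rng = np.random.default_rng(seed)
    starts = [x0] + [np.clip(x0 + rng.normal(0, jitter, 4), lo + 0.01, hi - 0.01)
                     for _ in range(max(0, n_restarts - 1))]
    best = None
    restart_objs = []
    for start in starts:
        res = minimize(objective, start, method="Nelder-Mead",
                       bounds=[(lo, hi)] * 4,
                       options={"maxiter": max_iter, "xatol": 1e-4,
                                "fatol": 1e-10})
        restart_objs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitNonConvergenceError(f"no restart converged; trace {restart_objs}")

    s_opt = dict(zip(REGIONS, np.clip(best.x, lo, hi)))
    at_bounds = [r for r, v in s_opt.items()
                 if v <= lo + 1e-3 or v >= hi - 1e-3]
    return SwellingFit(swelling=s_opt, objective=float(best.fun),
                       initial_objective=f0, n_evaluations=n_eval,
                       converged=bool(best.success or best.fun < f0),
                       at_bounds=at_bounds, restarts=restart_objs)


def forward_targets(geometry: GeometryParams | None = None,
                    materials: MaterialParams | None = None,
                    target_edge: float = 6.0,
                    sd: dict[str, float] | None = None) -> ExpansionTargets:
    """Generate expansion targets from the forward model (for recovery tests)."""
    geometry = geometry or GeometryParams()
    materials = materials or MaterialParams()
    domain = build_reference_geometry(geometry)
    mesh = mesh_domain(domain, target_edge=target_edge, half_model=True)
    problem = SwellingProblem(mesh, materials, geometry.d_vasc, domain=domain)
    change = regional_area_change(mesh, problem.solve())
    return ExpansionTargets(
        ratio={r: change[r]["wet_over_dry"] for r in REGIONS}, sd=sd)
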