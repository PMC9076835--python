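"""Synthetic inputs for every pipeline stage.

Three generators emulate the data the analysis consumes, each a pure
function of its spec (including the seed):

* paired dry/wet landmark sets produced by a known smooth deformation
  field: regions are vertical bands, the local area factor profile f(x)
  blends the per-region targets over a finite length, and the map
  ``(x, y) -> (G(x), c y)`` with ``G'(x) = f(x)/c`` realises that factor
  exactly everywhere (positive Jacobian by construction), plus isotropic
  Gaussian annotation noise;
* seven-segment AFM force curves with a Sneddon contact branch, linear
  baseline tilt, an adhesion dip on the final retraction and relative
  Gaussian noise;
* correlated samples of the nine geometric lengths (multivariate normal
  around the reference values, truncated to geometric validity by
  resampling, which preserves correlations better than clipping).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, box

from .afm import SEGMENT_LABELS, ForceCurve, Segment, sneddon_force
from .params import GeometryParams, MaterialParams, reference_config
from .strainmap import LandmarkSet

__all__ = [
    "reference_config", "DeformationSpec", "generate_landmarks",
    "CurveSpec", "generate_force_curve", "generate_geometry_sample",
    "example_covariation", "default_landmark_layout",
]


# ---------------------------------------------------------------------------
# Landmark sets


@dataclass(frozen=True)
class DeformationSpec:
    """Ground-truth regional area factors and annotation noise."""

    area_factors: dict[str, float] = field(
        default_factory=lambda: {"cortex": 1.8, "vasculature": 1.3})
    blend_length: float = 5.0    # μm
    noise_sd: float = 0.0        # μm
    seed: int = 0
    n_landmarks: int = 500

    def __post_init__(self) -> None:
        for k, v in self.area_factors.items():
            if not v > 0:
                raise ValueError(f"area factor for {k} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def default_landmark_layout() -> tuple[Polygon, dict[str, tuple[float, float]]]:
    """A simple two-region sample: cortex slab with a vascular band inside.

    Regions are vertical bands given as x-intervals on the dry image.
    """
    outline = box(0.0, 0.0, 300.0, 200.0)
    regions = {"vasculature": (90.0, 210.0)}
    return outline, regions


def _factor_profile(x: np.ndarray, outline: Polygon,
                    bands: dict[str, tuple[float, float]],
                    factors: dict[str, float], ell: float) -> np.ndarray:
    """Smooth per-x area-factor profile blending the band targets."""
    minx, _, maxx, _ = outline.bounds
    intervals = dict(bands)
    weights = []
    names = []
    for name, (x0, x1) in intervals.items():
        d = np.maximum.reduce([x0 - x, x - x1, np.zeros_like(x)])
        weights.append(np.exp(-0.5 * (d / ell) ** 2))
        names.append(name)
    # cortex = complement of the named bands within the outline
    d_c = np.zeros_like(x)
    for x0, x1 in intervals.values():
        inside = (x >= x0) & (x <= x1)
        dist = np.minimum(np.abs(x - x0), np.abs(x - x1))
        d_c = np.where(inside, np.maximum(d_c, dist), d_c)
    weights.append(np.exp(-0.5 * (d_c / ell) ** 2))
    names.append("cortex")
    w = np.vstack(weights)
    w = w / w.sum(axis=0, keepdims=True)
    f = np.array([factors.get(n, 1.0) for n in names])
    return f @ w


def generate_landmarks(spec: DeformationSpec,
                       layout: tuple[Polygon, dict[str, tuple[float, float]]] | None = None
                       ) -> tuple[LandmarkSet, dict[str, float]]:
    """Scatter dry landmarks and deform them by the regional field.

    The wet configuration is ``(G(x), c y)`` with ``G'(x) = f(x)/c`` and
    ``c`` the square root of the geometric-mean factor, so the local area
    factor equals the blended profile ``f(x)`` exactly at every point and
    the Jacobian is positive everywhere.  Returns the landmark set (with
    outline and region polygons attached, ready for the strain-mapping
    pipeline) and the ground-truth per-region area factors.  With zero
    noise and factors of 1 the wet coordinates equal the dry ones exactly.
    """
    outline, bands = layout if layout is not None else default_landmark_layout()
    rng = np.random.default_rng(spec.seed)

    # jittered grid of dry landmarks inside the outline
    minx, miny, maxx, maxy = outline.bounds
    n_target = spec.n_landmarks
    aspect = (maxx - minx) / (maxy - miny)
    ny = max(3, int(round(math.sqrt(n_target / aspect))))
    nx = max(3, int(round(n_target / ny)))
    gx = np.linspace(minx, maxx, nx + 2)[1:-1]
    gy = np.linspace(miny, maxy, ny + 2)[1:-1]
    pts = np.array([(x, y) for x in gx for y in gy])
    jitter_scale = 0.25 * min((maxx - minx) / nx, (maxy - miny) / ny)
    pts = pts + rng.uniform(-jitter_scale, jitter_scale, pts.shape)
    inside = shapely.contains_xy(outline, pts[:, 0], pts[:, 1])
    dry = pts[inside]

    factors = {name: spec.area_factors.get(name, 1.0) for name in
               list(bands) + ["cortex"]}
    c = math.sqrt(float(np.exp(np.mean(np.log(list(factors.values()))))))
    # integrate G'(x) = f(x)/c on a fine grid
    grid = np.linspace(minx, maxx, 4001)
    f_grid = _factor_profile(grid, outline, bands, factors, spec.blend_length)
    G = np.concatenate([[minx], minx + np.cumsum(
        (f_grid[1:] + f_grid[:-1]) / 2 * np.diff(grid)) / c])
    wet = np.column_stack([np.interp(dry[:, 0], grid, G), c * dry[:, 1]])
    wet = wet + rng.normal(0.0, spec.noise_sd, wet.shape)

    ids = np.arange(len(dry))
    ref = int(np.argmin(np.sum((dry - np.array(outline.centroid.coords[0])) ** 2,
                               axis=1)))
    region_polys = {name: box(x0, miny, x1, maxy)
                    for name, (x0, x1) in bands.items()}
    lm = LandmarkSet(ids=ids, dry=dry, wet=wet, reference_id=ids[ref],
                     outline_dry=outline, regions=region_polys)
    return lm, factors


# ---------------------------------------------------------------------------
# AFM force curves


@dataclass(frozen=True)
class CurveSpec:
    """Ground truth for one synthetic seven-segment force curve."""

    E: float = 5e9                 # Pa
    contact_position: float = 1.0e-6   # m, piezo height of first contact
    spring_constant: float = 40.0  # N/m
    trigger_force: float = 3e-6    # N
    baseline_offset: float = 0.0   # N
    baseline_slope: float = 0.0    # N/m
    adhesion: float = 50e-9        # N
    noise_sd: float = 0.0          # relative, multiplies the trigger force
    seed: int = 0
    z_length: float = 2.0e-6       # m of piezo travel
    n_per_segment: int = 2000      # 2 μm ramps recorded at 2000 pixels

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError("E must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _contact_force(h: np.ndarray, spec: CurveSpec) -> np.ndarray:
    """Force at piezo height h: Sneddon contact with cantilever compliance.

    In contact the indentation depth and the cantilever deflection share
    the piezo advance: ``delta + F/k = z0 - h``; solving the resulting
    quadratic gives the explicit branch used here.
    """
    z0, k = spec.contact_position, spec.spring_constant
    c = (spec.E / (1 - 0.5 ** 2)) * (2 * math.tan(math.radians(18.0)) / math.pi)
    adv = np.clip(z0 - h, 0.0, None)
    if spec.E == 0:
        return np.zeros_like(adv)
    a = c / k
    delta = (-1 + np.sqrt(1 + 4 * a * adv)) / (2 * a)
    return c * delta ** 2


def generate_force_curve(spec: CurveSpec) -> tuple[ForceCurve, dict[str, float]]:
    """Seven-segment synthetic force curve and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    z0 = spec.contact_position
    h_far = z0 + spec.z_length

    # piezo height at which the trigger force is reached
    if spec.E > 0:
        c = (spec.E / (1 - 0.5 ** 2)) * (2 * math.tan(math.radians(18.0)) / math.pi)
        delta_t = math.sqrt(spec.trigger_force / c)
        h_trig = z0 - delta_t - spec.trigger_force / spec.spring_constant
    else:
        h_trig = z0 - spec.z_length / 4

    n = spec.n_per_segment
    segs: list[Segment] = []

    def make(label: str, h: np.ndarray, dip: bool = False) -> Segment:
        f = _contact_force(h, spec)
        if spec.noise_sd > 0:  # multiplicative measurement noise on the signal
            f = f * (1 + rng.normal(0.0, spec.noise_sd, f.shape))
        if dip and spec.adhesion > 0:  # snap-off dip clear of the contact edge
            width = 0.01 * spec.z_length
            f = f - spec.adhesion * np.exp(-0.5 * ((h - (z0 + 5 * width)) / width) ** 2)
        return Segment(h, f + spec.baseline_offset + spec.baseline_slope * h,
                       label)

    down = np.linspace(h_far, h_trig, n)
    up = down[::-1]
    segs.append(make("extend1", down))
    segs.append(make("retract1", up))
    segs.append(make("extend2", down))
    segs.append(make("retract2", up))
    segs.append(make("extend3", down))
    segs.append(make("pause", np.full(max(n // 10, 5), h_trig)))
    segs.append(make("retract_final", up, dip=True))

    curve = ForceCurve(segs, spec.spring_constant, spec.trigger_force)
    truth = {"E": spec.E, "contact_position": z0, "adhesion": spec.adhesion}
    return curve, truth


# ---------------------------------------------------------------------------
# Correlated geometry samples


def example_covariation(names: tuple[str, ...] = ("D", "H", "R", "H_pod",
                                                  "H_side", "W_side", "W_vasc",
                                                  "D_cavity", "d_vasc"),
                        cv: float = 0.05) -> tuple[dict[str, float], np.ndarray]:
    """A plausible positive-semi-definite covariation example for testing.

    Overall specimen size drives a shared positive correlation (~0.5)
    between the main lengths, stronger (~0.7) between D and H, weak for
    the displacement measurement.
    """
    n = len(names)
    loading = np.full(n, math.sqrt(0.5))
    if "d_vasc" in names:
        loading[names.index("d_vasc")] = 0.3
    corr = np.outer(loading, loading)
    if "D" in names and "H" in names:
        i, j = names.index("D"), names.index("H")
        corr[i, j] = corr[j, i] = 0.7
    np.fill_diagonal(corr, 1.0)
    # guarantee PSD after the manual edits
    w, v = np.linalg.eigh(corr)
    corr = (v * np.clip(w, 1e-9, None)) @ v.T
    d = np.sqrt(np.diag(corr))
    corr = corr / np.outer(d, d)
    return {name: cv for name in names}, corr


def generate_geometry_sample(n: int,
                             cv: dict[str, float],
                             corr: np.ndarray,
                             seed: int = 0,
                             mean: GeometryParams | None = None,
                             max_tries: int = 200) -> pd.DataFrame:
    """Multivariate-normal draws of the geometric lengths, resampled to validity.

    Invalid draws (violating the geometric invariants) are replaced by new
    draws rather than clipped, which preserves the requested correlations
    up to the truncation bias (documented: grows with the CVs).
    """
    mean = mean or GeometryParams()
    names = tuple(cv)
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ValueError("correlation matrix shape does not match cv keys")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if np.linalg.eigvalsh(corr).min() < -1e-8:
        raise ValueError("correlation matrix must be positive semi-definite")
    mu = np.array([getattr(mean, nm) for nm in names])
    sig = np.array([cv[nm] for nm in names]) * mu
    cov = corr * np.outer(sig, sig)
    rng = np.random.default_rng(seed)

    rows = []
    tries = 0
    while len(rows) < n and tries < max_tries:
        tries += 1
        draw = rng.multivariate_normal(mu, cov, size=max(n - len(rows), 1),
                                       method="eigh")
        for vec in draw:
            if len(rows) >= n:
                break
            try:
                GeometryParams(**dict(zip(names, vec)))
            except Exception:
                continue
            rows.append(vec)
    if len(rows) < n:
        raise RuntimeError("could not draw enough valid geometries; CVs too large?")
    return pd.DataFrame(rows, columns=names)
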