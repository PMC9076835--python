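"""AFM force-curve processing and Sneddon conical-indenter fitting.

Force curves are recorded as piezo height (m) versus force (N) in a
seven-segment load cycle (two extend–retract cycles, a third extension, a
constant-force pause, and a final retraction).  The effective Young's
modulus is extracted from the final retraction: the curve is flattened
against a linear fit to its non-contact part, the contact point is located
as the first zero-force crossing coming down from the trigger force, the
abscissa is converted to tip–sample separation using the cantilever
deflection, and the contact branch is fitted with the Sneddon law for a
rigid cone,

    F = E / (1 - nu^2) * (2 tan(alpha) / pi) * delta^2,

with the modulus, the contact point and a force offset free.  Curves whose
adhesion (|minimum force| on the final retraction) reaches 160 nN are
rejected as wax contacts, and per-sample, per-region medians summarize the
retained fits.

Sign conventions: height decreases toward the sample; repulsive contact
force is positive; cantilever deflection is ``force / spring_constant``
and the tip–sample separation is ``height + deflection`` (the cantilever
bends away from the surface, so the tip lags the piezo in contact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize as lm_minimize

TIP_HALF_ANGLE_DEG = 18.0
TIP_POISSON = 0.5
ADHESION_THRESHOLD = 160e-9  # N

SEGMENT_LABELS = ("extend1", "retract1", "extend2", "retract2",
                  "extend3", "pause", "retract_final")


class NoContactError(RuntimeError):
    """The flattened curve never crosses zero force."""


class InsufficientDataError(RuntimeError):
    pass


@dataclass(eq=False)
class Segment:
    height: np.ndarray  # m
    force: np.ndarray   # N
    label: str

    def __post_init__(self) -> None:
        self.height = np.asarray(self.height, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.height.shape != self.force.shape:
            raise ValueError("height and force must have the same length")


@dataclass(eq=False)
class ForceCurve:
    segments: list[Segment]
    spring_constant: float      # N/m
    trigger_force: float        # N
    region: str = ""
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("curve has no segments")
        if not self.segments[-1].label.startswith("retract"):
            raise ValueError("final segment must be a retraction")

    @property
    def last_retraction(self) -> Segment:
        return self.segments[-1]

    def replace_segment(self, index: int, seg: Segment) -> "ForceCurve":
        segs = list(self.segments)
        segs[index] = seg
        return ForceCurve(segs, self.spring_constant, self.trigger_force,
                          self.region, self.sample_id)


@dataclass
class SneddonFit:
    E: float               # Pa
    contact_point: float   # m, on the separation axis
    force_offset: float    # N
    residual_norm: float
    alpha_deg: float = TIP_HALF_ANGLE_DEG
    nu: float = TIP_POISSON
    adhesion: float = float("nan")
    retained: bool = True


def sneddon_force(delta: np.ndarray, E: float,
                  alpha_deg: float = TIP_HALF_ANGLE_DEG,
                  nu: float = TIP_POISSON) -> np.ndarray:
    """Sneddon force law for a rigid cone; zero for non-positive depth."""
    d = np.clip(np.asarray(delta, dtype=float), 0.0, None)
    return E / (1 - nu ** 2) * (2 * math.tan(math.radians(alpha_deg)) / math.pi) * d ** 2


def flatten_baseline(seg: Segment, noncontact_fraction: float = 0.30) -> Segment:
    """Remove a linear baseline fitted on the non-contact part of a segment.

    The non-contact window is the ``noncontact_fraction`` of samples
    farthest from the surface (largest heights).  The fitted line is
    subtracted from the whole segment so the free baseline sits at zero
    force.
    """
    n = len(seg.height)
    k = max(int(round(noncontact_fraction * n)), 2)
    if n < 5 or k < 2:
        raise InsufficientDataError("segment too short to identify a baseline")
    idx = np.argsort(seg.height)[-k:]
    coeff = np.polyfit(seg.height[idx], seg.force[idx], 1)
    return Segment(seg.height, seg.force - np.polyval(coeff, seg.height),
                   seg.label)


def flatten_curve(curve: ForceCurve) -> ForceCurve:
    """Flatten every segment of a curve against its own non-contact window."""
    segs = [flatten_baseline(s) for s in curve.segments]
    return ForceCurve(segs, curve.spring_constant, curve.trigger_force,
                      curve.region, curve.sample_id)


def estimate_poc(seg: Segment) -> float:
    """First zero-force crossing scanning from the maximum-force end.

    On a flattened segment the scan starts at the trigger-force position
    (the sample-side end) and walks toward the free baseline; the crossing
    is linearly interpolated between the bracketing samples.
    """
    order = np.argsort(seg.height)  # sample side (small height) first
    h = seg.height[order]
    f = seg.force[order]
    start = int(np.argmax(f))
    if f[start] <= 0:
        raise NoContactError("maximum force is not positive; no contact found")
    for i in range(start, len(f) - 1):
        if f[i] > 0 >= f[i + 1]:
            t = f[i] / (f[i] - f[i + 1])
            return float(h[i] + t * (h[i + 1] - h[i]))
    raise NoContactError("force never crosses zero on the baseline side")


def tip_sample_distance(seg: Segment, spring_constant: float) -> Segment:
    """Convert the piezo-height axis to tip–sample separation.

    Separation is ``height + force / spring_constant``: in repulsive
    contact the cantilever bends away from the surface so the tip sits
    farther from the sample than the piezo height alone suggests.
    """
    deflection = seg.force / spring_constant
    return Segment(seg.height + deflection, seg.force, seg.label)


def fit_sneddon(seg: Segment,
                alpha_deg: float = TIP_HALF_ANGLE_DEG,
                nu: float = TIP_POISSON,
                contact_guess: float | None = None) -> SneddonFit:
    """Least-squares Sneddon fit of a flattened, separation-domain segment.

    Free parameters: modulus ``E``, contact point ``z0`` and a force
    offset.  Only separations on the indentation side of the contact point
    contribute (depth clipped at zero).  Strongly negative forces — the
    adhesion dip on retraction, unrepresentable by the adhesionless
    Sneddon law — are excluded: samples below −5 robust standard
    deviations of the non-contact scatter do not enter the fit.
    """
    s = np.asarray(seg.height, dtype=float)
    f = np.asarray(seg.force, dtype=float)
    if contact_guess is None:
        contact_guess = estimate_poc(seg)
    far = s > contact_guess + 0.2 * (s.max() - contact_guess)
    if np.sum(far) >= 10:
        sigma = 1.4826 * np.median(np.abs(f[far] - np.median(f[far])))
        keep = f >= -max(5 * sigma, 1e-15)
        if np.sum(keep) >= 10:
            s, f = s[keep], f[keep]
    depth0 = np.clip(contact_guess - s, 0, None)
    n_contact = int(np.sum(depth0 > 0))
    if n_contact < 10:
        raise InsufficientDataError(
            f"only {n_contact} samples on the indentation side")
    c_geom = 2 * math.tan(math.radians(alpha_deg)) / math.pi / (1 - nu ** 2)
    dmax = depth0.max()
    e_guess = max(f.max(), 1e-12) / (c_geom * dmax ** 2) if dmax > 0 else 1e6

    span = s.max() - s.min()
    params = Parameters()
    params.add("logE", value=math.log(e_guess), min=math.log(1e3),
               max=math.log(1e13))
    params.add("z0", value=contact_guess, min=s.min() - 0.5 * span,
               max=s.max() + 0.5 * span)
    params.add("offset", value=0.0)

    # force noise on AFM curves grows with the deflection signal, so weight
    # residuals by inverse magnitude (with a floor to keep the baseline in)
    scale = max(np.abs(f).max(), 1e-12)
    weight = 1.0 / (np.abs(f) + 0.02 * scale)

    def resid(p):
        model = sneddon_force(p["z0"].value - s, math.exp(p["logE"].value),
                              alpha_deg, nu) + p["offset"].value
        return (model - f) * weight

    out = lm_minimize(resid, params, method="leastsq")
    if not out.success:
        raise RuntimeError(f"Sneddon fit did not converge: {out.message}")
    E = math.exp(out.params["logE"].value)
    return SneddonFit(E=E, contact_point=float(out.params["z0"].value),
                      force_offset=float(out.params["offset"].value),
                      residual_norm=float(np.sqrt(np.sum(out.residual ** 2))),
                      alpha_deg=alpha_deg, nu=nu)


def adhesion_force(curve: ForceCurve) -> float:
    """|minimum force| on the (flattened) final retraction."""
    seg = flatten_baseline(curve.last_retraction)
    return float(abs(seg.force.min()))


def adhesion_filter(curves: list[ForceCurve],
                    threshold: float = ADHESION_THRESHOLD
                    ) -> tuple[list[ForceCurve], list[tuple[ForceCurve, float]]]:
    """Partition curves by adhesion: keep strictly below the threshold."""
    retained, rejected = [], []
    for c in curves:
        a = adhesion_force(c)
        if a < threshold:
            retained.append(c)
        else:
            rejected.append((c, a))
    return retained, rejected


def analyse_curve(curve: ForceCurve,
                  alpha_deg: float = TIP_HALF_ANGLE_DEG,
                  nu: float = TIP_POISSON,
                  adhesion_threshold: float = ADHESION_THRESHOLD) -> SneddonFit:
    """Full single-curve pipeline on the final retraction segment."""
    seg = flatten_baseline(curve.last_retraction)
    adhesion = float(abs(seg.force.min()))
    poc_h = estimate_poc(seg)
    sep = tip_sample_distance(seg, curve.spring_constant)
    # carry the height-domain POC estimate into the separation domain
    guess = poc_h  # deflection ~ 0 at contact, so the axes coincide there
    fit = fit_sneddon(sep, alpha_deg=alpha_deg, nu=nu, contact_guess=guess)
    fit.adhesion = adhesion
    fit.retained = adhesion < adhesion_threshold
    return fit


def region_median_modulus(fits: pd.DataFrame) -> pd.DataFrame:
    """Per-sample, per-region median modulus over retained fits.

    ``fits`` needs columns ``sample``, ``region``, ``E`` and optionally
    ``retained``.  Regions with no retained fit yield NaN.
    """
    df = fits.copy()
    if "retained" in df:
        df = df[df["retained"]]
    grouped = (df.groupby(["sample", "region"])["E"]
               .median().rename("median_E").reset_index())
    return grouped


# ---------------------------------------------------------------------------
# Text-format I/O


def read_curve_file(path: str | Path, spring_constant: float,
                    trigger_force: float, region: str = "",
                    sample_id: str = "") -> ForceCurve:
    """Read a per-curve CSV with columns height, force, segment."""
    df = pd.read_csv(path)
    need = {"height", "force", "segment"}
    if not need <= set(df.columns):
        raise ValueError(f"curve file must have columns {sorted(need)}")
    segs = [Segment(g["height"].to_numpy(), g["force"].to_numpy(), str(label))
            for label, g in df.groupby("segment", sort=False)]
    return ForceCurve(segs, spring_constant, trigger_force, region, sample_id)


def write_curve_file(path: str | Path, curve: ForceCurve) -> None:
    frames = [pd.DataFrame({"height": s.height, "force": s.force,
                            "segment": s.label}) for s in curve.segments]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def analyse_manifest(manifest_csv: str | Path) -> pd.DataFrame:
    """Process every curve listed in a manifest CSV.

    Columns: ``file``, ``region``, ``sample``, ``spring_constant``,
    ``trigger_force``; paths are relative to the manifest's directory.
    """
    mdir = Path(manifest_csv).parent
    manifest = pd.read_csv(manifest_csv)
    rows = []
    for _, rec in manifest.iterrows():
        curve = read_curve_file(mdir / rec["file"], rec["spring_constant"],
                                rec["trigger_force"], rec.get("region", ""),
                                str(rec.get("sample", "")))
        try:
            fit = analyse_curve(curve)
            rows.append({"file": rec["file"], "sample": curve.sample_id,
                         "region": curve.region, "E": fit.E,
                         "poc": fit.contact_point, "offset": fit.force_offset,
                         "residual": fit.residual_norm,
                         "adhesion": fit.adhesion, "retained": fit.retained})
        except (NoContactError, InsufficientDataError) as exc:
            rows.append({"file": rec["file"], "sample": str(rec.get("sample", "")),
                         "region": rec.get("region", ""), "E": np.nan,
                         "poc": np.nan, "offset": np.nan, "residual": np.nan,
                         "adhesion": np.nan, "retained": False,
                         "error": str(exc)})
    return pd.DataFrame(rows)
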