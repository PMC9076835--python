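"""Parameter containers for the apical-plate actuator model.

Two flat records drive the model: :class:`GeometryParams` holds the nine
measured lengths (μm) that determine the hydrated longitudinal section, and
:class:`MaterialParams` holds the region-wise relative cell-wall densities
(which set relative Young's moduli), the shared Poisson ratio, and the four
intrinsic swelling factors.  Both round-trip through flat YAML config files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import yaml

#: Canonical region names, in drawing/priority order.
REGIONS = ("podium", "vasculature", "side", "cortex")


class InvalidGeometryError(ValueError):
    """Raised when a parameter set cannot produce a valid planar domain."""


@dataclass(frozen=True)
class GeometryParams:
    """Lengths (μm) defining the hydrated apical-plate section.

    Attributes
    ----------
    D : float
        Diameter of the apical plate.
    H : float
        Height of the apical plate.
    R : float
        Radius of curvature of the floral podium cap.
    H_pod : float
        Height (sagitta) of the floral podium.
    H_side : float
        Height of the side regions.
    W_side : float
        Width of the side regions.
    W_vasc : float
        Width of the vascular bands.
    D_cavity : float
        Diameter of the central cavity at the base.
    d_vasc : float
        Prescribed inward displacement of the vascular base, wet -> dry.
    """

    D: float = 491.0
    H: float = 240.0
    R: float = 363.0
    H_pod: float = 38.8
    H_side: float = 91.4
    W_side: float = 47.6
    W_vasc: float = 34.3
    D_cavity: float = 74.8
    d_vasc: float = 15.3

    def __post_init__(self) -> None:
        for name, value in asdict(self).items():
            if not value > 0:
                raise InvalidGeometryError(f"{name} must be strictly positive, got {value}")
        if not self.D_cavity + 2 * self.W_vasc < self.D:
            raise InvalidGeometryError("D_cavity + 2*W_vasc must be < D")
        if not self.H_pod + self.H_side < self.H:
            raise InvalidGeometryError("H_pod + H_side must be < H")
        if not self.d_vasc < self.D / 2:
            raise InvalidGeometryError("d_vasc must be < D/2")
        if self.H_pod > self.R:
            raise InvalidGeometryError("podium sagitta H_pod cannot exceed its radius R")
        # half chord of the podium circular segment must fit in the plate
        if self.H_pod * (2 * self.R - self.H_pod) > (self.D / 2) ** 2:
            raise InvalidGeometryError("podium chord wider than the apical plate (H_pod/R vs D)")

    def replace(self, **kwargs: float) -> "GeometryParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class MaterialParams:
    """Region-wise material description (dimensionless).

    Relative densities are expressed against the vasculature; effective
    tissue Young's modulus is taken linearly proportional to density, so
    ``E_region = E_vasc * rho_region``.  ``s_*`` are intrinsic swelling
    factors: the fraction of area a region would lose on dehydration if
    detached from its neighbours.
    """

    rho_cort: float = 0.76
    rho_pod: float = 1.16
    rho_side: float = 1.04
    rho_vasc: float = 1.0
    nu: float = 0.29
    s_cort: float = 0.46
    s_pod: float = 0.44
    s_side: float = 0.57
    s_vasc: float = 0.24
    E_vasc: float = 1.0

    def __post_init__(self) -> None:
        for r in REGIONS:
            s = self.swelling(r)
            if not 0 < s < 1:
                raise ValueError(f"swelling factor of {r} must lie in (0, 1), got {s}")
            if not self.density(r) > 0:
                raise ValueError(f"relative density of {r} must be positive")
        if not 0 < self.nu < 0.5:
            raise ValueError(f"Poisson ratio must lie in (0, 0.5), got {self.nu}")
        if not self.E_vasc > 0:
            raise ValueError("E_vasc must be positive")

    _SHORT = {"podium": "pod", "vasculature": "vasc", "side": "side", "cortex": "cort"}

    def density(self, region: str) -> float:
        return getattr(self, f"rho_{self._short(region)}")

    def modulus(self, region: str) -> float:
        """Young's modulus of a region (density-proportional)."""
        return self.E_vasc * self.density(region) / self.rho_vasc

    def swelling(self, region: str) -> float:
        return getattr(self, f"s_{self._short(region)}")

    @property
    def swelling_factors(self) -> dict[str, float]:
        return {r: self.swelling(r) for r in REGIONS}

    def with_swelling(self, s: dict[str, float]) -> "MaterialParams":
        kw = {f"s_{self._short(r)}": v for r, v in s.items()}
        return replace(self, **kw)

    def substitute(self, mapping: dict[str, str]) -> "MaterialParams":
        """Give recipient regions the donor region's density and swelling.

        ``mapping`` maps recipient region name -> donor region name; the
        recipient takes the donor's relative density (hence modulus) and
        intrinsic swelling factor.  Everything else is unchanged.
        """
        for r in list(mapping) + list(mapping.values()):
            if r not in REGIONS:
                raise ValueError(f"unknown region {r!r}; expected one of {REGIONS}")
        kw: dict[str, float] = {}
        for recipient, donor in mapping.items():
            kw[f"rho_{self._short(recipient)}"] = self.density(donor)
            kw[f"s_{self._short(recipient)}"] = self.swelling(donor)
        return replace(self, **kw)

    @classmethod
    def _short(cls, region: str) -> str:
        try:
            return cls._SHORT[region]
        except KeyError:
            raise ValueError(f"unknown region {region!r}; expected one of {REGIONS}") from None

    def replace(self, **kwargs: float) -> "MaterialParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return asdict(self)


def reference_config() -> tuple[GeometryParams, MaterialParams]:
    """The measured/fitted parameter set of the reference actuator model."""
    return GeometryParams(), MaterialParams()


# ---------------------------------------------------------------------------
# Flat YAML config I/O


def save_config(path: str | Path, geometry: GeometryParams, materials: MaterialParams) -> None:
    payload = {"geometry": geometry.to_dict(), "materials": materials.to_dict()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_config(path: str | Path) -> tuple[GeometryParams, MaterialParams]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"config {path} is not a mapping")
    geo = GeometryParams(**payload.get("geometry", {}))
    mat = MaterialParams(**payload.get("materials", {}))
    return geo, mat
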