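"""Steady-state nutrient fields around a single algal cell (the phycosphere).

A photosynthesising cell of radius :math:`R` releases dissolved organic
carbon (DOC) at a rate :math:`Q` and takes up nitrate at a rate
:math:`U`.  In the diffusion-dominated regime the steady spherically
symmetric fields are the classic point-source/point-sink solutions

.. math::

    C_\\mathrm{DOC}(r) = C_\\infty + \\frac{Q}{4 \\pi D r}, \\qquad
    C_\\mathrm{NO_3}(r) = \\max\\!\\left(0,\\;
        C_\\infty - \\frac{U_\\mathrm{eff}}{4 \\pi D r}\\right),

for :math:`r \\ge R`, where :math:`U_\\mathrm{eff} = U\\,C_\\infty /
(C_\\infty + K_m)` saturates uptake at the ambient concentration
(Michaelis–Menten evaluated in the far field).  The DOC excess decays as
1/r, so the fold-change between the cell surface and the far field is
set by the ratio of the surface excess to the ambient background of the
same labile compounds.

Units follow :mod:`phycogradients.units`: radii and grids in µm,
concentrations in µM, per-cell rates in fmol cell⁻¹ d⁻¹, diffusivities
in m² s⁻¹.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .units import (
    FMOL_PER_DAY_TO_MOL_PER_S,
    MOL_PER_M3_TO_UM,
    UM_TO_M,
)

__all__ = [
    "GrowthPhase",
    "CellParams",
    "MediumParams",
    "RadialProfile",
    "TransportParams",
    "default_r_grid",
    "steady_state_doc_profile",
    "nitrate_profile",
    "normalize_profile",
    "fold_decrease",
    "stirring_number",
    "load_species_presets",
    "species_cell_and_medium",
]

# Free-solution diffusivities (m² s⁻¹): small sugars / amino acids for
# DOC, nitrate ion in seawater.  Overridable through MediumParams.
D_DOC_DEFAULT = 6.7e-10
D_NITRATE_DEFAULT = 1.7e-9


class GrowthPhase(str, enum.Enum):
    exponential = "exponential"
    stationary = "stationary"


@dataclass(frozen=True)
class CellParams:
    """Per-cell source/sink parameters of one phytoplankton species."""

    species_name: str
    radius_um: float
    exudation_q: float  # fmol C cell⁻¹ d⁻¹
    uptake_vmax: float  # fmol N cell⁻¹ d⁻¹
    uptake_km: float  # µM
    growth_phase: GrowthPhase = GrowthPhase.exponential

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError(f"radius_um must be > 0, got {self.radius_um}")
        if self.exudation_q < 0:
            raise ValueError(f"exudation_q must be >= 0, got {self.exudation_q}")
        if self.uptake_vmax < 0:
            raise ValueError(f"uptake_vmax must be >= 0, got {self.uptake_vmax}")
        if self.uptake_km <= 0:
            raise ValueError(f"uptake_km must be > 0, got {self.uptake_km}")


@dataclass(frozen=True)
class MediumParams:
    """Diffusivities and far-field concentrations of the medium."""

    d_doc: float = D_DOC_DEFAULT  # m² s⁻¹
    d_nitrate: float = D_NITRATE_DEFAULT  # m² s⁻¹
    bulk_doc: float = 0.0  # µM C (labile, exudate-like background)
    bulk_nitrate: float = 882.0  # µM (f/2 nominal nitrate)

    def __post_init__(self) -> None:
        if self.d_doc <= 0 or self.d_nitrate <= 0:
            raise ValueError("diffusivities must be > 0")
        if self.bulk_doc < 0 or self.bulk_nitrate < 0:
            raise ValueError("bulk concentrations must be >= 0")


@dataclass
class RadialProfile:
    """Concentration versus distance from the cell centre.

    ``r`` is in µm (ascending, ``r[0]`` at the cell surface) and ``conc``
    in µM unless ``normalized`` is set, in which case both are scaled to
    their maxima.
    """

    r: np.ndarray
    conc: np.ndarray
    solute: str  # "doc" | "nitrate"
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.r.ndim != 1 or self.r.size < 1:
            raise ValueError("r grid must be a non-empty 1-D array")
        if self.r.shape != self.conc.shape:
            raise ValueError("r and conc must have the same shape")
        if np.any(np.diff(self.r) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"r": self.r, "conc": self.conc,
             "solute": self.solute, "normalized": self.normalized}
        )


@dataclass(frozen=True)
class TransportParams:
    """Inputs of the stirring number lv/D."""

    spacing_l: float  # m, intermolecular spacing
    swim_speed_v: float  # m s⁻¹
    diffusivity_d: float  # m² s⁻¹

    def __post_init__(self) -> None:
        if self.spacing_l <= 0:
            raise ValueError("spacing_l must be > 0")
        if self.swim_speed_v < 0:
            raise ValueError("swim_speed_v must be >= 0")
        if self.diffusivity_d <= 0:
            raise ValueError("diffusivity_d must be > 0")


def default_r_grid(radius_um: float, extent: float = 100.0, n: int = 200) -> np.ndarray:
    """Log-spaced grid from the cell surface out to ``extent``·radius (µm)."""
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    if extent <= 1:
        raise ValueError("extent must exceed 1 cell radius")
    return np.geomspace(radius_um, extent * radius_um, n)


def _check_grid(r_grid: np.ndarray, radius_um: float) -> np.ndarray:
    r = np.asarray(r_grid, dtype=float)
    if r.size == 0:
        raise ValueError("empty r grid")
    if r[0] < radius_um * (1 - 1e-12):
        raise ValueError(
            f"r grid starts at {r[0]} µm, inside the cell radius {radius_um} µm"
        )
    return r


def _excess_um(rate_fmol_per_day: float, d: float, r_um: np.ndarray) -> np.ndarray:
    """rate/(4πDr) with rate in fmol cell⁻¹ d⁻¹, r in µm -> µM."""
    rate_si = rate_fmol_per_day * FMOL_PER_DAY_TO_MOL_PER_S
    return rate_si / (4.0 * math.pi * d * r_um * UM_TO_M) * MOL_PER_M3_TO_UM


def steady_state_doc_profile(
    cell: CellParams, medium: MediumParams, r_grid: np.ndarray | None = None
) -> RadialProfile:
    """DOC field around an exuding cell: C_bulk + Q/(4πDr)."""
    if r_grid is None:
        r_grid = default_r_grid(cell.radius_um)
    r = _check_grid(r_grid, cell.radius_um)
    conc = medium.bulk_doc + _excess_um(cell.exudation_q, medium.d_doc, r)
    return RadialProfile(r, conc, "doc", meta={"species": cell.species_name,
                                              "phase": cell.growth_phase.value})


def nitrate_profile(
    cell: CellParams, medium: MediumParams, r_grid: np.ndarray | None = None
) -> RadialProfile:
    """Nitrate field around a consuming cell: max(0, C_bulk − U_eff/(4πDr)).

    Uptake saturates at the far-field concentration:
    U_eff = U·C_bulk/(C_bulk + Km).
    """
    if r_grid is None:
        r_grid = default_r_grid(cell.radius_um)
    r = _check_grid(r_grid, cell.radius_um)
    c_inf = medium.bulk_nitrate
    u_eff = cell.uptake_vmax * c_inf / (c_inf + cell.uptake_km)
    conc = np.maximum(0.0, c_inf - _excess_um(u_eff, medium.d_nitrate, r))
    return RadialProfile(r, conc, "nitrate", meta={"species": cell.species_name,
                                                   "phase": cell.growth_phase.value})


def normalize_profile(profile: RadialProfile) -> RadialProfile:
    """Scale concentration and distance each by its maximum.

    An all-zero profile (fully depleted medium) stays all-zero; the
    normalized flag is still set and a warning is emitted.
    """
    if profile.r.size < 1:
        raise ValueError("empty profile")
    r_max = profile.r.max()
    c_max = profile.conc.max()
    if c_max == 0.0:
        warnings.warn(
            "normalizing an all-zero profile: concentrations left at zero",
            RuntimeWarning, stacklevel=2,
        )
        conc = profile.conc.copy()
    else:
        conc = profile.conc / c_max
    return replace(profile, r=profile.r / r_max, conc=conc, normalized=True)


def fold_decrease(profile: RadialProfile) -> float:
    """Surface-to-far-field concentration fold.

    For a source solute (DOC) this is conc(r_min)/conc(r_max); for a
    sink (nitrate) the reciprocal orientation, conc(r_max)/conc(r_min).
    A zero denominator (depleted end) yields +inf with a warning.
    """
    near, far = profile.conc[0], profile.conc[-1]
    num, den = (near, far) if profile.solute == "doc" else (far, near)
    if den == 0.0:
        warnings.warn("depleted reference concentration: fold is infinite",
                      RuntimeWarning, stacklevel=2)
        return math.inf
    return float(num / den)


def stirring_number(t: TransportParams) -> float:
    """Dimensionless lv/D comparing swimming to diffusive encounter."""
    return t.spacing_l * t.swim_speed_v / t.diffusivity_d


# ---------------------------------------------------------------------------
# Species presets


def load_species_presets() -> pd.DataFrame:
    """Species parameter table shipped with the package.

    Columns carry a provenance tag; values flagged "literature default"
    are scale estimates from published culture studies, not transcribed
    measurements.
    """
    with resources.files("phycogradients.data").joinpath("species_presets.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def species_cell_and_medium(
    species: str,
    phase: GrowthPhase | str = GrowthPhase.exponential,
    presets: pd.DataFrame | None = None,
) -> tuple[CellParams, MediumParams]:
    """Build (CellParams, MediumParams) for a preset species and phase."""
    phase = GrowthPhase(phase)
    table = load_species_presets() if presets is None else presets
    rows = table[table["species"] == species]
    if rows.empty:
        known = ", ".join(table["species"])
        raise KeyError(f"unknown species {species!r}; presets: {known}")
    row = rows.iloc[0]
    suffix = "exp" if phase is GrowthPhase.exponential else "stat"
    cell = CellParams(
        species_name=species,
        radius_um=float(row["radius_um"]),
        exudation_q=float(row[f"exudation_q_{suffix}"]),
        uptake_vmax=float(row["uptake_vmax"]),
        uptake_km=float(row["uptake_km"]),
        growth_phase=phase,
    )
    medium = MediumParams(
        d_doc=D_DOC_DEFAULT,
        d_nitrate=D_NITRATE_DEFAULT,
        bulk_doc=float(row[f"bulk_doc_{suffix}"]),
        bulk_nitrate=float(row[f"bulk_nitrate_{suffix}"]),
    )
    return cell, medium
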