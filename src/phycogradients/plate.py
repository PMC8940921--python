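"""Diffusive well-network model of the porous microplate.

Wells are treated as well-mixed compartments joined by nanoporous
copolymer walls; solutes cross a wall by Fickian diffusion,

.. math:: J_{ij} = D_\\mathrm{eff} A \\,(C_i - C_j)/L,

where :math:`A` is the shared wall cross-section and :math:`L` its
thickness.  The plate sits in a medium reservoir that either holds its
concentrations fixed (default: its volume is ~250× a well) or is a
finite compartment.  An algal population in designated wells grows on
nitrate with Monod kinetics, draws nitrate down in proportion to growth
through its cell quota, and exudes DOC at a constant per-cell rate:

.. math::

    \\mu = \\mu_\\max \\frac{C_N}{C_N + K_m}, \\qquad
    \\frac{dN}{dt} = \\mu N, \\qquad
    \\frac{dC_N}{dt} \\ni -q_N \\mu N, \\qquad
    \\frac{dC_\\mathrm{DOC}}{dt} \\ni +Q N .

Quota coupling makes growth and drawdown mass-consistent, so the batch
carrying capacity C_N(0)/q_N emerges rather than being imposed.

Units: days, µM, cells ml⁻¹, mm (geometry), µl (volumes), m² s⁻¹
(diffusivities); see :mod:`phycogradients.units`.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .phycosphere import D_DOC_DEFAULT, D_NITRATE_DEFAULT, MediumParams
from .units import PER_CELL_RATE_TO_UM_PER_DAY, SECONDS_PER_DAY, wall_exchange_rate_per_day

__all__ = [
    "RESERVOIR",
    "WallParams",
    "WellRole",
    "Well",
    "Edge",
    "Reservoir",
    "PlateLayout",
    "AlgalPopulation",
    "WellTimeSeries",
    "build_layout",
    "diffusive_flux",
    "simulate_plate",
    "doc_fold_across_wells",
    "nitrate_depletion_time",
    "peclet_check",
    "PecletResult",
]

RESERVOIR = "RESERVOIR"

# Effective diffusivities through the HEMA-EDMA wall (m² s⁻¹), per
# solute.  These are calibrated lumped conductances of the compartment
# model (they absorb porosity, tortuosity and solute partitioning into
# the water-swollen copolymer): DOC at ~0.1x free solution, nitrate
# strongly hindered so that well-reservoir equilibration of the
# inorganic pool sits on the multi-day timescale that reproduces the
# centre-well depletion timing and the reservoir-driven capacity gain.
# See the methods note for the calibration argument.
D_EFF_DOC_DEFAULT = 6.0e-11
D_EFF_NITRATE_DEFAULT = 3.4e-12


@dataclass(frozen=True)
class WallParams:
    """Geometry and per-solute effective diffusivity of one porous wall."""

    thickness_mm: float = 0.9
    area_mm2: float = 15.0
    d_eff_doc: float = D_EFF_DOC_DEFAULT
    d_eff_nitrate: float = D_EFF_NITRATE_DEFAULT

    def __post_init__(self) -> None:
        if self.thickness_mm <= 0:
            raise ValueError("wall thickness must be > 0")
        if self.area_mm2 <= 0:
            raise ValueError("wall area must be > 0")
        if not (0 < self.d_eff_doc <= D_DOC_DEFAULT):
            raise ValueError(
                f"d_eff_doc must be in (0, {D_DOC_DEFAULT}] (free-solution bound)")
        if not (0 < self.d_eff_nitrate <= D_NITRATE_DEFAULT):
            raise ValueError(
                f"d_eff_nitrate must be in (0, {D_NITRATE_DEFAULT}] (free-solution bound)")

    def d_eff(self, solute: str) -> float:
        if solute == "doc":
            return self.d_eff_doc
        if solute == "nitrate":
            return self.d_eff_nitrate
        raise KeyError(f"unknown solute {solute!r}")


class WellRole(str, enum.Enum):
    alga = "alga"
    bacteria = "bacteria"
    blank = "blank"
    medium_control = "medium-control"


@dataclass(frozen=True)
class Well:
    id: str
    x_mm: float
    y_mm: float
    volume_ul: float
    role: WellRole = WellRole.blank

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError(f"well {self.id}: volume must be > 0")

    def distance_to(self, other: "Well") -> float:
        return math.hypot(self.x_mm - other.x_mm, self.y_mm - other.y_mm)


@dataclass(frozen=True)
class Edge:
    a: str
    b: str  # well id or RESERVOIR
    wall: WallParams = field(default_factory=WallParams)


@dataclass(frozen=True)
class Reservoir:
    """External medium bath.  volume_ml=None keeps concentrations fixed."""

    doc: float = 0.0  # µM C
    nitrate: float = 882.0  # µM, f/2-Si nominal
    volume_ml: float | None = None

    def __post_init__(self) -> None:
        if self.doc < 0 or self.nitrate < 0:
            raise ValueError("reservoir concentrations must be >= 0")
        if self.volume_ml is not None and self.volume_ml <= 0:
            raise ValueError("reservoir volume must be > 0 (or None for fixed)")


class LayoutError(ValueError):
    pass


@dataclass
class PlateLayout:
    wells: list[Well]
    edges: list[Edge]
    reservoir: Reservoir = field(default_factory=Reservoir)
    name: str = "custom"

    def __post_init__(self) -> None:
        ids = [w.id for w in self.wells]
        if len(set(ids)) != len(ids):
            raise LayoutError("duplicate well ids")
        if not self.wells:
            raise LayoutError("layout has no wells")
        self._index = {w.id: i for i, w in enumerate(self.wells)}
        for e in self.edges:
            for node in (e.a, e.b):
                if node != RESERVOIR and node not in self._index:
                    raise LayoutError(f"edge references unknown well {node!r}")
            if e.a == e.b:
                raise LayoutError("self-loop edge")
        for i, w in enumerate(self.wells):
            for v in self.wells[i + 1:]:
                if w.distance_to(v) < 1e-9:
                    raise LayoutError(f"wells {w.id} and {v.id} overlap")
        self._check_connected()

    def _check_connected(self) -> None:
        nodes = set(self._index) | {RESERVOIR}
        adj: dict[str, set[str]] = {n: set() for n in nodes}
        for e in self.edges:
            adj[e.a].add(e.b)
            adj[e.b].add(e.a)
        seen = {self.wells[0].id}
        stack = [self.wells[0].id]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        missing = set(self._index) - seen
        if missing:
            raise LayoutError(f"disconnected wells: {sorted(missing)}")

    # -- lookups ---------------------------------------------------------
    @property
    def well_ids(self) -> list[str]:
        return [w.id for w in self.wells]

    def well(self, well_id: str) -> Well:
        return self.wells[self._index[well_id]]

    def index(self, well_id: str) -> int:
        return self._index[well_id]

    def wells_by_role(self, role: WellRole) -> list[Well]:
        return [w for w in self.wells if w.role == role]

    def distances_from_alga(self) -> dict[str, float]:
        """Euclidean distance (mm) of every well from the algal well(s)."""
        algal = self.wells_by_role(WellRole.alga)
        if not algal:
            raise LayoutError("layout has no algal well")
        return {
            w.id: min(w.distance_to(a) for a in algal) for w in self.wells
        }

    def exchange_operator(self, solute: str) -> tuple[np.ndarray, np.ndarray]:
        """Linear diffusion operator for one solute.

        Returns (A, r) with dC/dt = A @ C + r * C_reservoir, in d⁻¹;
        r[i] is well i's volumetric exchange rate with the reservoir.
        """
        m = len(self.wells)
        a = np.zeros((m, m))
        r = np.zeros(m)
        for e in self.edges:
            wall = e.wall
            d = wall.d_eff(solute)
            if RESERVOIR in (e.a, e.b):
                wid = e.b if e.a == RESERVOIR else e.a
                i = self._index[wid]
                k = wall_exchange_rate_per_day(
                    d, wall.area_mm2, wall.thickness_mm, self.wells[i].volume_ul)
                r[i] += k  # reservoir term enters as r*(C_res - C)
            else:
                i, j = self._index[e.a], self._index[e.b]
                k_i = wall_exchange_rate_per_day(
                    d, wall.area_mm2, wall.thickness_mm, self.wells[i].volume_ul)
                k_j = wall_exchange_rate_per_day(
                    d, wall.area_mm2, wall.thickness_mm, self.wells[j].volume_ul)
                a[i, i] -= k_i
                a[i, j] += k_i
                a[j, j] -= k_j
                a[j, i] += k_j
        return a, r


@dataclass(frozen=True)
class AlgalPopulation:
    """Nitrate-limited algal population (P. tricornutum scale defaults)."""

    initial_density: float = 1e6  # cells ml⁻¹
    mu_max: float = 0.5  # d⁻¹
    monod_km: float = 1.0  # µM nitrate
    quota_n: float = 70.0  # fmol N cell⁻¹ (sets batch capacity 882/q ≈ 1.3e7)
    exudation_q: float = 60.0  # fmol C cell⁻¹ d⁻¹

    def __post_init__(self) -> None:
        if self.initial_density < 0:
            raise ValueError("initial_density must be >= 0")
        if self.mu_max <= 0:
            raise ValueError("mu_max must be > 0")
        if self.monod_km <= 0 or self.quota_n <= 0:
            raise ValueError("monod_km and quota_n must be > 0")
        if self.exudation_q < 0:
            raise ValueError("exudation_q must be >= 0")


@dataclass
class WellTimeSeries:
    """Per-well trajectories: solute concentrations and populations."""

    time: np.ndarray  # d
    well_ids: list[str]
    doc: np.ndarray  # (t, wells) µM C
    nitrate: np.ndarray  # (t, wells) µM
    algae: np.ndarray  # (t, wells) cells ml⁻¹
    bacteria: dict[str, np.ndarray] = field(default_factory=dict)
    layout: PlateLayout | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for name in ("doc", "nitrate", "algae"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.time.size, len(self.well_ids)):
                raise ValueError(f"{name} has shape {arr.shape}, expected "
                                 f"({self.time.size}, {len(self.well_ids)})")
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative values")
            setattr(self, name, arr)

    def column(self, field_name: str, well_id: str) -> np.ndarray:
        j = self.well_ids.index(well_id)
        return getattr(self, field_name)[:, j]

    def at_time(self, t: float, field_name: str) -> np.ndarray:
        """Linear interpolation of one field across wells at time t."""
        arr = getattr(self, field_name)
        return np.array([np.interp(t, self.time, arr[:, j])
                         for j in range(arr.shape[1])])

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time, well_id, variable, value."""
        frames = []
        for name in ("doc", "nitrate", "algae"):
            arr = getattr(self, name)
            for j, wid in enumerate(self.well_ids):
                frames.append(pd.DataFrame(
                    {"time": self.time, "well_id": wid,
                     "variable": name, "value": arr[:, j]}))
        for taxon, arr in self.bacteria.items():
            for j, wid in enumerate(self.well_ids):
                frames.append(pd.DataFrame(
                    {"time": self.time, "well_id": wid,
                     "variable": taxon, "value": arr[:, j]}))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Layout presets

_WALL = WallParams()
_HEX_ANGLES = np.deg2rad(np.arange(0, 360, 60))


def _ring(prefix: str, radius_mm: float, volume_ul: float, role: WellRole,
          n: int = 6, phase_deg: float = 0.0) -> list[Well]:
    angles = np.deg2rad(np.arange(0, 360, 360 / n) + phase_deg)
    return [
        Well(f"{prefix}{i + 1}", radius_mm * math.cos(a), radius_mm * math.sin(a),
             volume_ul, role)
        for i, a in enumerate(angles)
    ]


def build_layout(preset: str = "hex7", *, wall: WallParams = _WALL,
                 reservoir: Reservoir | None = None,
                 volume_ul: float | None = None) -> PlateLayout:
    """Construct a named well-array layout.

    Presets
    -------
    hex7
        One centre well and six surrounding wells at 8 mm pitch, all
        holding algae (growth experiment; 75 µl per well).
    isolate_rings
        Central algal well with a radial arm of bacterial wells at 7,
        14 and 21 mm, the outermost adjacent to the reservoir
        (isolates experiment; 100 µl).
    community_layers
        Central algal well, six layer-1 bacterial wells at 8 mm and six
        layer-2 bacterial wells at 16 mm, layer 2 facing the reservoir
        (community experiment; 100 µl).
    """
    res = reservoir if reservoir is not None else Reservoir()
    if preset == "hex7":
        vol = volume_ul if volume_ul is not None else 75.0
        wells = [Well("centre", 0.0, 0.0, vol, WellRole.alga)]
        wells += _ring("outer", 8.0, vol, WellRole.alga)
        edges = [Edge("centre", f"outer{i}", wall) for i in range(1, 7)]
        edges += [Edge(f"outer{i}", f"outer{i % 6 + 1}", wall) for i in range(1, 7)]
        edges += [Edge(f"outer{i}", RESERVOIR, wall) for i in range(1, 7)]
        return PlateLayout(wells, edges, res, name="hex7")
    if preset == "isolate_rings":
        # two opposite radial arms of monoculture wells (one strain per
        # arm), at 7/14/21 mm, outermost facing the reservoir
        vol = volume_ul if volume_ul is not None else 100.0
        wells = [Well("centre", 0.0, 0.0, vol, WellRole.alga)]
        edges = []
        for arm, sign in (("A", 1.0), ("B", -1.0)):
            prev = "centre"
            for d in (7, 14, 21):
                wid = f"{arm}{d}"
                wells.append(Well(wid, sign * d, 0.0, vol, WellRole.bacteria))
                edges.append(Edge(prev, wid, wall))
                prev = wid
            edges.append(Edge(prev, RESERVOIR, wall))
        return PlateLayout(wells, edges, res, name="isolate_rings")
    if preset == "community_layers":
        vol = volume_ul if volume_ul is not None else 100.0
        wells = [Well("centre", 0.0, 0.0, vol, WellRole.alga)]
        wells += _ring("L1-", 8.0, vol, WellRole.bacteria)
        wells += _ring("L2-", 16.0, vol, WellRole.bacteria)
        edges = [Edge("centre", f"L1-{i}", wall) for i in range(1, 7)]
        edges += [Edge(f"L1-{i}", f"L1-{i % 6 + 1}", wall) for i in range(1, 7)]
        edges += [Edge(f"L1-{i}", f"L2-{i}", wall) for i in range(1, 7)]
        edges += [Edge(f"L2-{i}", RESERVOIR, wall) for i in range(1, 7)]
        return PlateLayout(wells, edges, res, name="community_layers")
    raise LayoutError(f"unknown preset {preset!r}; use hex7, isolate_rings, "
                      "community_layers or build a PlateLayout directly")


# ---------------------------------------------------------------------------
# Fluxes and simulation


def diffusive_flux(c_i: float, c_j: float, wall: WallParams,
                   solute: str = "doc") -> float:
    """Fickian flux through one wall, nmol d⁻¹ (positive from i to j)."""
    d = wall.d_eff(solute)
    j_mol_s = (d * wall.area_mm2 * 1e-6
               * (c_i - c_j) * 1e-3  # µM -> mol m⁻³
               / (wall.thickness_mm * 1e-3))
    return j_mol_s * SECONDS_PER_DAY * 1e9


def simulate_plate(
    layout: PlateLayout,
    alga: AlgalPopulation | None,
    medium: MediumParams | None = None,
    t_span: tuple[float, float] = (0.0, 20.0),
    dt_out: float = 0.1,
    seed: int | None = None,
    *,
    initial_doc: float | np.ndarray | None = None,
    initial_nitrate: float | np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
    method: str = "LSODA",
) -> WellTimeSeries:
    """Integrate the well-network ODEs.

    Wells start pre-equilibrated with the medium (nitrate at the
    reservoir level, DOC at zero) unless initial fields are given.  The
    run is deterministic; ``seed`` is accepted for interface symmetry
    and recorded in the metadata.
    """
    del seed  # no stochastic terms in the nutrient model
    m = len(layout.wells)
    res = layout.reservoir
    if medium is None:
        medium = MediumParams(bulk_doc=res.doc, bulk_nitrate=res.nitrate)

    a_doc, r_doc = layout.exchange_operator("doc")
    a_no3, r_no3 = layout.exchange_operator("nitrate")

    algal_mask = np.array([w.role == WellRole.alga for w in layout.wells])
    n0 = np.where(algal_mask, alga.initial_density if alga else 0.0, 0.0)

    doc0 = np.full(m, res.doc if initial_doc is None else initial_doc, dtype=float)
    no30 = np.full(m, res.nitrate if initial_nitrate is None else initial_nitrate,
                   dtype=float)
    finite_res = res.volume_ml is not None
    y0 = np.concatenate([doc0, no30, n0, [res.doc, res.nitrate] if finite_res else []])

    vols_ul = np.array([w.volume_ul for w in layout.wells])
    if finite_res:
        # reservoir balance: moles leaving wells enter the bath
        vol_ratio = vols_ul / (res.volume_ml * 1e3)

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        doc = y[:m]
        no3 = y[m:2 * m]
        n_alg = y[2 * m:3 * m]
        c_res_doc, c_res_no3 = (y[3 * m], y[3 * m + 1]) if finite_res \
            else (res.doc, res.nitrate)
        no3_pos = np.maximum(no3, 0.0)
        d_doc = a_doc @ doc + r_doc * (c_res_doc - doc)
        d_no3 = a_no3 @ no3 + r_no3 * (c_res_no3 - no3)
        d_n = np.zeros(m)
        if alga is not None:
            mu = alga.mu_max * no3_pos / (no3_pos + alga.monod_km) * algal_mask
            d_n = mu * n_alg
            d_no3 = d_no3 - alga.quota_n * mu * n_alg * PER_CELL_RATE_TO_UM_PER_DAY
            d_doc = d_doc + alga.exudation_q * n_alg * PER_CELL_RATE_TO_UM_PER_DAY \
                * algal_mask
        if finite_res:
            d_res_doc = -np.sum(r_doc * (c_res_doc - doc) * vol_ratio)
            d_res_no3 = -np.sum(r_no3 * (c_res_no3 - no3) * vol_ratio)
            return np.concatenate([d_doc, d_no3, d_n, [d_res_doc, d_res_no3]])
        return np.concatenate([d_doc, d_no3, d_n])

    t0, t1 = t_span
    t_eval = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
    t_eval[-1] = min(t_eval[-1], t1)
    sol = solve_ivp(rhs, (t0, t1), y0, method=method, t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(
            f"plate ODE solver failed: {sol.message}; layout={layout.name}, "
            f"alga={alga}, t_span={t_span}, rtol={rtol}, atol={atol}")
    y = sol.y.T
    floor = -10 * max(atol, 1e-12)
    if y.min() < floor:
        raise RuntimeError(
            f"negative state detected (min {y.min():.3e}); tighten tolerances "
            f"(rtol={rtol}, atol={atol}) or check parameters")
    y = np.clip(y, 0.0, None)
    return WellTimeSeries(
        time=sol.t,
        well_ids=layout.well_ids,
        doc=y[:, :m],
        nitrate=y[:, m:2 * m],
        algae=y[:, 2 * m:3 * m],
        layout=layout,
        meta={
            "solver": {"method": method, "rtol": rtol, "atol": atol,
                       "nfev": int(sol.nfev)},
            "reservoir": {"doc": res.doc, "nitrate": res.nitrate,
                          "volume_ml": res.volume_ml},
            "finite_reservoir": finite_res,
        },
    )


# ---------------------------------------------------------------------------
# Diagnostics


def doc_fold_across_wells(series: WellTimeSeries, t: float | None = None,
                          include_algal: bool = True) -> float:
    """DOC(nearest)/DOC(farthest) across wells ranked by distance from
    the algal well, at time ``t`` (default: end of the run).

    With ``include_algal`` (default) the nearest well is the algal well
    itself, i.e. the centre-to-outermost fold.
    """
    if series.layout is None:
        raise ValueError("series carries no layout; cannot rank wells by distance")
    dist = series.layout.distances_from_alga()
    ids = [w.id for w in series.layout.wells
           if include_algal or w.role != WellRole.alga]
    if len({round(dist[i], 9) for i in ids}) < 2:
        raise ValueError("need wells at >= 2 distinct distances from the alga")
    t = series.time[-1] if t is None else t
    doc = series.at_time(t, "doc")
    near = min(ids, key=lambda i: dist[i])
    far = max(ids, key=lambda i: dist[i])
    c_far = doc[series.well_ids.index(far)]
    c_near = doc[series.well_ids.index(near)]
    if c_far == 0.0:
        warnings.warn("far-field DOC is zero: fold is infinite", RuntimeWarning,
                      stacklevel=2)
        return math.inf
    return float(c_near / c_far)


def nitrate_depletion_time(series: WellTimeSeries, well_id: str,
                           threshold_fraction: float = 0.01) -> float:
    """First time (d) a well's nitrate falls to ``threshold_fraction`` of
    its initial value; +inf if it never does."""
    if not 0 < threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in (0, 1)")
    c = series.column("nitrate", well_id)
    thr = threshold_fraction * c[0]
    below = np.nonzero(c <= thr)[0]
    if below.size == 0:
        return math.inf
    k = below[0]
    if k == 0:
        return float(series.time[0])
    # linear interpolation of the crossing
    t0, t1 = series.time[k - 1], series.time[k]
    c0, c1 = c[k - 1], c[k]
    if c1 == c0:
        return float(t1)
    return float(t0 + (c0 - thr) / (c0 - c1) * (t1 - t0))


@dataclass(frozen=True)
class PecletResult:
    pe: float
    negligible: bool


def peclet_check(flow_speed: float, length: float, diffusivity: float,
                 threshold: float = 0.1) -> PecletResult:
    """Péclet number vL/D and whether advective transport is negligible."""
    if flow_speed < 0:
        raise ValueError("flow_speed must be >= 0")
    if length <= 0:
        raise ValueError("length must be > 0")
    if diffusivity <= 0:
        raise ValueError("diffusivity must be > 0")
    pe = flow_speed * length / diffusivity
    return PecletResult(pe=pe, negligible=pe < threshold)
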