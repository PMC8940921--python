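"""Synthetic algal-bacterial co-culture generator.

Bacterial taxa grow in the plate's wells on the simulated DOC and
nitrate fields.  Two lifestyles span the niche axis observed in
algal-microbiome cultures: *exudate specialists* grow only on algal
organic carbon, while *generalists* additionally grow on the inorganic
pool.  Per taxon b in well i,

.. math::

    \\frac{dB}{dt} = \\left[
        \\mu^{C}_\\max \\frac{C_\\mathrm{DOC}}{K_C + C_\\mathrm{DOC}}
      + \\mu^{N}_\\max \\frac{C_N}{K_N + C_N}
    \\right] B - m B,

with the two resource terms additive and substitutable, and resource
drawdown coupled through fixed cell yields.  The growth model is a
synthetic-data stand-in calibrated to the qualitative spatial patterns
of isolate and community co-cultures, not a fitted measurement.

The module also emulates the two measurement channels of such
experiments: flow-cytometry counts calibrated with counting beads, and
16S-like relative-abundance tables with multinomial sampling and
lognormal overdispersion.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .phycosphere import MediumParams
from .plate import AlgalPopulation, PlateLayout, WellRole, WellTimeSeries
from .units import PER_CELL_RATE_TO_UM_PER_DAY

__all__ = [
    "Strategy",
    "TaxonParams",
    "CytometrySample",
    "simulate_cocultures",
    "abundance_table",
    "sample_cytometry",
    "to_relative_abundance",
    "isolate_presets",
    "community_preset",
    "ABUNDANCE_COLUMNS",
]

#: (cells ml⁻¹ d⁻¹) / (cells µmol⁻¹) -> µM d⁻¹ drawdown
_DRAWDOWN = 1e3


class Strategy(str, enum.Enum):
    exudate_specialist = "exudate_specialist"
    generalist = "generalist"


@dataclass(frozen=True)
class TaxonParams:
    """Growth strategy of one bacterial taxon.

    Yields are in cells per µmol of resource; an exudate specialist has
    ``mu_max_n == 0`` by definition.
    """

    name: str
    strategy: Strategy
    mu_max_doc: float  # d⁻¹
    km_doc: float  # µM C
    mu_max_n: float = 0.0  # d⁻¹
    km_n: float = 20.0  # µM
    yield_doc: float = 1e8  # cells µmol⁻¹ C
    yield_n: float = 1e9  # cells µmol⁻¹ N
    mortality: float = 0.1  # d⁻¹
    initial_density: float = 1e5  # cells ml⁻¹

    def __post_init__(self) -> None:
        if min(self.mu_max_doc, self.mu_max_n, self.mortality,
               self.initial_density) < 0:
            raise ValueError(f"taxon {self.name}: rates must be >= 0")
        if self.km_doc <= 0 or self.km_n <= 0:
            raise ValueError(f"taxon {self.name}: half-saturations must be > 0")
        if self.yield_doc <= 0 or self.yield_n <= 0:
            raise ValueError(f"taxon {self.name}: yields must be > 0")
        if self.strategy is Strategy.exudate_specialist and self.mu_max_n != 0:
            raise ValueError(
                f"taxon {self.name}: an exudate specialist has mu_max_n = 0")


@dataclass(frozen=True)
class CytometrySample:
    """One stained, bead-calibrated cytometry acquisition."""

    bead_events: float
    cell_events: float
    dilution_factor: float
    bead_stock_density: float  # beads ml⁻¹ in the analysed mix

    def __post_init__(self) -> None:
        if self.bead_events < 0 or self.cell_events < 0:
            raise ValueError("event counts must be >= 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be >= 1")

    @property
    def estimated_density(self) -> float:
        """Back-calculated cell density (cells ml⁻¹); NaN if no beads."""
        if self.bead_events == 0:
            warnings.warn("no bead events: density estimate undefined",
                          RuntimeWarning, stacklevel=2)
            return float("nan")
        return (self.cell_events / self.bead_events
                * self.bead_stock_density * self.dilution_factor)


# ---------------------------------------------------------------------------
# Dynamics


def simulate_cocultures(
    layout: PlateLayout,
    alga: AlgalPopulation | None,
    taxa: list[TaxonParams],
    medium: MediumParams | None = None,
    t_span: tuple[float, float] = (0.0, 20.0),
    seed: int | None = None,
    *,
    dt_out: float = 0.25,
    inoculum: dict[str, dict[str, float]] | None = None,
    table_times: list[float] | None = None,
    n_replicates: int = 3,
    geometric_sd: float = 1.3,
    initial_doc: float | np.ndarray | None = None,
    initial_nitrate: float | np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-9,
) -> tuple[WellTimeSeries, pd.DataFrame]:
    """Co-culture dynamics plus a replicated abundance table.

    ``inoculum`` maps taxon name -> {well_id: cells ml⁻¹}; by default
    every bacteria-role well receives every taxon at its preset initial
    density.  The ODE integration is deterministic; ``seed`` drives only
    the replicate noise of the abundance table and is mandatory when
    ``geometric_sd > 1`` (unseeded stochastic calls are an error).
    """
    if not taxa:
        raise ValueError("taxon list is empty")
    names = [t.name for t in taxa]
    if len(set(names)) != len(names):
        raise ValueError("duplicate taxon names")
    if geometric_sd > 1.0 and seed is None:
        raise ValueError("seed is required when replicate noise is enabled")

    m = len(layout.wells)
    res = layout.reservoir
    if medium is None:
        medium = MediumParams(bulk_doc=res.doc, bulk_nitrate=res.nitrate)
    a_doc, r_doc = layout.exchange_operator("doc")
    a_no3, r_no3 = layout.exchange_operator("nitrate")
    algal_mask = np.array([w.role == WellRole.alga for w in layout.wells])

    b0 = np.zeros((len(taxa), m))
    if inoculum is None:
        bact = [i for i, w in enumerate(layout.wells)
                if w.role == WellRole.bacteria]
        for k, t in enumerate(taxa):
            b0[k, bact] = t.initial_density
    else:
        for k, t in enumerate(taxa):
            for wid, dens in inoculum.get(t.name, {}).items():
                b0[k, layout.index(wid)] = dens

    n0 = np.where(algal_mask, alga.initial_density if alga else 0.0, 0.0)
    doc0 = np.full(m, res.doc if initial_doc is None else initial_doc,
                   dtype=float)
    no30 = np.full(m, res.nitrate if initial_nitrate is None else initial_nitrate,
                   dtype=float)
    y0 = np.concatenate([doc0, no30, n0, b0.ravel()])

    mu_doc = np.array([t.mu_max_doc for t in taxa])[:, None]
    km_doc = np.array([t.km_doc for t in taxa])[:, None]
    mu_n = np.array([t.mu_max_n for t in taxa])[:, None]
    km_n = np.array([t.km_n for t in taxa])[:, None]
    y_doc = np.array([t.yield_doc for t in taxa])[:, None]
    y_n = np.array([t.yield_n for t in taxa])[:, None]
    mort = np.array([t.mortality for t in taxa])[:, None]

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        doc = y[:m]
        no3 = y[m:2 * m]
        n_alg = y[2 * m:3 * m]
        b = y[3 * m:].reshape(len(taxa), m)
        doc_pos = np.maximum(doc, 0.0)
        no3_pos = np.maximum(no3, 0.0)
        d_doc = a_doc @ doc + r_doc * (res.doc - doc)
        d_no3 = a_no3 @ no3 + r_no3 * (res.nitrate - no3)
        if alga is not None:
            mu_a = alga.mu_max * no3_pos / (no3_pos + alga.monod_km) * algal_mask
            d_n = mu_a * n_alg
            d_no3 = d_no3 - alga.quota_n * mu_a * n_alg * PER_CELL_RATE_TO_UM_PER_DAY
            d_doc = d_doc + alga.exudation_q * n_alg * PER_CELL_RATE_TO_UM_PER_DAY \
                * algal_mask
        else:
            d_n = np.zeros(m)
        g_doc = mu_doc * doc_pos / (km_doc + doc_pos)  # (taxa, wells)
        g_n = mu_n * no3_pos / (km_n + no3_pos)
        d_b = (g_doc + g_n - mort) * b
        d_doc = d_doc - _DRAWDOWN * np.sum(g_doc * b / y_doc, axis=0)
        d_no3 = d_no3 - _DRAWDOWN * np.sum(g_n * b / y_n, axis=0)
        return np.concatenate([d_doc, d_no3, d_n, d_b.ravel()])

    t0, t1 = t_span
    t_eval = np.arange(t0, t1 + 0.5 * dt_out, dt_out)
    sol = solve_ivp(rhs, (t0, t1), y0, method="LSODA", t_eval=t_eval,
                    rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"co-culture ODE solver failed: {sol.message}; "
                           f"layout={layout.name}, taxa={names}")
    y = sol.y.T
    # numerically negligible undershoot is tolerated relative to each
    # state block's scale; anything larger means solver trouble
    floor = -1e-7 * max(1.0, float(np.abs(y).max(initial=1.0)))
    if y.min() < floor:
        raise RuntimeError(f"negative state detected (min {y.min():.3e}, "
                           f"floor {floor:.3e}); tighten tolerances")
    y = np.clip(y, 0.0, None)

    series = WellTimeSeries(
        time=sol.t,
        well_ids=layout.well_ids,
        doc=y[:, :m],
        nitrate=y[:, m:2 * m],
        algae=y[:, 2 * m:3 * m],
        bacteria={t_.name: y[:, 3 * m + k * m:3 * m + (k + 1) * m]
                  for k, t_ in enumerate(taxa)},
        layout=layout,
        meta={"taxa": names, "seed": seed,
              "treatment": "with_alga" if alga is not None else "control"},
    )
    times = table_times if table_times is not None else [float(sol.t[-1])]
    table = abundance_table(series, times=times, n_replicates=n_replicates,
                            geometric_sd=geometric_sd, seed=seed)
    return series, table


ABUNDANCE_COLUMNS = [
    "well_id", "layer", "distance_mm", "treatment", "taxon",
    "absolute_density", "relative_abundance", "replicate", "timepoint",
]


def abundance_table(
    series: WellTimeSeries,
    times: list[float],
    n_replicates: int = 3,
    geometric_sd: float = 1.3,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy per-well, per-taxon abundance table with replicate noise.

    Replicates receive multiplicative lognormal noise with the given
    geometric standard deviation (the multiplicative error model used
    for bacterial counts); geometric_sd=1 disables noise.  Layers are
    ranks of the distinct bacterial-well distances from the alga
    (8 mm -> layer 1, 16 mm -> layer 2 in the community preset).
    """
    if series.layout is None:
        raise ValueError("series carries no layout")
    if not series.bacteria:
        raise ValueError("series has no bacterial populations")
    if geometric_sd < 1.0:
        raise ValueError("geometric_sd must be >= 1")
    if geometric_sd > 1.0 and seed is None:
        raise ValueError("seed is required when replicate noise is enabled")
    rng = np.random.default_rng(seed)
    sigma = np.log(geometric_sd)
    try:
        dist = series.layout.distances_from_alga()
    except Exception:
        # no designated algal/centre well: distances from the plate origin
        dist = {w.id: math.hypot(w.x_mm, w.y_mm) for w in series.layout.wells}
    bwells = [w.id for w in series.layout.wells_by_role(WellRole.bacteria)]
    if not bwells:
        bwells = [w.id for w in series.layout.wells]
    layer_of = {d: i + 1 for i, d in
                enumerate(sorted({round(dist[w], 6) for w in bwells}))}
    treatment = series.meta.get("treatment", "with_alga")

    rows = []
    for tp in times:
        for wid in bwells:
            j = series.well_ids.index(wid)
            for rep in range(1, n_replicates + 1):
                noise = {
                    tax: (np.exp(rng.normal(0.0, sigma)) if sigma > 0 else 1.0)
                    for tax in series.bacteria
                }
                absolute = {
                    tax: float(np.interp(tp, series.time, arr[:, j])) * noise[tax]
                    for tax, arr in series.bacteria.items()
                }
                total = sum(absolute.values())
                for tax, dens_val in absolute.items():
                    rows.append({
                        "well_id": wid,
                        "layer": layer_of[round(dist[wid], 6)],
                        "distance_mm": dist[wid],
                        "treatment": treatment,
                        "taxon": tax,
                        "absolute_density": dens_val,
                        "relative_abundance": dens_val / total if total > 0 else 0.0,
                        "replicate": rep,
                        "timepoint": tp,
                    })
    return pd.DataFrame(rows, columns=ABUNDANCE_COLUMNS)


# ---------------------------------------------------------------------------
# Measurement emulation


def sample_cytometry(
    density: float,
    *,
    dilution_factor: float = 35.0,
    bead_stock_density: float = 1e6,
    acquisition_volume_ul: float = 50.0,
    seed: int | None = None,
    noise: bool = True,
) -> CytometrySample:
    """Emulate a bead-calibrated cytometry acquisition of one sample.

    Bead and cell events are Poisson draws around their expectations;
    ``noise=False`` returns the expectations themselves, making the
    density back-calculation exact.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    vol_ml = acquisition_volume_ul * 1e-3
    exp_beads = bead_stock_density * vol_ml
    exp_cells = density / dilution_factor * vol_ml
    if noise:
        if seed is None:
            raise ValueError("seed is required when noise is enabled")
        rng = np.random.default_rng(seed)
        beads = float(rng.poisson(exp_beads))
        cells = float(rng.poisson(exp_cells))
    else:
        beads, cells = exp_beads, exp_cells
    return CytometrySample(bead_events=beads, cell_events=cells,
                           dilution_factor=dilution_factor,
                           bead_stock_density=bead_stock_density)


def to_relative_abundance(
    table: pd.DataFrame,
    sequencing_depth: int = 100_000,
    overdispersion: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Resample relative abundances as 16S-like multinomial counts.

    Within each (well, replicate, timepoint) sample, taxon weights are
    the absolute densities times mean-one lognormal overdispersion
    factors (sigma = ``overdispersion`` in log space), and
    ``sequencing_depth`` reads are drawn multinomially.  Expected
    proportions equal the density proportions.
    """
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    if (overdispersion > 0 or sequencing_depth > 0) and seed is None:
        raise ValueError("seed is required for stochastic resampling")
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["reads"] = 0
    for _, idx in out.groupby(["well_id", "replicate", "timepoint"]).groups.items():
        dens = out.loc[idx, "absolute_density"].to_numpy(dtype=float)
        if dens.sum() <= 0:
            warnings.warn("zero total density in a sample: uniform-zero row",
                          RuntimeWarning, stacklevel=2)
            out.loc[idx, "relative_abundance"] = 0.0
            continue
        w = dens.copy()
        if overdispersion > 0:
            # mean-one lognormal factors keep expectations proportional
            w = w * rng.lognormal(-overdispersion**2 / 2, overdispersion,
                                  size=w.size)
        p = w / w.sum()
        counts = rng.multinomial(sequencing_depth, p)
        out.loc[idx, "reads"] = counts
        out.loc[idx, "relative_abundance"] = counts / sequencing_depth
    return out


# ---------------------------------------------------------------------------
# Taxon presets (calibration, not measurement)


def isolate_presets() -> dict[str, TaxonParams]:
    """The two focal isolates of the distance-response experiment."""
    return {
        "Algoriphagus": TaxonParams(
            name="Algoriphagus", strategy=Strategy.exudate_specialist,
            mu_max_doc=1.0, km_doc=800.0, mu_max_n=0.0,
            yield_doc=1e8, mortality=0.1, initial_density=4e5),
        "Marinobacter": TaxonParams(
            name="Marinobacter", strategy=Strategy.generalist,
            mu_max_doc=0.7, km_doc=400.0, mu_max_n=1.2, km_n=10.0,
            yield_doc=1e8, yield_n=2e8, mortality=0.15, initial_density=4e6),
    }


def community_preset() -> list[TaxonParams]:
    """Eight-taxon community spanning the exudate/inorganic niche axis.

    Strategy assignments follow the direction of each genus's response
    to algal proximity; all rates are calibration constants of the
    generator.
    """
    iso = isolate_presets()
    return [
        replace(iso["Marinobacter"], initial_density=2e6),
        replace(iso["Algoriphagus"], initial_density=2e5),
        TaxonParams("Muricauda", Strategy.exudate_specialist,
                    mu_max_doc=0.6, km_doc=200.0, mortality=0.1,
                    initial_density=5e5),
        TaxonParams("Oceanicaulis", Strategy.exudate_specialist,
                    mu_max_doc=0.5, km_doc=250.0, mortality=0.1,
                    initial_density=5e5),
        TaxonParams("Rhodobacteraceae_unclassified", Strategy.generalist,
                    mu_max_doc=0.2, km_doc=500.0, mu_max_n=0.9, km_n=30.0,
                    mortality=0.1, initial_density=1e6),
        TaxonParams("Sphingomonadaceae_unclassified", Strategy.generalist,
                    mu_max_doc=0.1, km_doc=500.0, mu_max_n=0.8, km_n=25.0,
                    mortality=0.1, initial_density=4e5),
        TaxonParams("Altererythrobacter", Strategy.generalist,
                    mu_max_doc=0.1, km_doc=400.0, mu_max_n=0.7, km_n=15.0,
                    mortality=0.1, initial_density=4e5),
        TaxonParams("Alcanivorax", Strategy.generalist,
                    mu_max_doc=0.05, km_doc=400.0, mu_max_n=0.6, km_n=40.0,
                    mortality=0.1, initial_density=2e5),
    ]
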