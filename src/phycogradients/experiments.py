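"""The four canned experiment pipelines and their run manifests.

Each pipeline mirrors one arm of the porous-microplate study design:

``fig3_growth``
    Algal growth in the seven-well array, reservoir-coupled versus
    sealed, with centre/outer growth-rate contrast.
``fig4_model``
    Normalized phycosphere and plate nutrient profiles side by side,
    with gradient fold-changes and the nitrate depletion time.
``fig5_isolates``
    The two bacterial isolates at three distances from the alga, with
    and without the alga, over 20 days.
``fig6_community``
    The eight-taxon community in two layers for 7 days, ± alga, with
    16S-like relative abundances and layer × treatment ANOVA.

Every stage is seeded; manifests record the config snapshot, seed and
SHA-256 checksums of all outputs, which is sufficient to re-run the
deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import (community_preset, isolate_presets, simulate_cocultures,
                        to_relative_abundance)
from .config import RunConfig
from .phycosphere import (GrowthPhase, fold_decrease, load_species_presets,
                          normalize_profile, nitrate_profile,
                          species_cell_and_medium, steady_state_doc_profile)
from .plate import (AlgalPopulation, PlateLayout, WellRole, build_layout,
                    doc_fold_across_wells, nitrate_depletion_time,
                    simulate_plate)
from .stats import (bh_fdr, fold_change_by_distance, specific_growth_rate,
                    two_way_anova_interaction, welch_t_test)

__all__ = ["RunManifest", "run_experiment", "EXPERIMENTS"]


@dataclass
class RunManifest:
    experiment: str
    seed: int
    config: dict
    versions: dict
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    results: dict = field(default_factory=dict)
    runtime_s: float = 0.0

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=_json_default))
        return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _register(manifest: RunManifest, path: Path) -> None:
    manifest.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, out_dir: Path | None, name: str,
               manifest: RunManifest) -> None:
    if out_dir is None:
        return
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / name
    df.to_csv(path, index=False, float_format="%.10g")
    _register(manifest, path)


def _sealed(layout: PlateLayout) -> PlateLayout:
    edges = [e for e in layout.edges if "RESERVOIR" not in (e.a, e.b)]
    return PlateLayout(layout.wells, edges, layout.reservoir,
                       name=layout.name + "_sealed")


# ---------------------------------------------------------------------------


def run_fig3_growth(config: RunConfig | None = None, seed: int = 0,
                    out_dir: Path | None = None) -> RunManifest:
    """Algal accumulation in the well array versus sealed conditions."""
    cfg = config or RunConfig(preset="hex7", days=20.0)
    manifest = _new_manifest("fig3_growth", seed, cfg)
    t0 = time.perf_counter()
    layout = cfg.build_layout()
    alga = cfg.alga.build() if cfg.alga else AlgalPopulation()
    series = simulate_plate(layout, alga, t_span=(0.0, cfg.days), dt_out=cfg.dt_out)
    sealed = simulate_plate(_sealed(layout), alga, t_span=(0.0, cfg.days),
                            dt_out=cfg.dt_out)

    # triplicate counting noise on the deterministic trajectories
    # (hemocytometer/cytometry-style multiplicative error)
    rng = np.random.default_rng(seed)
    # realized rates around the centre well's onset of nitrate limitation,
    # where the centre/outer contrast is expressed
    window = (4.0, 8.0)
    rates = {}
    for wid in ("centre", "outer1"):
        traj = series.column("algae", wid)
        reps = pd.DataFrame(
            {f"rep{r}": traj * rng.lognormal(0.0, np.log(1.05), traj.size)
             for r in range(1, 4)}, index=series.time)
        rates[wid] = specific_growth_rate(reps, *window)

    outer_final = [series.column("algae", w.id)[-1]
                   for w in layout.wells if w.id != "centre"]
    res = {
        "final_density_centre": float(series.column("algae", "centre")[-1]),
        "final_density_outer_mean": float(np.mean(outer_final)),
        "final_density_sealed": float(np.mean(
            [sealed.column("algae", w.id)[-1] for w in layout.wells])),
        "mu_centre": rates["centre"].mu_mean,
        "mu_centre_sd": rates["centre"].mu_sd,
        "mu_outer": rates["outer1"].mu_mean,
        "mu_outer_sd": rates["outer1"].mu_sd,
        "mu_window_d": list(window),
        "reservoir_gain_fold": float(
            np.mean(outer_final + [series.column("algae", "centre")[-1]])
            / np.mean([sealed.column("algae", w.id)[-1] for w in layout.wells])),
    }
    manifest.results = res
    _write_csv(series.to_frame(), out_dir, "growth_timeseries.csv", manifest)
    _write_csv(sealed.to_frame(), out_dir, "growth_timeseries_sealed.csv", manifest)
    _finish(manifest, out_dir, t0)
    return manifest


def run_fig4_model(config: RunConfig | None = None, seed: int = 0,
                   out_dir: Path | None = None) -> RunManifest:
    """Normalized phycosphere and microplate nutrient profiles."""
    cfg = config or RunConfig(preset="community_layers", days=7.0)
    manifest = _new_manifest("fig4_model", seed, cfg)
    t0 = time.perf_counter()

    presets = load_species_presets()
    phyco_rows, folds = [], {}
    for species in presets["species"]:
        for phase in (GrowthPhase.exponential, GrowthPhase.stationary):
            cell, medium = species_cell_and_medium(species, phase, presets)
            doc = steady_state_doc_profile(cell, medium)
            no3 = nitrate_profile(cell, medium)
            if phase is GrowthPhase.exponential:
                folds[species] = fold_decrease(doc)
            for prof in (normalize_profile(doc),) + (
                    (normalize_profile(no3),) if no3.conc.max() > 0 else ()):
                df = prof.to_frame()
                df["species"] = species
                df["phase"] = phase.value
                phyco_rows.append(df)
    phyco = pd.concat(phyco_rows, ignore_index=True)

    layout = cfg.build_layout()
    alga = cfg.alga.build() if cfg.alga else AlgalPopulation()
    series = simulate_plate(layout, alga, t_span=(0.0, cfg.days), dt_out=0.05)
    dist = layout.distances_from_alga()
    order = sorted(layout.well_ids, key=lambda w: dist[w])
    t_end = float(series.time[-1])
    doc_end = series.at_time(t_end, "doc")
    no3_end = series.at_time(t_end, "nitrate")
    plate = pd.DataFrame({
        "well_id": order,
        "distance_mm": [dist[w] for w in order],
        "doc": [doc_end[series.well_ids.index(w)] for w in order],
        "nitrate": [no3_end[series.well_ids.index(w)] for w in order],
    })
    for col in ("doc", "nitrate"):
        peak = plate[col].max()
        plate[f"{col}_normalized"] = plate[col] / peak if peak > 0 else 0.0
    plate["distance_normalized"] = plate["distance_mm"] / plate["distance_mm"].max()

    manifest.results = {
        "phycosphere_doc_folds": {k: float(v) for k, v in folds.items()},
        "phycosphere_fold_min": float(min(folds.values())),
        "phycosphere_fold_max": float(max(folds.values())),
        "plate_doc_fold": doc_fold_across_wells(series, t=t_end),
        "nitrate_depletion_time_d": nitrate_depletion_time(series, "centre", 0.01),
        "days": cfg.days,
    }
    _write_csv(phyco, out_dir, "phycosphere_profiles.csv", manifest)
    _write_csv(plate, out_dir, "plate_profiles.csv", manifest)
    _finish(manifest, out_dir, t0)
    return manifest


def run_fig5_isolates(config: RunConfig | None = None, seed: int = 0,
                      out_dir: Path | None = None) -> RunManifest:
    """Distance response of the two isolates, ± alga, over 20 days."""
    cfg = config or RunConfig(preset="isolate_rings", days=20.0,
                              alga=None)  # alga defaults set below
    manifest = _new_manifest("fig5_isolates", seed, cfg)
    t0 = time.perf_counter()
    # the isolates experiment starts from a dense pre-acclimated algal culture
    alga = cfg.alga.build() if cfg.alga else AlgalPopulation(initial_density=1e7)
    presets = isolate_presets()
    layout = build_layout("isolate_rings", wall=cfg.wall.build(),
                          reservoir=cfg.reservoir.build())
    rng = np.random.default_rng(seed)
    tables, results = [], {}
    for taxon_name, tax in presets.items():
        inoc = {taxon_name: {f"{arm}{d}": tax.initial_density
                             for arm in "AB" for d in (7, 14, 21)}}
        for treatment, alga_in in (("with_alga", alga), ("control", None)):
            sub_seed = int(rng.integers(2 ** 31 - 1))
            series, table = simulate_cocultures(
                layout, alga_in, [tax], t_span=(0.0, cfg.days),
                inoculum=inoc, seed=sub_seed, table_times=[6.0, cfg.days],
                n_replicates=cfg.n_replicates, geometric_sd=cfg.geometric_sd)
            table["strain"] = taxon_name
            tables.append(table)
            key = f"{taxon_name}_{treatment}"
            resp_late = fold_change_by_distance(
                table, taxon_name, t=cfg.days, seed=sub_seed + 1)
            resp_early = fold_change_by_distance(
                table, taxon_name, t=6.0, seed=sub_seed + 2)
            results[key] = {
                "fold_day_final": resp_late.fold_decrease,
                "trend_rho_final": resp_late.statistic,
                "trend_p_final": resp_late.p_value,
                "fold_day6": resp_early.fold_decrease,
                "trend_rho_day6": resp_early.statistic,
            }
    all_tables = pd.concat(tables, ignore_index=True)
    results["specialist_vs_generalist_fold_ratio"] = (
        results["Algoriphagus_with_alga"]["fold_day_final"]
        / results["Marinobacter_with_alga"]["fold_day_final"])
    manifest.results = results
    _write_csv(all_tables, out_dir, "isolate_abundances.csv", manifest)
    _finish(manifest, out_dir, t0)
    return manifest


def run_fig6_community(config: RunConfig | None = None, seed: int = 0,
                       out_dir: Path | None = None) -> RunManifest:
    """Community structure across layers and treatments after 7 days."""
    cfg = config or RunConfig(preset="community_layers", days=7.0)
    manifest = _new_manifest("fig6_community", seed, cfg)
    t0 = time.perf_counter()
    layout = cfg.build_layout()
    taxa = [t.build() for t in cfg.taxa] if cfg.taxa else community_preset()
    alga = cfg.alga.build() if cfg.alga else AlgalPopulation()
    rng = np.random.default_rng(seed)
    tables = []
    for treatment, alga_in in (("with_alga", alga), ("control", None)):
        sub_seed = int(rng.integers(2 ** 31 - 1))
        _, table = simulate_cocultures(
            layout, alga_in, taxa, t_span=(0.0, cfg.days), seed=sub_seed,
            table_times=[cfg.days], n_replicates=cfg.n_replicates,
            geometric_sd=cfg.geometric_sd)
        table = to_relative_abundance(table, sequencing_depth=100_000,
                                      overdispersion=0.2, seed=sub_seed + 1)
        tables.append(table)
    table = pd.concat(tables, ignore_index=True)

    anova_rows = []
    for taxon in sorted({t.name for t in taxa}):
        sub = table[table["taxon"] == taxon].copy()
        sub["log_density"] = np.log10(np.maximum(sub["absolute_density"], 1e3))
        terms = two_way_anova_interaction(sub, "log_density",
                                          factors=("layer", "treatment"))
        welch = welch_t_test(
            sub.loc[sub["treatment"] == "with_alga", "log_density"],
            sub.loc[sub["treatment"] == "control", "log_density"])
        anova_rows.append({
            "taxon": taxon,
            "interaction_F": terms["layer:treatment"]["F"],
            "interaction_p": terms["layer:treatment"]["p"],
            "layer_p": terms["layer"]["p"],
            "treatment_p": terms["treatment"]["p"],
            "welch_treatment_p": welch.p_two_tailed,
        })
    anova = pd.DataFrame(anova_rows)
    anova["interaction_p_bh"] = bh_fdr(anova["interaction_p"])
    manifest.results = {
        "n_samples": int(len(table) / len(taxa)),
        "n_interaction_significant": int((anova["interaction_p"] < 0.05).sum()),
        "interaction_p": dict(zip(anova["taxon"], anova["interaction_p"])),
    }
    _write_csv(table, out_dir, "community_abundances.csv", manifest)
    _write_csv(anova, out_dir, "community_anova.csv", manifest)
    _finish(manifest, out_dir, t0)
    return manifest


# ---------------------------------------------------------------------------

EXPERIMENTS = {
    "fig3_growth": run_fig3_growth,
    "fig4_model": run_fig4_model,
    "fig5_isolates": run_fig5_isolates,
    "fig6_community": run_fig6_community,
}


def _new_manifest(name: str, seed: int, cfg: RunConfig) -> RunManifest:
    return RunManifest(
        experiment=name, seed=seed,
        config=cfg.model_dump(mode="json"),
        versions={"phycogradients": __version__,
                  "numpy": np.__version__, "pandas": pd.__version__},
    )


def _finish(manifest: RunManifest, out_dir: Path | None, t0: float) -> None:
    manifest.runtime_s = round(time.perf_counter() - t0, 3)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest.write(out_dir)


def run_experiment(name: str, config: RunConfig | None = None, seed: int = 0,
                   out_dir: str | Path | None = None) -> RunManifest:
    """Run one named experiment pipeline and return its manifest."""
    if name not in EXPERIMENTS:
        raise KeyError(f"unknown experiment {name!r}; "
                       f"choose from {sorted(EXPERIMENTS)}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    return EXPERIMENTS[name](config, seed, out)
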