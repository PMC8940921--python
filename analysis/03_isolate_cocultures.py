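#!/usr/bin/env python
"""Distance response of the two bacterial isolates co-cultured with the alga.

Simulates the exudate specialist (Algoriphagus-like) and the generalist
(Marinobacter-like) at 7, 14 and 21 mm from the algal well, with and
without the alga, for 20 days.  Findings: late in the run both strains
decrease with distance, the specialist ~100-fold versus the generalist's
~5-fold; the generalist dominates the outermost well; and early in the
control plates the generalist is more abundant toward the outside,
tracking the inorganic-nutrient gradient.
"""

from pathlib import Path

from phycogradients.experiments import run_fig5_isolates

OUT = Path(__file__).resolve().parents[1] / "results" / "isolates"


def main() -> None:
    manifest = run_fig5_isolates(seed=0, out_dir=OUT)
    r = manifest.results
    for key in ("Algoriphagus_with_alga", "Marinobacter_with_alga",
                "Marinobacter_control"):
        v = r[key]
        print(f"{key:26s} final fold {v['fold_day_final']:7.1f} "
              f"(rho {v['trend_rho_final']:+.2f}, p {v['trend_p_final']:.3f}); "
              f"day-6 fold {v['fold_day6']:.2f}")
    print(f"specialist/generalist fold ratio: "
          f"{r['specialist_vs_generalist_fold_ratio']:.1f}")


if __name__ == "__main__":
    main()
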