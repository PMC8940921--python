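#!/usr/bin/env python
"""Layer x treatment structure of the synthetic eight-taxon community.

Runs the two-layer community design (7 days, ± alga), converts the
generated densities to 16S-like relative abundances, and tests each
genus for a layer x treatment interaction with the balanced two-way
ANOVA (BH-adjusted).  Finding: exudate-leaning taxa gain with the alga
(most strongly in layer 1) while inorganic-leaning taxa lose, producing
interaction signals for the most distance-responsive genera.
"""

from pathlib import Path

import pandas as pd

from phycogradients.experiments import run_fig6_community

OUT = Path(__file__).resolve().parents[1] / "results" / "community"


def main() -> None:
    manifest = run_fig6_community(seed=17, out_dir=OUT)
    anova = pd.read_csv(OUT / "community_anova.csv")
    print(anova.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
    print(f"{manifest.results['n_interaction_significant']} taxa with "
          "layer x treatment interaction at p < 0.05 "
          f"({manifest.results['n_samples']} samples)")


if __name__ == "__main__":
    main()
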