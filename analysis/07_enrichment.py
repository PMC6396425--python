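"""eQTL and GO enrichment contrasts on planted regulatory fixtures.

Recovers the planted proximal/distal eQTL odds ratios (20 and 4) from
distance-stratified 2x2 tables, and compares SNP-to-gene mapping
strategies on GO-term enrichment: the planted term is found under the
interaction strategy and label-permuted nulls stay clean.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ldhic.experiments import go_detection_sweep, or_recovery_sweep

OUT = Path("results")
N_SEEDS = 20

ors = or_recovery_sweep(n_seeds=N_SEEDS, base_seed=1)
ors.to_csv(OUT / "eqtl_or_recovery.tsv", sep="\t", index=False,
           float_format="%.6g")
for stratum in ("proximal", "distal"):
    g = ors[ors["stratum"] == stratum]
    cover = np.mean((g["ci_low"] <= g["planted"])
                    & (g["planted"] <= g["ci_high"]))
    print(f"{stratum}: planted OR {g['planted'].iloc[0]:.0f}, recovered "
          f"mean OR {g['or'].mean():.1f} (log OR {g['log_or'].mean():.2f}), "
          f"95% CI coverage {100 * cover:.0f}%")

go = go_detection_sweep(n_seeds=N_SEEDS, base_seed=1)
go.to_csv(OUT / "go_detection.tsv", sep="\t", index=False,
          float_format="%.6g")
print(f"planted GO term at q<0.05 in "
      f"{100 * np.mean(go['q_planted'] < 0.05):.0f}% of seeds; "
      f"label-permuted nulls average "
      f"{go['n_null_discoveries'].mean():.2f} discoveries")
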