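#!/usr/bin/env python
"""Per-feature significance screening for both group comparisons.

Each texture feature and clinical covariate is tested between PA and EH,
and between PA+EH and controls, with Welch's t, the two-sample KS test
and the Mann-Whitney U test.  A feature counts as significant only when
all three agree at alpha = 0.05.  Writes the raw p-value table and a
rendered report with blank cells for non-significant entries.
"""

import argparse
from pathlib import Path

import pandas as pd

from carotexture.stats import (
    COMPARISONS,
    count_significant,
    feature_significance,
    results_frame,
    significance_report,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--clinical", type=Path, default=Path("results/clinical.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    clinical = pd.read_csv(args.clinical)
    clin_cols = [c for c in clinical.columns if c not in ("patient_id", "group_label")]
    frames = []
    for comp in COMPARISONS:
        tex = feature_significance(table, comp, args.alpha)
        cols = ([c for c in clin_cols if c not in ("aldosterone", "renin", "arr")]
                if comp == "HTN_vs_C" else clin_cols)
        clin = feature_significance(clinical, comp, args.alpha, feature_cols=cols)
        frames.append(results_frame(tex + clin))
        significance_report(tex, clin, args.alpha).to_csv(
            args.outdir / f"stats_report_{comp}.csv", index=False)
        print(f"{comp}: {count_significant(tex, args.alpha)} of {len(tex)} texture "
              f"features significant by all three tests at alpha={args.alpha}")
    pd.concat(frames).to_csv(args.outdir / "stats.csv", index=False)


if __name__ == "__main__":
    main()
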