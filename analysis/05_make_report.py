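#!/usr/bin/env python
"""Assemble the run summary from the tables written by steps 02-04."""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--resultsdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    d = args.resultsdir

    stats = pd.read_csv(d / "stats.csv")
    acc = pd.read_csv(d / "accuracy.csv", keep_default_na=False)
    lines = ["# Synthetic cohort analysis summary", ""]
    lines.append("## Feature screening (significant by all three tests, alpha=0.05)")
    tex = stats[stats.feature.str.match(r"mu|sigma|H_|W")]
    for comp, grp in tex.groupby("comparison"):
        lines.append(f"- {comp}: {int(grp.significant_all.sum())} of {len(grp)} texture features")
    lines.append("")
    lines.append("## Per-patient leave-one-out accuracy")
    lines.append("")
    lines.append(acc.to_markdown(index=False))
    out = d / "report.md"
    out.write_text("\n".join(lines) + "\n")
    print(f"wrote {out}")
    print("\n".join(lines))


if __name__ == "__main__":
    main()
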