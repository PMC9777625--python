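#!/usr/bin/env python
"""Patient-level leave-one-out classification for all feature subsets.

Evaluates gradient-boosted classifiers on both tasks (PA vs EH and
hypertensives vs controls) for the four feature subsets — clinical,
clinical+IMT, texture, and the aldosterone panel (PA vs EH only) —
with per-patient probability aggregation.  Writes the accuracy grid,
per-patient predictions, ROC coordinates and ROC plots.
"""

import argparse
from pathlib import Path

import pandas as pd

from carotexture.classify import (
    TASKS,
    ModelConfig,
    TaskSpec,
    accuracy_table,
    loo_evaluate,
)
from carotexture.pipeline import _plot_rocs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", type=Path, default=Path("results/features.csv"))
    ap.add_argument("--clinical", type=Path, default=Path("results/clinical.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    clinical = pd.read_csv(args.clinical)
    results = {}
    for task in TASKS:
        for subset in ("clinical", "clinical_imt", "texture", "aldo"):
            if subset == "aldo" and task == "HTN_vs_C":
                continue
            spec = TaskSpec(task, subset)
            res = loo_evaluate(table, clinical, spec, ModelConfig(), seed=args.seed)
            results[(task, subset)] = res
            res.per_patient.to_csv(args.outdir / f"loo_{task}_{subset}.csv", index=False)
            pd.DataFrame({"fpr": res.fpr, "tpr": res.tpr}).to_csv(
                args.outdir / f"roc_{task}_{subset}.csv", index=False)
            print(f"{task:10s} {subset:13s} accuracy={res.accuracy:.2f} auc={res.auc:.2f}")

    acc = accuracy_table(results)
    acc.to_csv(args.outdir / "accuracy.csv", index=False)
    _plot_rocs(results, args.outdir)
    print("\n" + acc.to_markdown(index=False))


if __name__ == "__main__":
    main()
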