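"""Fit logistic models on the selected features and evaluate them over
10 shuffled stratified 0.7/0.3 splits per side.

Reports AUC, specificity, sensitivity, PPV, NPV, precision, recall and
F-score (mean +/- SD over repetitions) and writes the full model
report JSON plus ROC and radiomics-score plot data for the first
repetition.

    python analysis/05_fit_and_evaluate.py --features results/features.csv --seed 1
"""

import argparse
import json
from pathlib import Path

from hipporad.io import read_feature_table
from hipporad.model_eval import (METRICS, RepetitionPlan, binarize_labels,
                                 fit_logistic, report_to_json, roc_points,
                                 run_repetitions, score_plot)
from hipporad.selection import impute_abnormal, split_train_test, standardize


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path,
                    default=Path("results/features.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--reps", type=int, default=10)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_feature_table(args.features)
    for side in ("left", "right"):
        sel_path = args.out_dir / f"selection_{side}.json"
        selected = json.loads(sel_path.read_text())["final_features"]
        if not selected:
            print(f"{side}: no selected features, skipping")
            continue
        side_tab = table[table["side"] == side].reset_index(drop=True)
        side_tab, _ = impute_abnormal(side_tab)
        plan = RepetitionPlan(n_repetitions=args.reps, base_seed=args.seed)
        report = run_repetitions(side_tab, selected, plan)
        report_to_json(report, args.out_dir / f"model_report_{side}.json")
        agg = report["aggregate"]
        print(f"{side} model ({len(selected)} features, "
              f"{args.reps} repetitions):")
        for m in METRICS:
            print(f"    test {m:<12} {agg[f'test_{m}_mean']:.3f} "
                  f"+/- {agg[f'test_{m}_sd']:.3f}")
        print(f"    train AUC {agg['train_auc_mean']:.3f} "
              f"(gap {agg['auc_gap_mean']:+.3f})")

        # plot data from the first repetition's split
        train, test = split_train_test(side_tab, plan.train_fraction,
                                       plan.seeds()[0])
        train, test, _ = standardize(train, test, selected)
        feats = [f for f in selected if f in train.columns]
        model = fit_logistic(train[feats], binarize_labels(train["label"]))
        y_te = binarize_labels(test["label"])
        scores = model.score(test[feats])
        roc_points(scores, y_te).to_csv(
            args.out_dir / f"roc_test_{side}.csv", index=False)
        score_plot(scores, y_te).to_csv(
            args.out_dir / f"radiomics_scores_{side}.csv", index=False)
        print(f"  -> model_report_{side}.json, roc_test_{side}.csv, "
              f"radiomics_scores_{side}.csv")


if __name__ == "__main__":
    main()
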