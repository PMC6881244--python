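"""Run the three-stage feature-selection cascade per hippocampus side.

Imputation, stratified 0.7/0.3 split and standardization happen on the
training rows; the cascade (univariate tests -> Spearman redundancy
filter -> cross-validated LASSO) yields the side's selected features.
Writes the selection audit JSON plus coefficient-path and CV-curve
CSVs (the coefficients-lambda and error-lambda plot data).

    python analysis/04_select_features.py --features results/features.csv --seed 1
"""

import argparse
from pathlib import Path

import pandas as pd

from hipporad.catalog import default_catalog
from hipporad.io import read_feature_table
from hipporad.selection import (SelectionConfig, impute_abnormal,
                                run_selection, split_train_test, standardize)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path,
                    default=Path("results/features.csv"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    table = read_feature_table(args.features)
    names = [c for c in default_catalog().names if c in table.columns]
    for side in ("left", "right"):
        side_tab = table[table["side"] == side].reset_index(drop=True)
        cfg = SelectionConfig(seed=args.seed)
        train, test = split_train_test(side_tab, cfg.train_fraction,
                                       seed=args.seed)
        train, _ = impute_abnormal(train, names)
        cols = [c for c in names if c in train.columns]
        train, test, _ = standardize(train, test, cols)
        cols = [c for c in cols if c in train.columns]
        result = run_selection(train, cols, cfg)
        out = args.out_dir / f"selection_{side}.json"
        result.to_json(out)
        pd.DataFrame(result.coef_path,
                     columns=result.correlation_survivors).assign(
            lam=result.lambda_grid).to_csv(
            args.out_dir / f"coef_path_{side}.csv", index=False)
        pd.DataFrame({"lam": result.lambda_grid,
                      "cv_deviance": result.cv_error}).to_csv(
            args.out_dir / f"cv_curve_{side}.csv", index=False)
        counts = result.stage_counts()
        print(f"{side}: 385 -> {counts['univariate']} (univariate) -> "
              f"{counts['correlation']} (correlation) -> "
              f"{counts['lasso']} (LASSO, lambda={result.chosen_lambda:.4g})")
        for name, coef in result.coefficients.items():
            print(f"    {coef:+.3f}  {name}")
        print(f"  -> {out}")


if __name__ == "__main__":
    main()
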