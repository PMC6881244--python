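"""End-to-end orchestration: simulate -> extract -> select -> evaluate.

The pipeline runs the five-step chain per hippocampus side (left and
right models are fully independent fits), writing feature tables,
selection audit trails and model reports into a run directory.  A
single master seed deterministically derives every stage seed, so the
whole run — and any stage rerun in isolation — is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from hipporad.catalog import FeatureCatalog, default_catalog
from hipporad.cohort_stats import demographics_table
from hipporad.features import extract_all
from hipporad.io import (read_manifest, read_mask, read_volume,
                         write_feature_table)
from hipporad.model_eval import RepetitionPlan, report_to_json, run_repetitions
from hipporad.selection import (SelectionConfig, impute_abnormal,
                                run_selection, split_train_test, standardize)
from hipporad.synthetic import SyntheticCohortSpec, generate_cohort

log = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from the master seed."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31 - 1)


def extract_cohort(manifest: pd.DataFrame,
                   catalog: FeatureCatalog | None = None) -> pd.DataFrame:
    """Extract the full catalog for every (subject, side) pair.

    Returns a table with one row per subject and side, the side
    encoded in a column so left/right models are built from filtered
    views.
    """
    if catalog is None:
        catalog = default_catalog()
    rows = []
    for _, rec in manifest.iterrows():
        volume = read_volume(rec["volume_path"])
        for side in ("left", "right"):
            mask = read_mask(rec[f"mask_{side}_path"], volume, side=side)
            vec = extract_all(volume, mask, catalog)
            row = {"subject_id": rec["subject_id"], "label": rec["label"],
                   "side": side}
            row.update(vec.to_dict())
            rows.append(row)
    table = pd.DataFrame(rows)
    # keep catalog order
    return table[["subject_id", "label", "side"] + catalog.names]


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    sides: tuple = ("left", "right")
    master_seed: int = 0
    cohort_spec: SyntheticCohortSpec | None = None
    manifest_path: str | None = None       # use an existing cohort instead
    selection: SelectionConfig = dataclasses.field(
        default_factory=SelectionConfig)
    n_repetitions: int = 10


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and return a per-side summary.

    Artifacts written under ``config.out_dir``: the feature table,
    demographics table, per-side selection JSON and model report, and
    a run summary embedding the config and catalog version.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = default_catalog()

    if config.manifest_path is not None:
        manifest = read_manifest(config.manifest_path)
    else:
        spec = config.cohort_spec or SyntheticCohortSpec(
            seed=stage_seed(config.master_seed, "simulate"))
        manifest = generate_cohort(spec, out / "cohort")
    log.info("cohort: %d subjects", len(manifest))

    demo = demographics_table(manifest)
    demo.to_csv(out / "demographics.csv", index=False)

    table = extract_cohort(manifest, catalog)
    write_feature_table(table, out / "features.csv")
    log.info("extracted %d features x %d rows", len(catalog), len(table))

    summary: dict = {"sides": {}, "n_features": len(catalog),
                     "catalog_version": catalog.config["version"],
                     "master_seed": config.master_seed}
    for side in config.sides:
        side_tab = table[table["side"] == side].reset_index(drop=True)
        sel_cfg = dataclasses.replace(
            config.selection, seed=stage_seed(config.master_seed,
                                              f"select-{side}"))
        train, test = split_train_test(side_tab, sel_cfg.train_fraction,
                                       seed=stage_seed(config.master_seed,
                                                       f"split-{side}"))
        train, _ = impute_abnormal(train, catalog.names)
        feat_cols = [c for c in catalog.names if c in train.columns]
        train, test, _ = standardize(train, test, feat_cols)
        feat_cols = [c for c in feat_cols if c in train.columns]
        result = run_selection(train, feat_cols, sel_cfg)
        result.to_json(out / f"selection_{side}.json")
        features = result.final_features
        if not features:
            summary["sides"][side] = {"selected": [], "report": None}
            continue
        full_side, _ = impute_abnormal(side_tab.copy(), catalog.names)
        plan = RepetitionPlan(
            n_repetitions=config.n_repetitions,
            base_seed=stage_seed(config.master_seed, f"reps-{side}"))
        report = run_repetitions(full_side, features, plan)
        report["selection_counts"] = result.stage_counts()
        report_to_json(report, out / f"model_report_{side}.json")
        summary["sides"][side] = {
            "selected": features,
            "cascade": [len(catalog)] + list(result.stage_counts().values()),
            "test_auc_mean": report["aggregate"]["test_auc_mean"],
            "train_auc_mean": report["aggregate"]["train_auc_mean"],
        }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=1))
    return summary
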