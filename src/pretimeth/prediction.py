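"""Apply stored per-locus models to new beta matrices.

This is the array-expansion step: a 450K-style matrix provides the
feature-locus betas, and each model locus gets a predicted beta per
sample.  A prediction is missing whenever a required feature locus is
absent from the input platform or its value is missing in that sample
(missingness compounds with the number of features a model uses);
every missing prediction carries a machine-readable reason.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arrays_io import MethylationMatrix
from .locus_models import CATEGORIES, CVMetrics, LocusModel, compute_metrics

REASON_FEATURE_ABSENT = "feature_absent_from_platform"
REASON_FEATURE_MISSING = "feature_value_missing"
REASON_MODEL_FLAGGED = "model_flagged"

RESULT_COLUMNS = ["model_probe_id", "sample_id", "predicted_beta", "category", "reason"]


def predict_matrix(
    models: dict[str, LocusModel], input_matrix: MethylationMatrix
) -> pd.DataFrame:
    """Predict every model locus in every input sample.

    Returns a long-form table with columns ``model_probe_id``,
    ``sample_id``, ``predicted_beta`` (NaN when not predictable),
    ``category`` and ``reason`` (empty when predicted).  Deterministic:
    rows ordered by probe then sample.
    """
    if not models:
        raise ValueError("empty model table")
    samples = input_matrix.sample_ids
    n_samples = len(samples)
    present = set(input_matrix.data.index)
    frames = []
    for mp in sorted(models):
        m = models[mp]
        pred = np.full(n_samples, np.nan)
        reason = np.array([""] * n_samples, dtype=object)
        if m.flagged:
            reason[:] = REASON_MODEL_FLAGGED
        else:
            absent = [f for f in m.feature_probe_ids if f not in present]
            if absent:
                reason[:] = REASON_FEATURE_ABSENT
            else:
                X = input_matrix.data.loc[m.feature_probe_ids].to_numpy(dtype=float).T
                ok = ~np.isnan(X).any(axis=1)
                if ok.any():
                    pred[ok] = m.predict(X[ok])
                reason[~ok] = REASON_FEATURE_MISSING
        frames.append(
            pd.DataFrame(
                {
                    "model_probe_id": mp,
                    "sample_id": samples,
                    "predicted_beta": pred,
                    "category": m.category,
                    "reason": reason,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)[RESULT_COLUMNS]


def filter_by_category(
    results: pd.DataFrame, allowed: set[str] | list[str]
) -> pd.DataFrame:
    """Keep predictions whose generating model's accuracy tier is allowed."""
    allowed = set(allowed)
    if not allowed:
        raise ValueError("empty allowed category set")
    unknown = allowed - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    return results[results["category"].isin(allowed)].reset_index(drop=True)


def category_counts(results: pd.DataFrame) -> pd.Series:
    """Number of distinct model loci per category in a result table."""
    return results.groupby("category")["model_probe_id"].nunique()


def results_to_matrix(results: pd.DataFrame) -> MethylationMatrix:
    """Pivot a prediction table to a probes × samples beta matrix (NaN kept)."""
    wide = results.pivot(
        index="model_probe_id", columns="sample_id", values="predicted_beta"
    )
    wide.index.name = "probe_id"
    wide.columns.name = None
    return MethylationMatrix(wide)


def predictable_locus_count(results: pd.DataFrame) -> int:
    """Model loci with at least one non-missing prediction."""
    ok = results[~results["predicted_beta"].isna()]
    return int(ok["model_probe_id"].nunique())


def predictable_cell_count(results: pd.DataFrame) -> int:
    """Non-missing (locus, sample) predictions."""
    return int((~results["predicted_beta"].isna()).sum())


def evaluate_predictions(
    results: pd.DataFrame,
    reference: MethylationMatrix,
    group_by_category: bool = False,
) -> dict[str, CVMetrics]:
    """Score predictions against reference measurements.

    Pairs each non-missing prediction with the reference beta for the
    same (probe, sample); pairs with a missing reference value are
    dropped.  Returns ``{"all": metrics}`` or one entry per category.
    """
    merged = results[~results["predicted_beta"].isna()].copy()
    if merged.empty:
        raise ValueError("no non-missing predictions to evaluate")
    ref = reference.data
    in_ref = merged["model_probe_id"].isin(ref.index) & merged["sample_id"].isin(ref.columns)
    merged = merged[in_ref]
    if merged.empty:
        raise ValueError("zero overlapping (probe, sample) pairs with the reference")
    obs = ref.to_numpy(dtype=float)[
        ref.index.get_indexer(merged["model_probe_id"]),
        ref.columns.get_indexer(merged["sample_id"]),
    ]
    merged["observed_beta"] = obs
    merged = merged[~merged["observed_beta"].isna()]
    if merged.empty:
        raise ValueError("zero overlapping non-missing pairs with the reference")
    out: dict[str, CVMetrics] = {}
    if group_by_category:
        for cat, sub in merged.groupby("category"):
            out[str(cat)] = compute_metrics(
                sub["predicted_beta"].to_numpy(), sub["observed_beta"].to_numpy()
            )
    else:
        out["all"] = compute_metrics(
            merged["predicted_beta"].to_numpy(), merged["observed_beta"].to_numpy()
        )
    return out
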