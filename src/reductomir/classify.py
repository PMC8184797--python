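"""Venn partition of two DE contrasts and cross-model inverse co-regulation.

The pooled (Tg vs NTg) and dose (TgH vs TgL) contrasts partition every tested
feature into transgene-only, transgene-dose, dose-only or not-significant
subsets. Comparing a transgenic overexpression model against a knockout model
classifies each shared feature as inversely co-regulated (opposite fold-change
signs, significant in both), inversely trending (opposite signs without the
dual significance requirement), concordant, or absent from one model.

By default raw p-values at 0.05 enter the Venn, matching the figure-level
definition of the subsets; ``use_adjusted`` switches to the Bonferroni Q.
Features absent from one contrast are imputed p = 1 rather than dropped so
the partition stays exhaustive.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["venn_classify", "subset_counts", "concordance"]

VENN_SUBSETS = ("transgene_only", "transgene_dose", "dose_only", "not_significant")
CONCORDANCE_STATUSES = (
    "inversely_coregulated",
    "inversely_trending",
    "concordant",
    "absent",
)


def _p_column(use_adjusted: bool) -> str:
    return "qvalue_bonferroni" if use_adjusted else "pvalue"


def _prep(de: pd.DataFrame, use_adjusted: bool, which: str) -> pd.DataFrame:
    if de["feature_id"].duplicated().any():
        dups = de.loc[de["feature_id"].duplicated(), "feature_id"]
        raise ValueError(f"duplicated features in {which} results: {list(dups[:5])}")
    col = _p_column(use_adjusted)
    out = de[["feature_id", col, "log2FC"]].rename(
        columns={col: f"p_{which}", "log2FC": f"lfc_{which}"}
    )
    return out


def venn_classify(
    pooled: pd.DataFrame,
    dose: pd.DataFrame,
    p_threshold: float = 0.05,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Assign each feature to a Venn subset from the two contrasts.

    Subsets are mutually exclusive and exhaustive over the union of the two
    feature universes: significant only in the pooled contrast ->
    transgene_only; in both -> transgene_dose; only in the dose contrast ->
    dose_only; otherwise not_significant. Untested features (NaN p) count as
    p = 1.
    """
    merged = pd.merge(
        _prep(pooled, use_adjusted, "pooled"),
        _prep(dose, use_adjusted, "dose"),
        on="feature_id",
        how="outer",
    )
    for which in ("pooled", "dose"):
        merged[f"p_{which}"] = merged[f"p_{which}"].fillna(1.0)
        merged[f"lfc_{which}"] = merged[f"lfc_{which}"].fillna(0.0)
    sig_p = merged["p_pooled"] < p_threshold
    sig_d = merged["p_dose"] < p_threshold
    subset = np.select(
        [sig_p & sig_d, sig_p, sig_d],
        ["transgene_dose", "transgene_only", "dose_only"],
        default="not_significant",
    )
    merged["direction_pooled"] = np.sign(merged["lfc_pooled"]).astype(int)
    merged["direction_dose"] = np.sign(merged["lfc_dose"]).astype(int)
    merged["subset"] = subset
    return merged.sort_values("feature_id").reset_index(drop=True)


def subset_counts(venn: pd.DataFrame) -> pd.Series:
    """Counts per Venn subset, zero-filled over all four subsets."""
    counts = venn["subset"].value_counts()
    return pd.Series({s: int(counts.get(s, 0)) for s in VENN_SUBSETS}, name="n_features")


def concordance(
    model_a: pd.DataFrame,
    model_b: pd.DataFrame,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Cross-model status for every feature in either DE table.

    inversely_coregulated: opposite LFC signs AND p < threshold in both
    models; inversely_trending: opposite signs without that requirement;
    concordant: same (or zero) signs; absent: missing from one model. The
    status is symmetric in the two models.
    """
    a = _prep(model_a, use_adjusted=False, which="A")
    b = _prep(model_b, use_adjusted=False, which="B")
    merged = pd.merge(a, b, on="feature_id", how="outer", indicator=True)
    opposite = (merged["lfc_A"] * merged["lfc_B"]) < 0
    both_sig = (merged["p_A"] < p_threshold) & (merged["p_B"] < p_threshold)
    status = np.select(
        [
            merged["_merge"] != "both",
            opposite & both_sig,
            opposite,
        ],
        ["absent", "inversely_coregulated", "inversely_trending"],
        default="concordant",
    )
    merged["status"] = status
    merged = merged.drop(columns="_merge").rename(
        columns={
            "lfc_A": "lfc_model_A",
            "p_A": "p_model_A",
            "lfc_B": "lfc_model_B",
            "p_B": "p_model_B",
        }
    )
    return merged.sort_values("feature_id").reset_index(drop=True)
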