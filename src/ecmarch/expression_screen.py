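"""Transcriptome fold-change screen and cytokine-array normalization.

The screen mirrors a knockout-vs-parental differential comparison on
gene-level tables: non-coding biotypes (lincRNA, miRNA, 3' overlapping
ncRNA, processed pseudogene, antisense) are removed so only protein-
coding transcripts remain; genes are called up if fold change exceeds
1.5 and down if below 0.5, at Benjamini-Hochberg FDR-adjusted p < 0.05
(all inequalities strict); and up/down calls from two cell lines are
intersected to find shared response genes.

Cytokine-array spots come in duplicate: the analyte level is the duplicate
mean minus the membrane background, normalized to the reference spots and
floored at zero (background exceeding signal is noise).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EXCLUDED_BIOTYPES",
    "filter_protein_coding",
    "bh_adjust",
    "classify_fold_changes",
    "shared_gene_sets",
    "normalize_cytokine_spots",
    "ScreenResult",
]

#: Biotypes removed before the fold-change screen.
EXCLUDED_BIOTYPES = frozenset(
    ["lincRNA", "miRNA", "3prime_overlapping_ncRNA", "processed_pseudogene", "antisense"]
)

KNOWN_BIOTYPES = EXCLUDED_BIOTYPES | {"protein_coding"}

REQUIRED_COLUMNS = ("gene_id", "biotype", "fold_change")


class ScreenResult:
    """Classified screen: a table with a ``screen_class`` column plus the
    derived up/down gene-id sets.

    Classes are exhaustive and mutually exclusive:
    ``up`` / ``down`` (significant calls), ``not_significant`` (fold
    change beyond a threshold but adjusted p >= alpha), ``unchanged``
    (fold change between the thresholds), ``excluded_biotype``.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table

    @property
    def up_genes(self) -> set[str]:
        return set(self.table.loc[self.table["screen_class"] == "up", "gene_id"])

    @property
    def down_genes(self) -> set[str]:
        return set(self.table.loc[self.table["screen_class"] == "down", "gene_id"])

    def class_counts(self) -> dict[str, int]:
        return self.table["screen_class"].value_counts().to_dict()


def _check_columns(table: pd.DataFrame, *extra: str) -> None:
    missing = [c for c in (*REQUIRED_COLUMNS, *extra) if c not in table.columns]
    if missing:
        raise ValueError(f"expression table missing column(s): {missing}")


def filter_protein_coding(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the excluded non-coding biotypes, keeping protein-coding rows.

    Unknown biotypes (e.g. "TEC") are retained with a warning rather than
    silently discarded.
    """
    if "biotype" not in table.columns:
        raise ValueError("expression table missing column(s): ['biotype']")
    unknown = set(table["biotype"]) - KNOWN_BIOTYPES
    if unknown:
        warnings.warn(f"retaining rows with unrecognized biotype(s): {sorted(unknown)}")
    return table[~table["biotype"].isin(EXCLUDED_BIOTYPES)].reset_index(drop=True)


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_fold_changes(
    table: pd.DataFrame,
    up_threshold: float = 1.5,
    down_threshold: float = 0.5,
    alpha: float = 0.05,
) -> ScreenResult:
    """Classify each gene by fold change and FDR-adjusted significance.

    ``up``: fold change strictly above ``up_threshold`` and adjusted
    p strictly below ``alpha``; ``down`` symmetric below
    ``down_threshold``.  If no ``p_adj`` column is present it is computed
    from ``p_raw`` by Benjamini-Hochberg.  Excluded biotypes keep the
    class ``excluded_biotype``; the screen itself runs on the retained rows.
    """
    _check_columns(table)
    out = table.copy().reset_index(drop=True)
    if "p_adj" not in out.columns:
        if "p_raw" not in out.columns:
            raise ValueError("expression table needs a p_adj or p_raw column")
        retained_mask = ~out["biotype"].isin(EXCLUDED_BIOTYPES)
        out["p_adj"] = np.nan
        out.loc[retained_mask, "p_adj"] = bh_adjust(out.loc[retained_mask, "p_raw"])
    cls = []
    for _, row in out.iterrows():
        if row["biotype"] in EXCLUDED_BIOTYPES:
            cls.append("excluded_biotype")
        elif row["fold_change"] > up_threshold:
            cls.append("up" if row["p_adj"] < alpha else "not_significant")
        elif row["fold_change"] < down_threshold:
            cls.append("down" if row["p_adj"] < alpha else "not_significant")
        else:
            cls.append("unchanged")
    out["screen_class"] = cls
    return ScreenResult(out)


def shared_gene_sets(result_a: ScreenResult, result_b: ScreenResult) -> dict:
    """Intersect up-with-up and down-with-down calls of two screens."""
    shared_up = result_a.up_genes & result_b.up_genes
    shared_down = result_a.down_genes & result_b.down_genes
    return {
        "shared_up": sorted(shared_up),
        "shared_down": sorted(shared_down),
        "n_shared_up": len(shared_up),
        "n_shared_down": len(shared_down),
    }


def normalize_cytokine_spots(
    duplicates: tuple[float, float], background: float, reference: float
) -> float:
    """Duplicate-spot cytokine level: ``(mean(duplicates) - background) /
    reference``, floored at 0."""
    if reference <= 0:
        raise ValueError("reference spot intensity must be positive")
    level = (float(np.mean(duplicates)) - background) / reference
    if level < 0:
        warnings.warn("background exceeds signal; normalized level floored at 0")
        return 0.0
    return level
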