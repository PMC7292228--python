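"""Driver-TF prediction by integrating expression and chromatin-accessibility
changes.

Each transcription factor carries a log2 expression fold change (vs the
non-targeting control) and a motif-displacement differential for four cell
lines: two drug-resistant xenograft-derived lines ("XE") and two
knockdown-only lines ("sh").  A weight gamma balances the two groups so
neither dominates; per-modality overall scores are the gamma-weighted sums,
their product is the Combined-Score, two sign-adjustment rules rescue TFs
that act through only one modality, and the final candidates are the top
TFs by adjusted Combined-Score plus the top TFs by ATAC-Score.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "de_filter",
    "gamma",
    "overall_score",
    "combined_score",
    "score_table",
    "adjust_scores",
    "select_candidates",
    "rank_tf_table",
]

XE_RNA = ["rna_lfc_xe1", "rna_lfc_xe2"]
SH_RNA = ["rna_lfc_sh1", "rna_lfc_sh2"]
XE_ATAC = ["atac_d_xe1", "atac_d_xe2"]
SH_ATAC = ["atac_d_sh1", "atac_d_sh2"]


def de_filter(
    results: pd.DataFrame,
    fc_cut: float = 2.0,
    fdr_cut: float = 0.1,
    strict_fdr: bool = True,
) -> pd.Index:
    """Differential-expression filter: genes with absolute fold change
    greater than ``fc_cut`` (fold change = 2**log2fc) and FDR below
    ``fdr_cut`` (strict by default; ``strict_fdr=False`` uses <=).

    ``results`` needs columns ``log2fc`` and ``fdr``.
    """
    if ((results["fdr"] < 0) | (results["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    fc = np.power(2.0, results["log2fc"].abs())
    keep_fdr = results["fdr"] < fdr_cut if strict_fdr else results["fdr"] <= fdr_cut
    return results.index[(fc > fc_cut) & keep_fdr]


def gamma(xe_values: np.ndarray | pd.Series, sh_values: np.ndarray | pd.Series) -> float:
    """Group-balancing weight: sum of |XE values| over sum of |sh values|."""
    xe = np.abs(np.asarray(xe_values, dtype=float)).sum()
    sh = np.abs(np.asarray(sh_values, dtype=float)).sum()
    if sh == 0:
        raise ZeroDivisionError(
            "gamma undefined: the knockdown-only group has zero total "
            "absolute signal")
    return float(xe / sh)


def overall_score(
    xe_values: np.ndarray | pd.Series,
    sh_values: np.ndarray | pd.Series,
    gamma_value: float,
    weight_group: str = "sh",
) -> float:
    """Weighted overall score for one TF and one modality.

    Default multiplies the sh-group sum by gamma so both groups contribute
    equal total magnitude (gamma = sum|XE| / sum|sh|); ``weight_group="xe"``
    implements the inverse reading (XE sum multiplied by gamma).
    """
    if gamma_value <= 0:
        raise ValueError("gamma must be positive")
    xe = np.asarray(xe_values, dtype=float)
    sh = np.asarray(sh_values, dtype=float)
    if np.isnan(xe).any() or np.isnan(sh).any():
        raise ValueError("missing line values")
    if weight_group == "sh":
        return float(xe.sum() + gamma_value * sh.sum())
    if weight_group == "xe":
        return float(gamma_value * xe.sum() + sh.sum())
    raise ValueError("weight_group must be 'sh' or 'xe'")


def combined_score(rna: float, atac: float) -> float:
    """Combined-Score: product of the overall RNA- and ATAC-Scores."""
    return float(rna * atac)


def score_table(
    table: pd.DataFrame,
    weight_group: str = "sh",
) -> pd.DataFrame:
    """Compute per-TF overall RNA-/ATAC-Scores and the Combined-Score.

    ``table`` is indexed by tf_id with the eight per-line columns
    (rna_lfc_xe1/2, rna_lfc_sh1/2, atac_d_xe1/2, atac_d_sh1/2).  One gamma
    is computed per modality over all TFs in the table.
    """
    for col in XE_RNA + SH_RNA + XE_ATAC + SH_ATAC:
        if col not in table.columns:
            raise ValueError(f"score table missing column {col}")
    out = table.copy()
    g_rna = gamma(table[XE_RNA].to_numpy().ravel(), table[SH_RNA].to_numpy().ravel())
    g_atac = gamma(table[XE_ATAC].to_numpy().ravel(), table[SH_ATAC].to_numpy().ravel())
    if weight_group == "sh":
        out["rna_score"] = table[XE_RNA].sum(axis=1) + g_rna * table[SH_RNA].sum(axis=1)
        out["atac_score"] = table[XE_ATAC].sum(axis=1) + g_atac * table[SH_ATAC].sum(axis=1)
    elif weight_group == "xe":
        out["rna_score"] = g_rna * table[XE_RNA].sum(axis=1) + table[SH_RNA].sum(axis=1)
        out["atac_score"] = g_atac * table[XE_ATAC].sum(axis=1) + table[SH_ATAC].sum(axis=1)
    else:
        raise ValueError("weight_group must be 'sh' or 'xe'")
    out["combined_score"] = out["rna_score"] * out["atac_score"]
    out.attrs["gamma_rna"] = g_rna
    out.attrs["gamma_atac"] = g_atac
    return out


def _top_ids(series: pd.Series, n: int) -> set:
    """Ids of the n largest values, ties broken by id."""
    ordered = series.sort_index().sort_values(ascending=False, kind="mergesort")
    return set(ordered.index[:n])


def adjust_scores(
    table: pd.DataFrame,
    top_rna: int = 12,
    top_atac: int = 5,
) -> pd.DataFrame:
    """Apply the two sign-adjustment rules to the Combined-Score.

    Rule 1: a TF down in both modalities (rna_score < 0 and atac_score < 0)
    has its Combined-Score negated, so concordant downregulation cannot rank
    as a positive driver.  Rule 2 (rescue): a TF within the top ``top_rna``
    RNA-Scores or top ``top_atac`` ATAC-Scores whose (post-rule-1) score is
    negative gets it flipped positive — a strong single-modality TF is not
    penalized by a weakly discordant other modality.  Rule 1 applies first.
    """
    out = table.copy()
    adjusted = out["combined_score"].copy()
    both_neg = (out["rna_score"] < 0) & (out["atac_score"] < 0)
    adjusted[both_neg] = -adjusted[both_neg]
    rescue_ids = _top_ids(out["rna_score"], top_rna) | _top_ids(out["atac_score"], top_atac)
    rescue = out.index.isin(list(rescue_ids)) & (adjusted < 0)
    adjusted[rescue] = -adjusted[rescue]
    out["adjusted_combined_score"] = adjusted
    out["rule1_applied"] = both_neg
    out["rule2_applied"] = rescue
    return out


def select_candidates(
    table: pd.DataFrame,
    n_combined: int = 20,
    n_atac: int = 2,
) -> pd.DataFrame:
    """Select candidate driver TFs: the union of the top ``n_combined`` by
    adjusted Combined-Score and the top ``n_atac`` by ATAC-Score.

    Adds ``rank`` (1 = highest adjusted score; ties break by tf_id),
    ``selected`` and ``selected_by`` (combined/atac/both) columns.
    """
    if len(table) < n_combined:
        warnings.warn(
            f"only {len(table)} TFs for a top-{n_combined} selection; "
            "returning all", stacklevel=2)
    out = table.copy()
    ordered = out["adjusted_combined_score"].sort_index().sort_values(
        ascending=False, kind="mergesort")
    rank = pd.Series(np.arange(1, len(ordered) + 1), index=ordered.index)
    out["rank"] = rank
    top_combined = set(ordered.index[:n_combined])
    top_atac_ids = _top_ids(out["atac_score"], n_atac)
    out["selected"] = out.index.isin(list(top_combined | top_atac_ids))
    by = np.where(
        out.index.isin(list(top_combined & top_atac_ids)), "both",
        np.where(out.index.isin(list(top_combined)), "combined",
                 np.where(out.index.isin(list(top_atac_ids)), "atac", "")))
    out["selected_by"] = by
    return out.sort_values("rank")


def rank_tf_table(
    table: pd.DataFrame,
    weight_group: str = "sh",
    top_rna: int = 12,
    top_atac: int = 5,
    n_combined: int = 20,
    n_atac: int = 2,
) -> pd.DataFrame:
    """Full driver-prediction pass: gammas and overall scores, Combined-
    Score, sign adjustments, ranking and 20+2 candidate selection."""
    scored = score_table(table, weight_group=weight_group)
    adjusted = adjust_scores(scored, top_rna=top_rna, top_atac=top_atac)
    out = select_candidates(adjusted, n_combined=n_combined, n_atac=n_atac)
    out.attrs.update(scored.attrs)
    return out
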