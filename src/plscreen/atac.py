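"""Interval-level ATAC-seq analysis.

Consensus peaks across replicates and pseudoreplicates, presence/absence
gain-loss peaks between conditions, genomic-region annotation of peak
centers, motif-displacement (MD) scores and their between-condition
differentials, and the ATAC/RNA concordance CDF statistic.

Intervals are 0-based half-open throughout, carried as DataFrames with
columns ``chrom``, ``start``, ``end`` and optionally ``summit`` (absolute
position) and ``score``.  All primitives are plain sorted-array sweeps;
each is oracle-tested against a quadratic brute force.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

__all__ = [
    "merge_intervals",
    "consensus_peaks",
    "differential_peaks",
    "peak_centers",
    "annotate_peaks",
    "md_score",
    "md_differential",
    "concordance_cdf",
]

BED_COLUMNS = ["chrom", "start", "end"]


def _check_intervals(df: pd.DataFrame, name: str = "interval set") -> pd.DataFrame:
    missing = set(BED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{name} missing columns {sorted(missing)}")
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError(f"{name} violates 0 <= start < end")
    return df


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Sort and merge overlapping and book-ended intervals per chromosome
    (coverage semantics, as ``bedtools merge``)."""
    _check_intervals(df)
    out = []
    for chrom, sub in df.sort_values(["chrom", "start", "end"]).groupby("chrom", sort=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        cur_s, cur_e = starts[0], ends[0]
        for s, e in zip(starts[1:], ends[1:]):
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=BED_COLUMNS)


def _intersect_two(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Common coverage of two merged interval sets (>=1 bp overlaps,
    intersection spans)."""
    out = []
    for chrom in sorted(set(a["chrom"]) & set(b["chrom"])):
        sa = a[a["chrom"] == chrom]
        sb = b[b["chrom"] == chrom]
        ia = ib = 0
        astarts, aends = sa["start"].to_numpy(), sa["end"].to_numpy()
        bstarts, bends = sb["start"].to_numpy(), sb["end"].to_numpy()
        while ia < len(astarts) and ib < len(bstarts):
            s = max(astarts[ia], bstarts[ib])
            e = min(aends[ia], bends[ib])
            if s < e:
                out.append((chrom, s, e))
            if aends[ia] <= bends[ib]:
                ia += 1
            else:
                ib += 1
    return pd.DataFrame(out, columns=BED_COLUMNS)


def consensus_peaks(
    replicates: list[pd.DataFrame],
    pseudoreplicates: list[pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Consensus peaks: the coverage present (>=1 bp overlap) in every
    replicate and pseudoreplicate, as intersection spans."""
    sets = list(replicates) + list(pseudoreplicates or [])
    if not sets:
        raise ValueError("no peak sets given")
    merged = [merge_intervals(s) for s in sets]
    acc = merged[0]
    for other in merged[1:]:
        acc = _intersect_two(acc, other)
        if acc.empty:
            break
    return acc.reset_index(drop=True)


def _has_overlap(query: pd.DataFrame, subject: pd.DataFrame) -> np.ndarray:
    """Boolean per query interval: any >=1 bp overlap with the (merged)
    subject set."""
    subject = merge_intervals(subject) if len(subject) else subject
    result = np.zeros(len(query), dtype=bool)
    for chrom, sub in query.groupby("chrom"):
        ss = subject[subject["chrom"] == chrom] if len(subject) else subject
        if ss is None or len(ss) == 0:
            continue
        bstarts = ss["start"].to_numpy()
        bends = ss["end"].to_numpy()
        qs = sub["start"].to_numpy()
        qe = sub["end"].to_numpy()
        # first subject interval whose end is beyond the query start
        idx = np.searchsorted(bends, qs, side="right")
        hit = (idx < len(bstarts)) & (bstarts[np.minimum(idx, len(bstarts) - 1)] < qe)
        result[query.index.get_indexer(sub.index)] = hit
    return result


def differential_peaks(
    condition: pd.DataFrame, control: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence differential peaks: gained = condition peaks with
    zero overlap in control, lost = control peaks with zero overlap in
    condition."""
    condition = _check_intervals(condition.reset_index(drop=True), "condition")
    control = _check_intervals(control.reset_index(drop=True), "control")
    gained = condition[~_has_overlap(condition, control)].reset_index(drop=True)
    lost = control[~_has_overlap(control, condition)].reset_index(drop=True)
    return gained, lost


def peak_centers(df: pd.DataFrame) -> pd.Series:
    """Peak center: summit when present (MACS-style), else midpoint."""
    mid = (df["start"] + df["end"]) // 2
    if "summit" in df.columns:
        return df["summit"].fillna(mid).astype(int)
    return mid.astype(int)


# --- annotation -------------------------------------------------------------


def _containment(pos: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
    """pos inside any of the merged [start, end) intervals."""
    if len(starts) == 0:
        return np.zeros(len(pos), dtype=bool)
    i = np.searchsorted(starts, pos, side="right") - 1
    ok = i >= 0
    out = np.zeros(len(pos), dtype=bool)
    out[ok] = pos[ok] < ends[i[ok]]
    return out


def annotate_peaks(
    peaks: pd.DataFrame,
    annotation: pd.DataFrame,
    promoter_radius: int = 2000,
) -> tuple[pd.DataFrame, pd.Series]:
    """Class each peak center as promoter / exon / intron / intergenic and
    assign a nearest gene by TSS distance.

    ``annotation``: one row per gene with columns ``gene_id``, ``chrom``,
    ``strand``, ``tss``, ``exon_starts``, ``exon_ends`` (comma-separated or
    list).  Priority: promoter (TSS +- radius) > exon > intron (gene body
    outside exons) > intergenic.  Nearest-gene ties break toward the
    lexicographically first gene id.  Returns (per-peak table, class
    proportions).
    """
    peaks = _check_intervals(peaks.reset_index(drop=True), "peaks")
    centers = peak_centers(peaks).to_numpy()
    classes = np.full(len(peaks), "intergenic", dtype=object)
    nearest = np.full(len(peaks), "", dtype=object)

    per_chrom: dict[str, dict] = {}
    for chrom, sub in annotation.groupby("chrom"):
        exon_s, exon_e, body = [], [], []
        for _, row in sub.iterrows():
            es = _as_int_list(row["exon_starts"])
            ee = _as_int_list(row["exon_ends"])
            exon_s.extend(es)
            exon_e.extend(ee)
            lo = min(es + [int(row["tss"])])
            hi = max(ee + [int(row["tss"]) + 1])
            body.append((lo, hi))
        exons = merge_intervals(pd.DataFrame(
            {"chrom": chrom, "start": exon_s, "end": exon_e})) if exon_s else \
            pd.DataFrame(columns=BED_COLUMNS)
        bodies = merge_intervals(pd.DataFrame(
            [(chrom, lo, hi) for lo, hi in body], columns=BED_COLUMNS))
        tss_sorted = sub.sort_values(["tss", "gene_id"])
        per_chrom[chrom] = {
            "exon_starts": exons["start"].to_numpy(),
            "exon_ends": exons["end"].to_numpy(),
            "body_starts": bodies["start"].to_numpy(),
            "body_ends": bodies["end"].to_numpy(),
            "tss": tss_sorted["tss"].to_numpy(),
            "gene_ids": tss_sorted["gene_id"].to_numpy(),
        }

    for chrom, sub in peaks.groupby("chrom"):
        idx = sub.index.to_numpy()
        c = centers[idx]
        if chrom not in per_chrom:
            warnings.warn(f"chromosome {chrom} absent from annotation; "
                          "peaks classed intergenic", stacklevel=2)
            continue
        ann = per_chrom[chrom]
        tss = ann["tss"]
        gids = ann["gene_ids"]
        # nearest TSS, ties toward the lexicographically first gene id
        pos = np.searchsorted(tss, c)
        left = np.clip(pos - 1, 0, len(tss) - 1)
        right = np.clip(pos, 0, len(tss) - 1)
        dl = np.abs(c - tss[left])
        dr = np.abs(c - tss[right])
        take_left = (dl < dr) | ((dl == dr) & (gids[left] <= gids[right]))
        ng = np.where(take_left, left, right)
        dist = np.minimum(dl, dr)
        nearest[idx] = gids[ng]

        promoter = dist <= promoter_radius
        in_exon = _containment(c, ann["exon_starts"], ann["exon_ends"])
        in_body = _containment(c, ann["body_starts"], ann["body_ends"])
        classes[idx[promoter]] = "promoter"
        classes[idx[~promoter & in_exon]] = "exon"
        classes[idx[~promoter & ~in_exon & in_body]] = "intron"

    table = peaks.copy()
    table["center"] = centers
    table["region"] = classes
    table["nearest_gene"] = nearest
    order = ["promoter", "exon", "intron", "intergenic"]
    proportions = (table["region"].value_counts(normalize=True)
                   .reindex(order, fill_value=0.0))
    return table, proportions


def _as_int_list(value) -> list[int]:
    if isinstance(value, str):
        return [int(v) for v in value.strip().strip(",").split(",") if v.strip()]
    return [int(v) for v in value]


# --- motif displacement -----------------------------------------------------


def _nearest_center_distance(
    hits: pd.DataFrame, peaks: pd.DataFrame
) -> np.ndarray:
    """Distance from each motif-hit center to its nearest peak center
    (inf when the hit's chromosome has no peak)."""
    hit_centers = peak_centers(hits).to_numpy()
    dist = np.full(len(hits), np.inf)
    centers_by_chrom = {
        chrom: np.sort(peak_centers(sub).to_numpy())
        for chrom, sub in peaks.groupby("chrom")
    }
    for chrom, sub in hits.reset_index(drop=True).groupby("chrom"):
        pc = centers_by_chrom.get(chrom)
        if pc is None or len(pc) == 0:
            continue
        c = hit_centers[sub.index.to_numpy()]
        pos = np.searchsorted(pc, c)
        left = np.clip(pos - 1, 0, len(pc) - 1)
        right = np.clip(pos, 0, len(pc) - 1)
        d = np.minimum(np.abs(c - pc[left]), np.abs(c - pc[right]))
        dist[sub.index.to_numpy()] = d
    return dist


def md_score(
    peaks: pd.DataFrame,
    motif_hits: pd.DataFrame,
    r_small: int = 150,
    r_large: int = 1500,
) -> pd.DataFrame:
    """Motif-displacement score per motif.

    md = (#hit centers within +-r_small of their nearest peak center) /
    (#hit centers within +-r_large).  Each hit counts once, against its
    nearest peak center.  ``motif_hits`` needs a ``motif_id`` column.
    Motifs with zero hits inside r_large get md = NaN (flagged undefined).
    """
    if r_small >= r_large:
        raise ValueError("r_small must be smaller than r_large")
    if "motif_id" not in motif_hits.columns:
        raise ValueError("motif_hits needs a motif_id column")
    hits = motif_hits.reset_index(drop=True)
    dist = _nearest_center_distance(hits, peaks)
    rows = []
    for motif, sub in hits.groupby("motif_id"):
        d = dist[sub.index.to_numpy()]
        n_large = int((d <= r_large).sum())
        n_small = int((d <= r_small).sum())
        md = n_small / n_large if n_large else np.nan
        rows.append((motif, md, n_small, n_large))
    return pd.DataFrame(rows, columns=["motif_id", "md", "n_small", "n_large"]
                        ).set_index("motif_id")


def md_differential(
    cond_peaks: pd.DataFrame,
    ctrl_peaks: pd.DataFrame,
    motif_hits: pd.DataFrame,
    r_small: int = 150,
    r_large: int = 1500,
) -> pd.DataFrame:
    """Per-motif MD-score differential: delta = md(condition) − md(control).

    Undefined MD scores propagate as missing deltas.
    """
    cond = md_score(cond_peaks, motif_hits, r_small, r_large)
    ctrl = md_score(ctrl_peaks, motif_hits, r_small, r_large)
    out = pd.DataFrame({
        "md_condition": cond["md"],
        "md_control": ctrl["md"],
    })
    out["delta"] = out["md_condition"] - out["md_control"]
    return out


def concordance_cdf(
    peak_table: pd.DataFrame,
    rna_lfc: pd.Series,
    fc_cuts: tuple[float, ...] = (2.0, 5.0),
    p_cut: float = 0.01,
) -> dict[float, dict]:
    """ATAC/RNA concordance: for each fold-change cut, select genes whose
    differential peaks pass |FC| > cut and p <= p_cut, and compare the
    empirical CDF of their RNA log2 fold changes against all genes with a
    two-sample KS statistic.

    ``peak_table`` needs columns ``gene``, ``fold_change``, ``p``.
    """
    out: dict[float, dict] = {}
    all_lfc = rna_lfc.dropna()
    for cut in fc_cuts:
        sel = peak_table[(peak_table["fold_change"].abs() > cut)
                         & (peak_table["p"] <= p_cut)]
        genes = sorted(set(sel["gene"]) & set(all_lfc.index))
        entry: dict = {"genes": genes}
        if not genes:
            entry.update(ks=np.nan, p_value=np.nan, defined=False)
        else:
            res = ks_2samp(all_lfc.loc[genes].to_numpy(), all_lfc.to_numpy())
            entry.update(ks=float(res.statistic), p_value=float(res.pvalue),
                         defined=True)
        out[cut] = entry
    return out
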