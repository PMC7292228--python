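"""Small closed-form assay quantities.

FACS growth-competition fold change (odds ratio of the marker-positive
fraction between two time points) and the AR-selective signature score
(sum of expression abundances over a predefined androgen-responsive gene
list).
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = ["competition_fold_change", "ar_signature_score"]


def competition_fold_change(x, y, unit: str = "fraction") -> float:
    """Relative cell-number fold change of the marker-positive population
    in a mixed-culture competition assay.

    ``x``: marker-positive fraction at day 0; ``y``: the same at the later
    time point.  Returns Y(1−X) / (X(1−Y)) — the ratio of the marked:
    unmarked odds at the two time points (culture-duration terms cancel).
    ``unit="percent"`` accepts 0–100 inputs.
    """
    if unit == "percent":
        x, y = x / 100.0, y / 100.0
    elif unit != "fraction":
        raise ValueError("unit must be 'fraction' or 'percent'")
    for name, v in (("x", x), ("y", y)):
        if not 0 < v < 1:
            raise ValueError(
                f"{name}={v}: marker fractions must be strictly inside (0, 1); "
                "the odds ratio is undefined at the boundaries")
    return (y * (1 - x)) / (x * (1 - y))


def ar_signature_score(expression: pd.DataFrame, gene_list) -> pd.Series:
    """Per-sample signature score: sum of abundances (RPKM) over the genes
    in ``gene_list``.

    ``expression`` is gene x sample.  Genes missing from the table
    contribute zero, with a warning.
    """
    genes = list(dict.fromkeys(gene_list))
    if not genes:
        raise ValueError("empty gene list")
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression abundances must be non-negative")
    present = [g for g in genes if g in expression.index]
    missing = sorted(set(genes) - set(present))
    if missing:
        warnings.warn(f"{len(missing)} signature gene(s) absent from the "
                      f"expression table: {missing[:5]}", stacklevel=2)
    if not present:
        return pd.Series(0.0, index=expression.columns, name="ar_signature")
    return expression.loc[present].sum(axis=0).rename("ar_signature")
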