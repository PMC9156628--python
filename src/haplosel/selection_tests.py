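"""McDonald–Kreitman test, Direction of Selection, and proportion contrasts."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import pandas as pd
from scipy import stats

from .errors import ValidationError


def dos(dn: float, ds: float, pn: float, ps: float) -> float:
    """Direction of Selection: Dn/(Dn+Ds) - Pn/(Pn+Ps).

    NaN (flagged undefined) when either denominator is zero.
    """
    for v in (dn, ds, pn, ps):
        if v < 0:
            raise ValidationError("counts must be >= 0")
    if dn + ds == 0 or pn + ps == 0:
        return math.nan
    return dn / (dn + ds) - pn / (pn + ps)


def mk_chi2(
    dn: float, ds: float, pn: float, ps: float, continuity: bool = False
) -> Tuple[float, float]:
    """Pearson chi-square (df=1) on the 2x2 table [[Dn, Ds], [Pn, Ps]].

    No continuity correction by default; a degenerate margin (any zero row or
    column total) yields (0, 1).
    """
    for v in (dn, ds, pn, ps):
        if v < 0:
            raise ValidationError("counts must be >= 0")
    n = dn + ds + pn + ps
    if n < 1:
        raise ValidationError("table total must be >= 1")
    r1, r2 = dn + ds, pn + ps
    c1, c2 = dn + pn, ds + ps
    if min(r1, r2, c1, c2) == 0:
        return 0.0, 1.0
    delta = abs(dn * ps - ds * pn)
    if continuity:
        delta = max(delta - n / 2.0, 0.0)
    chi2 = n * delta * delta / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def flag_positive(p: float, dos_value: float,
                  p_max: float = 0.05, dos_min: float = 0.0) -> bool:
    """Positive-selection call: significant MK test and DoS above threshold."""
    if math.isnan(dos_value):
        return False
    return p < p_max and dos_value > dos_min


def compare_proportions(k1: int, n1: int, k2: int, n2: int) -> Tuple[float, float]:
    """Two-proportion Pearson chi-square (df=1, no continuity correction)."""
    if n1 < 1 or n2 < 1:
        raise ValidationError("sample sizes must be >= 1")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValidationError("successes must lie in [0, n]")
    return mk_chi2(k1, n1 - k1, k2, n2 - k2)


@dataclass
class MKResult:
    gene_id: str
    chi2: float
    p: float
    dos: float
    positive: bool


def mk_table(
    summaries: pd.DataFrame,
    p_max: float = 0.05,
    dos_min: float = 0.0,
    continuity: bool = False,
) -> pd.DataFrame:
    """Per-gene MK/DoS table from a frame with columns pn, ps, dn, ds."""
    rows = []
    for row in summaries.itertuples(index=False):
        chi2, p = mk_chi2(row.dn, row.ds, row.pn, row.ps, continuity=continuity)
        d = dos(row.dn, row.ds, row.pn, row.ps)
        rows.append({
            "gene_id": row.gene_id,
            "chi2": chi2,
            "mk_p": p,
            "dos": d,
            "positive": flag_positive(p, d, p_max=p_max, dos_min=dos_min),
        })
    return pd.DataFrame(rows)


def class_positive_fractions(
    mk: pd.DataFrame, classification: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class positive-selection fractions with pairwise chi-square tests."""
    merged = mk.merge(classification[["gene_id", "label"]], on="gene_id")
    summary = (
        merged.groupby("label")
        .agg(n=("gene_id", "size"), n_positive=("positive", "sum"))
        .reset_index()
    )
    summary["fraction_positive"] = summary["n_positive"] / summary["n"]
    pair_rows = []
    labels = list(summary["label"])
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            a = summary.loc[summary["label"] == la].iloc[0]
            b = summary.loc[summary["label"] == lb].iloc[0]
            chi2, p = compare_proportions(
                int(a["n_positive"]), int(a["n"]), int(b["n_positive"]), int(b["n"])
            )
            pair_rows.append({"class_a": la, "class_b": lb, "chi2": chi2, "p": p})
    return summary, pd.DataFrame(pair_rows)
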