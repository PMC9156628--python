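"""Group-comparison statistics: one-way ANOVA, ANCOVA with a covariate,
Tukey HSD, and OLS regressions on expression bias."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.anova import anova_lm

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    response: str
    f_stat: float
    df_between: int
    df_within: int
    p: float
    tukey: List[Tuple[str, float, float]] = field(default_factory=list)
    beta: Optional[float] = None
    covariate_used: bool = False


def anova_oneway(groups: Sequence[Sequence[float]],
                 response: str = "") -> ComparisonResult:
    """Classical one-way ANOVA from the between/within decomposition."""
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValidationError("each group needs n >= 2")
    all_obs = np.concatenate(arrays)
    grand = all_obs.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_b = len(arrays) - 1
    df_w = len(all_obs) - len(arrays)
    if ssw == 0.0 and ssb == 0.0:
        return ComparisonResult(response, 0.0, df_b, df_w, 1.0)
    if ssw == 0.0:
        return ComparisonResult(response, math.inf, df_b, df_w, 0.0)
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return ComparisonResult(response, f, df_b, df_w, p)


def ancova_with_covariate(
    groups: Sequence[Sequence[float]],
    covariate: Sequence[Sequence[float]],
    response: str = "",
) -> ComparisonResult:
    """Linear model response ~ group + covariate; group F from type-II SS."""
    if len(groups) != len(covariate):
        raise ValidationError("groups and covariate must align")
    y, g, x = [], [], []
    for i, (obs, cov) in enumerate(zip(groups, covariate)):
        if len(obs) != len(cov):
            raise ValidationError(f"group {i}: response/covariate length mismatch")
        y.extend(obs)
        x.extend(cov)
        g.extend([f"g{i}"] * len(obs))
    df = pd.DataFrame({"y": y, "group": g, "x": x})
    if df["x"].nunique() <= 1:
        logger.warning("constant covariate: falling back to plain ANOVA")
        return anova_oneway(groups, response=response)
    model = smf.ols("y ~ C(group) + x", data=df).fit()
    table = anova_lm(model, typ=2)
    f = float(table.loc["C(group)", "F"])
    p = float(table.loc["C(group)", "PR(>F)"])
    df_b = int(table.loc["C(group)", "df"])
    df_w = int(table.loc["Residual", "df"])
    beta = float(model.params["x"])
    return ComparisonResult(response, f, df_b, df_w, p, beta=beta, covariate_used=True)


def tukey_hsd(groups: Sequence[Sequence[float]],
              names: Optional[Sequence[str]] = None) -> List[Tuple[str, float, float]]:
    """Studentized-range adjusted pairwise comparisons (uses the ANOVA MSW)."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValidationError("need >= 2 groups with n >= 2 each")
    if names is None:
        names = [f"g{i}" for i in range(len(arrays))]
    res = stats.tukey_hsd(*arrays)
    out = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            diff = arrays[i].mean() - arrays[j].mean()
            out.append((f"{names[i]}-{names[j]}", float(diff),
                        float(res.pvalue[i, j])))
    return out


def regress_on_bias(stat: Sequence[float], bias: Sequence[float]) -> Tuple[float, float]:
    """OLS slope of a per-gene statistic on log2 expression bias, with its p.

    Pairs with a missing value in either vector are dropped.
    """
    stat = np.asarray(stat, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if stat.shape != bias.shape:
        raise ValidationError("stat and bias must align")
    keep = ~(np.isnan(stat) | np.isnan(bias))
    stat, bias = stat[keep], bias[keep]
    if len(stat) < 3:
        raise ValidationError("need >= 3 complete observations")
    if np.var(bias) == 0:
        raise ValidationError("bias has zero variance")
    fit = stats.linregress(bias, stat)
    return float(fit.slope), float(fit.pvalue)


def compare_across_classes(
    master: pd.DataFrame,
    responses: Sequence[str],
    class_col: str = "label",
    classes: Sequence[str] = ("haploid_biased", "diploid_biased", "constitutive"),
    covariate: Optional[str] = "gc",
) -> pd.DataFrame:
    """Run ANOVA (and ANCOVA when a covariate is given) for each response.

    Rows with missing response values are dropped pairwise, with the kept
    counts reported.
    """
    rows = []
    for resp in responses:
        sub = master[master[class_col].isin(classes)]
        cols = [resp] + ([covariate] if covariate else [])
        sub = sub.dropna(subset=cols)
        groups, covs, names = [], [], []
        for cls in classes:
            vals = sub.loc[sub[class_col] == cls, resp].to_numpy()
            if len(vals) >= 2:
                groups.append(vals)
                names.append(cls)
                if covariate:
                    covs.append(sub.loc[sub[class_col] == cls, covariate].to_numpy())
        if len(groups) < 2:
            logger.warning("%s: fewer than 2 usable classes, skipped", resp)
            continue
        plain = anova_oneway(groups, response=resp)
        tukey = tukey_hsd(groups, names=names)
        row = {
            "response": resp,
            "n_used": int(sum(len(g) for g in groups)),
            "F": plain.f_stat,
            "df_between": plain.df_between,
            "df_within": plain.df_within,
            "p": plain.p,
            "tukey": "; ".join(f"{pair}:d={d:.4g},p={p:.4g}" for pair, d, p in tukey),
        }
        if covariate:
            adj = ancova_with_covariate(groups, covs, response=resp)
            row.update({
                "F_ancova": adj.f_stat,
                "p_ancova": adj.p,
                "covariate_beta": adj.beta,
            })
        rows.append(row)
    return pd.DataFrame(rows)
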