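"""Sex-/tissue-biased expression classification from a count matrix.

Genes are called up-regulated in a (sex, tissue) group when they show
log2 fold change > 0 toward that group and FDR-adjusted q < alpha in every
required pairwise comparison for that group: versus the same tissue of the
opposite sex and versus each other tissue of the same sex, within the same
developmental dataset (adult and larval datasets are handled separately and
merged afterwards). A gene up-regulated only in male groups is
haploid-biased, only in female groups diploid-biased, in groups of both
sexes constitutive, otherwise unclassified.

The differential test is deliberately simple and fully specified:
median-of-ratios size factors, Welch t-test on log2(normalized + 1), and
Benjamini–Hochberg adjustment within each comparison.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

LABELS = ("haploid_biased", "diploid_biased", "constitutive", "unclassified")


def filter_low_counts(counts: pd.DataFrame, min_total: int = 10) -> pd.DataFrame:
    """Drop genes whose total count across all samples is below min_total."""
    if min_total < 0:
        raise ConfigurationError("min_total must be >= 0")
    kept = counts.loc[counts.sum(axis=1) >= min_total]
    if kept.empty:
        logger.warning("low-count filter removed every gene")
    return kept


def normalize_median_of_ratios(counts: pd.DataFrame) -> Tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios size factors and the normalized matrix.

    The size factor of sample j is the median, over genes expressed in every
    sample, of count_gj divided by the gene's geometric mean across samples.
    """
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        raise ValidationError("no gene has nonzero counts in every sample")
    ref = counts.loc[all_pos].astype(float)
    log_geo_mean = np.log(ref).mean(axis=1)
    ratios = np.log(ref).sub(log_geo_mean, axis=0)
    size_factors = np.exp(ratios.median(axis=0))
    normalized = counts.div(size_factors, axis=1)
    return size_factors, normalized


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def test_upregulation(
    m_a: pd.DataFrame, m_b: pd.DataFrame, comparison: str = ""
) -> pd.DataFrame:
    """Per-gene DE result for normalized group submatrices A vs B.

    log2FC is the difference of group means on the log2(x + 1) scale
    (A over B); p is a two-sided Welch t-test on the same scale; q is
    Benjamini–Hochberg within the comparison.
    """
    if m_a.shape[1] < 2 or m_b.shape[1] < 2:
        raise ConfigurationError("need >= 2 samples per group")
    if not m_a.index.equals(m_b.index):
        raise ValidationError("group submatrices must share the same gene index")
    la = np.log2(m_a.to_numpy(dtype=float) + 1.0)
    lb = np.log2(m_b.to_numpy(dtype=float) + 1.0)
    log2fc = la.mean(axis=1) - lb.mean(axis=1)
    pvals = np.array([_welch_p(la[i], lb[i]) for i in range(la.shape[0])])
    out = pd.DataFrame({
        "gene_id": m_a.index,
        "comparison": comparison,
        "log2fc": log2fc,
        "p": pvals,
        "q": bh_fdr(pvals),
    })
    return out


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass(frozen=True)
class Group:
    sex: str
    tissue: str
    stage: str

    @property
    def name(self) -> str:
        return f"{self.sex}_{self.tissue}"


def groups_from_meta(meta: pd.DataFrame) -> List[Group]:
    seen = []
    for _, row in meta.iterrows():
        g = Group(row["sex"], row["tissue"], row["stage"])
        if g not in seen:
            seen.append(g)
    return seen


def required_comparisons(groups: Sequence[Group]) -> Dict[Group, List[Tuple[Group, Group]]]:
    """Pairwise comparisons each group must win: opposite sex in the same
    tissue, and each other tissue of the same sex, within the same stage."""
    req: Dict[Group, List[Tuple[Group, Group]]] = {}
    for g in groups:
        needed = []
        for other in groups:
            if other is g or other.stage != g.stage:
                continue
            same_tissue_cross_sex = other.tissue == g.tissue and other.sex != g.sex
            same_sex_cross_tissue = other.sex == g.sex and other.tissue != g.tissue
            if same_tissue_cross_sex or same_sex_cross_tissue:
                needed.append((g, other))
        if not needed:
            raise ConfigurationError(f"group {g.name} has no comparison partner")
        req[g] = needed
    return req


def run_pairwise_de(
    counts: pd.DataFrame, meta: pd.DataFrame, min_total: int = 10
) -> pd.DataFrame:
    """Filter, normalize and run every required pairwise comparison."""
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValidationError(f"metadata missing for samples {missing}")
    counts = filter_low_counts(counts, min_total)
    _, normalized = normalize_median_of_ratios(counts)
    groups = groups_from_meta(meta.loc[counts.columns])
    req = required_comparisons(groups)
    pairs = sorted(
        {tuple(sorted((a.name, b.name))) + (a.stage,)
         for comps in req.values() for a, b in comps}
    )
    by_name = {g.name: g for g in groups}
    frames = []
    for name_a, name_b, _stage in pairs:
        ga, gb = by_name[name_a], by_name[name_b]
        cols_a = meta.index[(meta["sex"] == ga.sex) & (meta["tissue"] == ga.tissue)]
        cols_b = meta.index[(meta["sex"] == gb.sex) & (meta["tissue"] == gb.tissue)]
        cols_a = [c for c in cols_a if c in normalized.columns]
        cols_b = [c for c in cols_b if c in normalized.columns]
        label = f"{name_a}_vs_{name_b}"
        frames.append(
            test_upregulation(normalized[cols_a], normalized[cols_b], comparison=label)
        )
    return pd.concat(frames, ignore_index=True)


def _lookup(de_idx: Mapping[str, pd.DataFrame], a: Group, b: Group) -> Tuple[pd.DataFrame, float]:
    """DE frame for the (a, b) pair plus the sign of log2FC toward a."""
    key_ab = f"{a.name}_vs_{b.name}"
    key_ba = f"{b.name}_vs_{a.name}"
    if key_ab in de_idx:
        return de_idx[key_ab], 1.0
    if key_ba in de_idx:
        return de_idx[key_ba], -1.0
    raise ConfigurationError(f"missing comparison {key_ab}")


def classify_genes(
    de: pd.DataFrame, meta: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Assign haploid_biased / diploid_biased / constitutive / unclassified.

    Stages (datasets) are classified separately and merged by union of group
    memberships; a haploid call in one stage conflicting with a diploid call
    in another yields unclassified with a warning.
    """
    groups = groups_from_meta(meta)
    req = required_comparisons(groups)
    de_idx = {c: sub.set_index("gene_id") for c, sub in de.groupby("comparison")}
    gene_ids = de["gene_id"].unique()

    stage_labels: Dict[str, Dict[str, str]] = {}
    memberships: Dict[str, set] = {g: set() for g in gene_ids}
    for stage in sorted({g.stage for g in groups}):
        stage_groups = [g for g in groups if g.stage == stage]
        stage_sets: Dict[str, set] = {g: set() for g in gene_ids}
        for grp in stage_groups:
            frames = []
            for a, b in req[grp]:
                sub, sign = _lookup(de_idx, a, b)
                ok = (sign * sub["log2fc"] > 0) & (sub["q"] < alpha)
                frames.append(ok)
            member = pd.concat(frames, axis=1).all(axis=1)
            for gid in member.index[member]:
                stage_sets[gid].add(grp)
        labels = {}
        for gid, sets in stage_sets.items():
            sexes = {g.sex for g in sets}
            if sexes == {"male"}:
                labels[gid] = "haploid_biased"
            elif sexes == {"female"}:
                labels[gid] = "diploid_biased"
            elif sexes == {"male", "female"}:
                labels[gid] = "constitutive"
            else:
                labels[gid] = "unclassified"
            memberships[gid].update(sets)
        stage_labels[stage] = labels

    rows = []
    n_conflicts = 0
    for gid in gene_ids:
        per_stage = {s: stage_labels[s].get(gid, "unclassified") for s in stage_labels}
        informative = {s: l for s, l in per_stage.items() if l != "unclassified"}
        if {"haploid_biased", "diploid_biased"} <= set(informative.values()):
            label = "unclassified"
            n_conflicts += 1
        else:
            sexes = {g.sex for g in memberships[gid]}
            if sexes == {"male"}:
                label = "haploid_biased"
            elif sexes == {"female"}:
                label = "diploid_biased"
            elif sexes == {"male", "female"}:
                label = "constitutive"
            else:
                label = "unclassified"
        rows.append({
            "gene_id": gid,
            "label": label,
            "tissue_sets": ";".join(sorted(g.name for g in memberships[gid])),
        })
    if n_conflicts:
        logger.warning(
            "%d genes with conflicting haploid/diploid calls across datasets "
            "set to unclassified", n_conflicts
        )
    return pd.DataFrame(rows)


def intersection_counts(classification: pd.DataFrame) -> pd.DataFrame:
    """Count genes in each exact combination of (sex, tissue) memberships."""
    classified = classification[classification["tissue_sets"] != ""]
    if classified.empty:
        return pd.DataFrame(columns=["tissue_sets", "count"])
    table = (
        classified.groupby("tissue_sets").size().reset_index(name="count")
        .sort_values("count", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return table
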