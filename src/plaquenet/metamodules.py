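"""Merging region-wise modules into cortex-wide meta-modules.

Module pairs are compared by gene-overlap Jaccard (J) and by the
component-wise maximum over regions of their within-region eigengene
Pearson correlations (E). The dissimilarity D = 1 − (E + 3·J)/4 — a
1:3-weighted mean of the two similarities — feeds Euclidean-distance
hierarchical clustering cut at k meta-modules (default 15). Genes claimed
by modules of several meta-modules are re-assigned to the meta-module with
the highest eigengene-based connectivity (kME). Differential module
eigengene (DME) tests compare ME distributions between groups with a
two-sided Wilcoxon rank-sum test and BH correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from plaquenet.networks import ModuleSet, module_eigengenes, module_kme


def pairwise_jaccard(modulesets: Sequence[ModuleSet]) -> pd.DataFrame:
    """J[m1, m2] = |genes ∩| / |genes ∪| over all modules of all regions.

    Modules from the same region partition their genes, so within-region
    off-diagonal entries are 0 by construction (asserted).
    """
    sets: dict[str, set] = {}
    region_of: dict[str, str] = {}
    for ms in modulesets:
        for mod, genes in ms.module_genes().items():
            if not genes:
                raise ValueError(f"module {mod!r} is empty")
            sets[mod] = set(genes)
            region_of[mod] = ms.region
    names = sorted(sets)
    if len(names) < 2:
        raise ValueError("need at least 2 modules")
    J = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, m1 in enumerate(names):
        for m2 in names[i + 1 :]:
            inter = len(sets[m1] & sets[m2])
            union = len(sets[m1] | sets[m2])
            j = inter / union
            if region_of[m1] == region_of[m2]:
                assert inter == 0, f"modules {m1}, {m2} share genes within one region"
            J.loc[m1, m2] = J.loc[m2, m1] = j
    return J


def max_cross_correlation(me: pd.DataFrame, regions: pd.Series) -> pd.DataFrame:
    """E = element-wise maximum over regions of the per-region Pearson
    correlation matrices of the ME columns (spots grouped by region)."""
    regions = regions.reindex(me.index)
    names = list(me.columns)
    E = np.full((len(names), len(names)), -np.inf)
    for region in pd.unique(regions.dropna()):
        sub = me[(regions == region).to_numpy()]
        if len(sub) < 3:
            continue
        with np.errstate(invalid="ignore"):
            c = np.corrcoef(sub.to_numpy(float), rowvar=False)
        c = np.where(np.isnan(c), -np.inf, c)
        E = np.maximum(E, c)
    if np.isinf(E).any():
        i, j = np.argwhere(np.isinf(E))[0]
        raise ValueError(
            f"no region yields a correlation for pair ({names[i]}, {names[j]})"
        )
    np.fill_diagonal(E, 1.0)
    return pd.DataFrame(E, index=names, columns=names)


def meta_dissimilarity(
    E: pd.DataFrame, J: pd.DataFrame, literal: bool = False
) -> pd.DataFrame:
    """D = 1 − (E + 3J)/4 (weighted-mean reading; ``literal=True`` computes
    the alternative 1 − (E + 3J/4), which can go negative)."""
    if E.shape != J.shape or list(E.index) != list(J.index):
        raise ValueError("E and J must be aligned")
    if literal:
        D = 1.0 - (E + 3.0 * J / 4.0)
    else:
        D = 1.0 - (E + 3.0 * J) / 4.0
    return (D + D.T) / 2.0


def cluster_metamodules(
    D: pd.DataFrame, k: int = 15, linkage: str = "average"
) -> tuple[dict[str, str], np.ndarray]:
    """Hierarchical clustering of the Euclidean distances between rows of D,
    cut to exactly k clusters. Returns module → meta-module ("MM1"..) map
    plus the linkage tree. Meta-modules are numbered by decreasing size,
    ties by earliest module name."""
    names = list(D.index)
    if k > len(names):
        raise ValueError(f"k={k} exceeds number of modules ({len(names)})")
    if D.isna().any().any():
        raise ValueError("D contains missing values")
    dist = pdist(D.to_numpy(float), metric="euclidean")
    tree = sch.linkage(dist, method=linkage)
    raw = sch.fcluster(tree, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for name, lbl in zip(names, raw):
        groups.setdefault(int(lbl), []).append(name)
    order = sorted(groups, key=lambda g: (-len(groups[g]), min(groups[g])))
    rename = {g: f"MM{i + 1}" for i, g in enumerate(order)}
    mapping = {name: rename[int(lbl)] for name, lbl in zip(names, raw)}
    return mapping, tree


@dataclass
class MetaModuleHierarchy:
    """Full meta-module stage output."""

    J: pd.DataFrame
    E: pd.DataFrame
    D: pd.DataFrame
    tree: np.ndarray
    k: int
    module_to_meta: dict[str, str]
    gene_to_meta: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    meta_me: pd.DataFrame = field(default_factory=pd.DataFrame)


def meta_module_genes(
    modulesets: Sequence[ModuleSet], module_to_meta: Mapping[str, str]
) -> dict[str, list[str]]:
    """Union of member-module genes per meta-module (a gene can appear in
    several meta-modules before re-assignment)."""
    out: dict[str, set] = {}
    for ms in modulesets:
        for mod, genes in ms.module_genes().items():
            meta = module_to_meta[mod]
            out.setdefault(meta, set()).update(genes)
    return {m: sorted(g) for m, g in out.items()}


def assign_genes_to_metamodules(
    modulesets: Sequence[ModuleSet],
    module_to_meta: Mapping[str, str],
    expr: pd.DataFrame,
) -> tuple[pd.Series, pd.DataFrame]:
    """Resolve multi-meta-module genes by kME against meta-module eigengenes.

    Meta-module eigengenes are first PCs over the union of member genes
    (same sign rule as module eigengenes) computed on ``expr`` (observations
    × genes). Genes in exactly one meta-module keep it; genes claimed by
    several go to the one with the highest kME (ties: lexicographically
    smallest meta-module id). Genes with no finite kME are left unassigned
    and reported with label NaN.
    """
    genesets = meta_module_genes(modulesets, module_to_meta)
    meta_me = module_eigengenes(expr, genesets)
    claimed: dict[str, set] = {}
    for meta, genes in genesets.items():
        for g in genes:
            claimed.setdefault(g, set()).add(meta)
    all_expr = expr[[g for g in sorted(claimed) if g in expr.columns]]
    kme = module_kme(all_expr, meta_me)
    assignment = {}
    for gene, metas in sorted(claimed.items()):
        metas = sorted(metas)
        if len(metas) == 1:
            assignment[gene] = metas[0]
            continue
        vals = kme.loc[gene, metas] if gene in kme.index else pd.Series(np.nan, index=metas)
        if vals.isna().all():
            assignment[gene] = np.nan
            continue
        best = vals.max()
        assignment[gene] = min(m for m in metas if vals[m] == best)
    return pd.Series(assignment, name="meta_module"), meta_me


def build_metamodules(
    modulesets: Sequence[ModuleSet],
    me: pd.DataFrame,
    regions: pd.Series,
    expr: pd.DataFrame,
    k: int = 15,
    linkage: str = "average",
) -> MetaModuleHierarchy:
    """End-to-end meta-module stage: J, E, D, tree, k-cut, gene re-assignment."""
    J = pairwise_jaccard(modulesets)
    E = max_cross_correlation(me[J.index], regions)
    D = meta_dissimilarity(E, J)
    module_to_meta, tree = cluster_metamodules(D, k=k, linkage=linkage)
    gene_to_meta, meta_me = assign_genes_to_metamodules(modulesets, module_to_meta, expr)
    return MetaModuleHierarchy(
        J=J, E=E, D=D, tree=tree, k=k, module_to_meta=module_to_meta,
        gene_to_meta=gene_to_meta, meta_me=meta_me,
    )


def dme_test(
    me: pd.DataFrame,
    group_labels: pd.Series,
    group1: str,
    group2: str,
    regions: pd.Series | None = None,
    home_region: Mapping[str, str] | None = None,
    min_n: int = 3,
) -> pd.DataFrame:
    """Differential module eigengene test.

    Per module (and per region when ``regions`` is given): two-sided
    Wilcoxon rank-sum p on ME values of group1 vs group2, effect = mean
    difference, BH FDR across all tests of the contrast. Region-specific
    modules (named in ``home_region``) are tested only in their home region;
    other modules in every region.
    """
    group_labels = group_labels.reindex(me.index)
    region_iter = ["all"] if regions is None else sorted(pd.unique(regions.reindex(me.index).dropna()))
    rows = []
    for region in region_iter:
        if regions is None:
            rmask = np.ones(len(me), dtype=bool)
        else:
            rmask = (regions.reindex(me.index) == region).to_numpy()
        for module in me.columns:
            if home_region is not None and module in home_region:
                if regions is not None and home_region[module] != region:
                    continue
            g1 = me.loc[rmask & (group_labels == group1).to_numpy(), module]
            g2 = me.loc[rmask & (group_labels == group2).to_numpy(), module]
            if len(g1) < min_n or len(g2) < min_n:
                rows.append((module, region, np.nan, np.nan, "too_few_observations"))
                continue
            if g1.var() == 0 and g2.var() == 0 and g1.mean() == g2.mean():
                rows.append((module, region, 0.0, 1.0, ""))
                continue
            pooled = np.concatenate([g1, g2])
            no_ties = len(np.unique(pooled)) == len(pooled)
            method = "exact" if (no_ties and max(len(g1), len(g2)) <= 30) else "asymptotic"
            stat = scipy.stats.mannwhitneyu(g1, g2, alternative="two-sided", method=method)
            rows.append((module, region, g1.mean() - g2.mean(), stat.pvalue, ""))
    out = pd.DataFrame(rows, columns=["module", "region", "effect", "p", "reason"])
    tested = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    out["fdr"] = fdr
    out["contrast"] = f"{group1}_vs_{group2}"
    return out


def correlate_scores(
    me: pd.DataFrame, scores: pd.Series, groupby: pd.Series | None = None, min_n: int = 3
) -> pd.DataFrame:
    """Pearson correlation of each ME with an external per-observation score
    (e.g. polygenic disease-risk scores), optionally per group; groups with
    <3 observations or constant scores yield NaN."""
    scores = scores.reindex(me.index)
    groups = (
        pd.Series("all", index=me.index) if groupby is None else groupby.reindex(me.index)
    )
    rows = []
    for group in sorted(pd.unique(groups.dropna())):
        mask = (groups == group).to_numpy()
        sub_s = scores[mask]
        for module in me.columns:
            if mask.sum() < min_n or sub_s.std(ddof=0) == 0 or sub_s.isna().any():
                rows.append((module, group, np.nan))
                continue
            r = np.corrcoef(me.loc[mask, module], sub_s)[0, 1]
            rows.append((module, group, r))
    return pd.DataFrame(rows, columns=["module", "group", "pearson_r"])
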