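"""Amyloid-imaging integration: spot scores, Gi* hotspots, gene calling.

Segmented amyloid objects are assigned to Visium spots by a circle-circle
intersection test with an expanded spot radius (half the lattice pitch by
default, covering the gap between capture areas). Per-spot count and
total-area scores feed the Getis-Ord Gi* local hotspot z-statistic over the
hexagonal neighbor graph (self-inclusion, binary weights). Genes are called
amyloid-associated when a per-gene count GLM on the hotspot score is
FDR-significant AND normalized expression correlates positively with the
score — a two-gate rule that discards significant depletions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.stats
from scipy.spatial import cKDTree
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from plaquenet.types import (
    AmyloidBinaryTable,
    CountsTable,
    DegenerateFieldError,
    SpotGrid,
)


def effective_radius(grid: SpotGrid, override_um: float | None = None) -> float:
    """Expanded spot radius used for binary assignment: half the pitch.

    The physical capture area is ``diameter_um / 2`` but spots tile only
    ~55/100 of the section; expanding to spacing/2 attributes every binary
    near the lattice to its closest spot(s) while keeping double assignment
    rare. ``override_um`` substitutes any other radius.
    """
    if override_um is not None:
        if override_um <= 0:
            raise ValueError("override radius must be positive")
        return float(override_um)
    if grid.spacing_um <= 0:
        raise ValueError("grid spacing must be positive")
    return grid.spacing_um / 2.0


def score_spots(
    grid: SpotGrid,
    binaries: AmyloidBinaryTable,
    effective_radius_um: float | None = None,
) -> pd.DataFrame:
    """Per-spot binary count and total area.

    Binary *i* (a circle of radius ``diameter_um/2``) is assigned to spot *s*
    iff the center distance is ≤ effective_radius + diameter_i/2. A binary
    intersecting several spots contributes to all of them.
    """
    r_eff = effective_radius(grid, effective_radius_um)
    n_binaries = np.zeros(len(grid), dtype=np.int64)
    total_area = np.zeros(len(grid), dtype=float)
    if len(binaries) > 0:
        tree = cKDTree(grid.coords)
        centers = binaries.binaries[["x_um", "y_um"]].to_numpy(float)
        radii = r_eff + binaries.binaries["diameter_um"].to_numpy(float) / 2.0
        areas = binaries.binaries["area_um2"].to_numpy(float)
        for center, radius, area in zip(centers, radii, areas):
            hits = tree.query_ball_point(center, radius)
            for s in hits:
                n_binaries[s] += 1
                total_area[s] += area
    return pd.DataFrame(
        {"n_binaries": n_binaries, "total_area_um2": total_area},
        index=grid.spot_ids,
    )


@dataclass
class NeighborGraph:
    """Symmetric unweighted spot adjacency; self-weight is added analytically."""

    adjacency: scipy.sparse.csr_matrix
    spot_ids: pd.Index

    @property
    def n(self) -> int:
        return len(self.spot_ids)

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


def build_neighbor_graph(grid: SpotGrid, tol: float = 0.05) -> NeighborGraph:
    """Edges between spots closer than ``spacing_um * (1 + tol)``."""
    coords = grid.coords
    tree = cKDTree(coords)
    pairs = tree.query_pairs(grid.spacing_um * (1.0 + tol), output_type="ndarray")
    n = len(grid)
    if len(pairs) == 0:
        adj = scipy.sparse.csr_matrix((n, n))
    else:
        i = np.concatenate([pairs[:, 0], pairs[:, 1]])
        j = np.concatenate([pairs[:, 1], pairs[:, 0]])
        adj = scipy.sparse.csr_matrix(
            (np.ones(len(i)), (i, j)), shape=(n, n)
        )
    return NeighborGraph(adjacency=adj, spot_ids=grid.spot_ids)


def gi_star(scores: pd.Series | np.ndarray, graph: NeighborGraph) -> pd.Series:
    """Getis-Ord Gi* z-values with self-inclusion and binary weights.

    Gi* = (Σ_j w_ij x_j − X̄ W_i) / (S · sqrt((n Σ_j w_ij² − W_i²)/(n−1)))
    with w_ij = 1 for j ∈ neighbors(i) ∪ {i}, W_i = Σ_j w_ij, X̄ the global
    mean and S the population standard deviation.
    """
    x = np.asarray(scores, dtype=float)
    n = graph.n
    if x.shape != (n,):
        raise ValueError("score vector does not match graph size")
    if n < 2:
        raise ValueError("need at least 2 spots")
    xbar = x.mean()
    s = np.sqrt((x**2).mean() - xbar**2)
    if s == 0:
        raise DegenerateFieldError("constant score field: Gi* undefined")
    wi = graph.degrees() + 1.0  # self-weight
    local_sum = graph.adjacency @ x + x  # Σ_j w_ij x_j including self
    denom_inner = (n * wi - wi**2) / (n - 1)  # binary weights: Σ w² = W
    denom = s * np.sqrt(denom_inner)
    z = np.full(n, np.nan)
    ok = denom > 0
    z[ok] = (local_sum[ok] - xbar * wi[ok]) / denom[ok]
    return pd.Series(z, index=graph.spot_ids, name="gi_star")


def _drop_collinear(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str], list[str]]:
    """Greedy left-to-right column selection keeping a full-rank design."""
    keep: list[int] = []
    dropped: list[str] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    return X[:, keep], [names[j] for j in keep], dropped


def _design_matrix(
    score: np.ndarray, sample_ids: np.ndarray, total_umi: np.ndarray
) -> tuple[np.ndarray, list[str], list[str]]:
    cols = [np.ones_like(score), score]
    names = ["intercept", "score"]
    levels = sorted(pd.unique(sample_ids))
    for lvl in levels[1:]:
        cols.append((sample_ids == lvl).astype(float))
        names.append(f"sample[{lvl}]")
    cols.append(np.log1p(total_umi))
    names.append("log1p_total_umi")
    X = np.column_stack(cols)
    return _drop_collinear(X, names)


def amyloid_glm(
    counts: CountsTable,
    score: pd.Series,
    include: pd.Series | np.ndarray | None = None,
    family: str = "quasipoisson",
) -> pd.DataFrame:
    """Per-gene count GLM of UMI on a per-spot score field.

    Log-link GLM with sample-of-origin and log(total UMI + 1) covariates;
    quasi-Poisson variance by default (Pearson-χ² scaled Poisson), optional
    negative binomial. Returns gene, beta (score coefficient), se, wald_p
    (two-sided), n_spots and a reason code for skipped genes.
    """
    if family not in ("quasipoisson", "poisson", "negbin"):
        raise ValueError(f"unknown family {family!r}")
    mask = np.ones(counts.n_spots, dtype=bool) if include is None else np.asarray(include, bool)
    score_v = score.reindex(counts.spot_ids).to_numpy(float)[mask]
    if not np.isfinite(score_v).all():
        raise ValueError("score field not finite on included spots")
    sample_v = counts.sample_ids.to_numpy()[mask]
    umi_v = counts.total_umi().to_numpy(float)[mask]
    X, names, dropped = _design_matrix(score_v, sample_v, umi_v)
    if dropped:
        import warnings

        warnings.warn(f"dropped collinear design column(s): {dropped}", stacklevel=2)
    if "score" not in names:
        raise ValueError("score column is collinear with covariates")
    j = names.index("score")
    if family == "negbin":
        fam = sm.families.NegativeBinomial()
    else:
        fam = sm.families.Poisson()
    scale = "X2" if family == "quasipoisson" else 1.0

    rows = []
    y_all = counts.values[:, mask]
    for g, gene in enumerate(counts.gene_ids):
        y = y_all[g].astype(float)
        if y.sum() == 0:
            rows.append((gene, np.nan, np.nan, np.nan, int(mask.sum()), "all_zero"))
            continue
        try:
            res = sm.GLM(y, X, family=fam).fit(scale=scale)
            beta, se = res.params[j], res.bse[j]
            if not np.isfinite(se) or se == 0:
                rows.append((gene, beta, np.nan, np.nan, int(mask.sum()), "degenerate_se"))
                continue
            p = 2.0 * scipy.stats.norm.sf(abs(beta / se))
            rows.append((gene, beta, se, p, int(mask.sum()), ""))
        except Exception as exc:  # noqa: BLE001 - fit failure is a per-gene outcome
            rows.append((gene, np.nan, np.nan, np.nan, int(mask.sum()), f"fit_failed:{type(exc).__name__}"))
    return pd.DataFrame(rows, columns=["gene", "beta", "se", "wald_p", "n_spots", "reason"])


def log1p_cpm(counts: CountsTable) -> pd.DataFrame:
    """log(1 + counts-per-million) normalized expression, genes × spots."""
    totals = counts.values.sum(axis=0).astype(float)
    totals[totals == 0] = 1.0
    cpm = counts.values / totals[None, :] * 1e6
    return pd.DataFrame(np.log1p(cpm), index=counts.gene_ids, columns=counts.spot_ids)


def _pearson_rows(M: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of M with vector v (NaN if constant)."""
    Mc = M - M.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((Mc**2).sum(axis=1) * (vc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Mc @ vc) / denom
    return r


def call_amyloid_genes(
    glm_results: pd.DataFrame,
    counts: CountsTable,
    score: pd.Series,
    include: pd.Series | np.ndarray | None = None,
    alpha: float = 0.05,
    stain: str = "AmyloGlo",
    analysis_unit: str = "pooled-GM",
) -> pd.DataFrame:
    """Two-gate caller: BH-FDR < alpha on the GLM Wald p AND positive
    Pearson correlation of log1p-CPM expression with the score field."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    mask = np.ones(counts.n_spots, dtype=bool) if include is None else np.asarray(include, bool)
    res = glm_results.copy()
    tested = res["wald_p"].notna()
    fdr = np.full(len(res), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = multipletests(res.loc[tested, "wald_p"], method="fdr_bh")[1]
    res["fdr"] = fdr

    norm = log1p_cpm(counts)
    expr = norm.to_numpy()[:, mask]
    score_v = score.reindex(counts.spot_ids).to_numpy(float)[mask]
    r_by_gene = pd.Series(_pearson_rows(expr, score_v), index=counts.gene_ids)
    res["pearson_r"] = res["gene"].map(r_by_gene).to_numpy()
    res["stain"] = stain
    res["analysis_unit"] = analysis_unit
    res["is_associated"] = (res["fdr"] < alpha) & (res["pearson_r"] > 0)
    res["is_associated"] = res["is_associated"].fillna(False).astype(bool)
    cols = ["gene", "stain", "analysis_unit", "beta", "se", "wald_p", "fdr",
            "pearson_r", "is_associated", "n_spots", "reason"]
    return res[cols]


def run_amyloid_analysis(
    counts: CountsTable,
    regions: pd.Series,
    score: pd.Series,
    mode: str = "human",
    wm_label: str = "WM",
    alpha: float = 0.05,
    stain: str = "AmyloGlo",
    family: str = "quasipoisson",
) -> pd.DataFrame:
    """Full caller: human mode pools gray-matter spots (WM excluded, one
    analysis unit); mouse mode runs each region cluster separately."""
    if mode not in ("human", "mouse"):
        raise ValueError("mode must be 'human' or 'mouse'")
    regions = regions.reindex(counts.spot_ids)
    results = []
    if mode == "human":
        units = [("pooled-GM", (regions != wm_label).to_numpy())]
    else:
        units = [(str(c), (regions == c).to_numpy()) for c in sorted(regions.unique())]
    for unit, mask in units:
        if mask.sum() < 3:
            continue
        glm = amyloid_glm(counts, score, include=mask, family=family)
        results.append(
            call_amyloid_genes(glm, counts, score, include=mask, alpha=alpha,
                               stain=stain, analysis_unit=unit)
        )
    if not results:
        raise ValueError("no analysis unit with enough spots")
    return pd.concat(results, ignore_index=True)


@dataclass
class OverlapStat:
    """2×2 overlap of two gene sets against a stated background."""

    a: int  # in both
    b: int  # A only
    c: int  # B only
    d: int  # neither
    jaccard: float
    odds_ratio: float
    fisher_p: float


def overlap_gene_sets(A, B, background) -> OverlapStat:
    """Jaccard, sample odds ratio (Haldane 0.5 correction iff any zero cell)
    and one-sided Fisher exact enrichment p for two sets in a background."""
    bg = set(background)
    if not bg:
        raise ValueError("background is empty")
    A, B = set(A), set(B)
    if not A <= bg or not B <= bg:
        raise ValueError("A and B must be subsets of the background")
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = len(bg) - a - b - c
    union = a + b + c
    jaccard = a / union if union else 0.0
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    _, fisher_p = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return OverlapStat(a=a, b=b, c=c, d=d, jaccard=jaccard,
                       odds_ratio=odds_ratio, fisher_p=float(fisher_p))
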