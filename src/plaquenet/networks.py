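"""Region-wise weighted co-expression networks from pseudobulk profiles.

The construction follows the standard weighted-network recipe: genes kept
when expressed in ≥5% of spots of any region; per-(sample, region)
pseudobulk log2(CPM + 1); soft-power chosen as the smallest candidate whose
signed scale-free fit exceeds 0.8; signed adjacency raised to that power;
topological overlap; average-linkage clustering of 1 − TOM with a static
height cut plus explicit eigengene-correlation merging (minimum module size
50, merge height 0.1). Module eigengenes are the sign-fixed first principal
component of the module's standardized expression; kME is the Pearson
correlation of each gene with each eigengene. Meta-spots (grid-wise pooling
of adjacent spots) support brain-wide networks on sparse sections, and a
consensus TOM combines per-region TOMs by 95th-percentile scaling followed
by the element-wise minimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from plaquenet.types import CountsTable, SpotGrid

UNASSIGNED = "unassigned"


def filter_expressed_genes(
    counts: CountsTable, groups: pd.Series, min_frac: float = 0.05
) -> list[str]:
    """Keep a gene iff some region expresses it (>0 UMI) in ≥ ``min_frac`` of spots."""
    groups = groups.reindex(counts.spot_ids)
    nonzero = counts.values > 0
    keep = np.zeros(counts.n_genes, dtype=bool)
    for region in pd.unique(groups.dropna()):
        mask = (groups == region).to_numpy()
        if mask.sum() == 0:
            continue
        frac = nonzero[:, mask].mean(axis=1)
        keep |= frac >= min_frac
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def pseudobulk_log2cpm(
    counts: CountsTable,
    regions: pd.Series,
    genes: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-(sample, region) summed UMI → CPM → log2(CPM + pseudocount).

    Rows are a (sample_id, region) MultiIndex; (sample, region) pairs with
    zero total UMI are dropped with a warning.
    """
    regions = regions.reindex(counts.spot_ids)
    if genes is not None:
        idx = counts.gene_ids.get_indexer(pd.Index(genes))
        if (idx < 0).any():
            raise KeyError("gene not present in counts")
        values = counts.values[idx]
        gene_ids = pd.Index(genes)
    else:
        values = counts.values
        gene_ids = counts.gene_ids
    rows = {}
    keys = pd.DataFrame(
        {"sample": counts.sample_ids.to_numpy(), "region": regions.to_numpy()}
    )
    for (sample, region), sub in keys.groupby(["sample", "region"], sort=True):
        mask = np.zeros(len(keys), dtype=bool)
        mask[sub.index] = True
        total = values[:, mask].sum(axis=1).astype(float)
        grand = total.sum()
        if grand == 0:
            warnings.warn(f"({sample}, {region}) has zero total UMI; row dropped",
                          stacklevel=2)
            continue
        cpm = total / grand * 1e6
        rows[(sample, region)] = np.log2(cpm + pseudocount)
    if not rows:
        return pd.DataFrame(columns=gene_ids)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=gene_ids)
    out.index = pd.MultiIndex.from_tuples(out.index, names=["sample", "region"])
    return out


def adjacency_matrix(
    expr: pd.DataFrame, power: float, network_type: str = "signed"
) -> pd.DataFrame:
    """Soft-thresholded co-expression adjacency from rows=observations."""
    if network_type not in ("signed", "unsigned"):
        raise ValueError("network_type must be 'signed' or 'unsigned'")
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(expr.to_numpy(float), rowvar=False)
    if network_type == "signed":
        adj = ((1.0 + cor) / 2.0) ** power
    else:
        adj = np.abs(cor) ** power
    return pd.DataFrame(adj, index=expr.columns, columns=expr.columns)


@dataclass
class NetworkConfig:
    """Soft-power scan result."""

    candidate_powers: tuple[int, ...]
    chosen_power: int
    network_type: str = "signed"
    fit_by_power: dict[int, float] = field(default_factory=dict)
    passed: bool = True
    min_module_size: int = 50
    merge_height: float = 0.1


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed scale-free topology index: −sign(slope)·R² of log10 p(k) on
    log10 k over equal-count connectivity bins."""
    k = np.asarray(connectivity, float)
    k = k[k > 0]
    if len(k) < n_bins:
        n_bins = max(2, len(k) // 2)
    if n_bins < 2:
        return 0.0
    quantiles = np.quantile(k, np.linspace(0, 1, n_bins + 1))
    quantiles[-1] += 1e-12
    which = np.clip(np.searchsorted(quantiles, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        width = quantiles[b + 1] - quantiles[b]
        if sel.sum() == 0 or width <= 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        # equal-count bins hold a constant fraction; the density p(k) is
        # that fraction divided by the bin width
        ys.append(np.log10(sel.mean() / width))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return 0.0
    slope, intercept = np.polyfit(xs, ys, 1)
    pred = slope * np.asarray(xs) + intercept
    ss_res = ((np.asarray(ys) - pred) ** 2).sum()
    ss_tot = ((np.asarray(ys) - np.mean(ys)) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def select_soft_power(
    expr: pd.DataFrame,
    candidate_powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    threshold: float = 0.8,
    network_type: str = "signed",
    min_mean_connectivity: float = 1.0,
) -> NetworkConfig:
    """Smallest candidate power whose scale-free fit exceeds ``threshold``;
    falls back to the best-fitting power with ``passed=False``.

    Powers whose mean connectivity drops below ``min_mean_connectivity``
    are ineligible: a vanishing network fits a straight line in log-log
    space for spurious reasons (sampling noise raised to a high power), so
    a good fit there says nothing about scale-free topology.
    """
    if len(expr) < 4:
        raise ValueError("need at least 4 observations")
    fits: dict[int, float] = {}
    eligible: dict[int, bool] = {}
    for p in candidate_powers:
        adj = adjacency_matrix(expr, p, network_type).to_numpy()
        np.fill_diagonal(adj, 0.0)
        k = np.nansum(adj, axis=1)
        fits[p] = scale_free_fit(k)
        eligible[p] = k.mean() >= min_mean_connectivity
    passing = [p for p in sorted(candidate_powers) if fits[p] > threshold and eligible[p]]
    if passing:
        return NetworkConfig(tuple(candidate_powers), passing[0],
                             network_type, fits, passed=True)
    best = max(sorted(candidate_powers), key=lambda p: fits[p])
    return NetworkConfig(tuple(candidate_powers), best, network_type, fits, passed=False)


def tom_matrix(
    expr: pd.DataFrame, power: float, network_type: str = "signed"
) -> pd.DataFrame:
    """Topological overlap: TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j)+1−a_ij),
    diagonal 1. Constant genes are dropped with a warning."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 genes")
    sd = expr.std(axis=0, ddof=0)
    constant = sd[sd == 0].index
    if len(constant):
        warnings.warn(f"dropping {len(constant)} constant gene(s)", stacklevel=2)
        expr = expr.drop(columns=constant)
    adj = adjacency_matrix(expr, power, network_type).to_numpy()
    np.fill_diagonal(adj, 0.0)
    k = adj.sum(axis=1)
    shared = adj @ adj
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + adj) / (kmin + 1.0 - adj)
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=expr.columns, columns=expr.columns)


def module_eigengenes(
    expr: pd.DataFrame, modules: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """First principal component per module on column-standardized expression,
    unit variance, sign fixed so cor(ME, mean standardized expression) ≥ 0."""
    out = {}
    for name in sorted(modules):
        genes = [g for g in modules[name] if g in expr.columns]
        if len(genes) < 2:
            raise ValueError(f"module {name!r} has <2 genes present")
        sub = expr[genes].to_numpy(float)
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=0)
        nonconst = sd > 0
        if not nonconst.any():
            out[name] = np.zeros(len(expr))
            continue
        z = (sub[:, nonconst] - mean[nonconst]) / sd[nonconst]
        u, s, _ = np.linalg.svd(z, full_matrices=False)
        me = u[:, 0] * s[0]
        me_sd = me.std(ddof=0)
        if me_sd > 0:
            me = me / me_sd
        ref = z.mean(axis=1)
        c = np.dot(me - me.mean(), ref - ref.mean())
        if c < 0:
            me = -me
        out[name] = me
    return pd.DataFrame(out, index=expr.index)


def module_kme(expr: pd.DataFrame, me: pd.DataFrame) -> pd.DataFrame:
    """kME[g, m] = Pearson cor(expression of gene g, eigengene of module m);
    NaN for constant genes."""
    X = expr.to_numpy(float)
    E = me.to_numpy(float)
    Xc = X - X.mean(axis=0)
    Ec = E - E.mean(axis=0)
    xn = np.sqrt((Xc**2).sum(axis=0))
    en = np.sqrt((Ec**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        kme = (Xc.T @ Ec) / np.outer(xn, en)
    return pd.DataFrame(kme, index=expr.columns, columns=me.columns)


def _assignments_to_modules(assignments: pd.Series) -> dict[str, list[str]]:
    mods: dict[str, list[str]] = {}
    for gene, label in assignments.items():
        if label != UNASSIGNED:
            mods.setdefault(str(label), []).append(gene)
    return mods


def _regroup(labels: pd.Series) -> dict[int, list[str]]:
    return {int(k): list(v.index) for k, v in labels.groupby(labels) if k != -1}


def merge_modules(
    labels: pd.Series, expr: pd.DataFrame, merge_height: float = 0.1
) -> pd.Series:
    """Iteratively merge the module pair with the highest eigengene
    correlation while it exceeds 1 − merge_height (labels: int codes,
    −1 = unassigned)."""
    labels = labels.copy()
    while True:
        groups = _regroup(labels)
        if len(groups) < 2:
            break
        me = module_eigengenes(expr, {str(k): g for k, g in groups.items()})
        cor = me.corr().to_numpy()
        np.fill_diagonal(cor, -np.inf)
        i, j = np.unravel_index(np.argmax(cor), cor.shape)
        if cor[i, j] <= 1.0 - merge_height:
            break
        a, b = int(me.columns[i]), int(me.columns[j])
        labels[labels == max(a, b)] = min(a, b)
    return labels


def detect_modules(
    tom: pd.DataFrame,
    expr: pd.DataFrame,
    min_module_size: int = 50,
    merge_height: float = 0.1,
    cut_height: float = 0.995,
) -> pd.Series:
    """Average-linkage clustering of 1 − TOM with a static height cut,
    followed by iterative merging of modules whose eigengenes correlate
    above 1 − merge_height. Returns gene → label ("M1".., or "unassigned"),
    modules numbered by decreasing size."""
    genes = list(tom.index)
    dis = 1.0 - tom.to_numpy(float)
    np.fill_diagonal(dis, 0.0)
    dis = np.clip((dis + dis.T) / 2.0, 0.0, None)
    link = sch.linkage(squareform(dis, checks=False), method="average")
    raw = sch.fcluster(link, t=cut_height, criterion="distance")
    labels = pd.Series(raw, index=genes)
    sizes = labels.value_counts()
    labels[labels.map(sizes) < min_module_size] = -1

    labels = merge_modules(labels, expr, merge_height)
    groups = _regroup(labels)
    if not groups:
        warnings.warn("no module passed the minimum size; all genes unassigned",
                      stacklevel=2)
        return pd.Series(UNASSIGNED, index=genes)
    order = sorted(groups, key=lambda k: (-len(groups[k]), genes.index(groups[k][0])))
    rename = {k: f"M{i + 1}" for i, k in enumerate(order)}
    out = pd.Series(UNASSIGNED, index=genes, dtype=object)
    for k, members in groups.items():
        out[members] = rename[k]
    return out


def project_modules(
    modules: Mapping[str, Sequence[str]], query_expr: pd.DataFrame
) -> tuple[pd.DataFrame, list[str]]:
    """Recompute MEs on query data restricted to each module's genes (same
    standardization and sign rule); modules with <2 genes present are
    skipped and listed."""
    present, skipped = {}, []
    for name in sorted(modules):
        genes = [g for g in modules[name] if g in query_expr.columns]
        if len(genes) < 2:
            skipped.append(name)
        else:
            present[name] = genes
    if not present:
        return pd.DataFrame(index=query_expr.index), skipped
    return module_eigengenes(query_expr, present), skipped


def make_metaspots(
    grid: SpotGrid, counts: CountsTable, bin_width_spots: int = 2
) -> tuple[SpotGrid, CountsTable]:
    """Merge adjacent spots in a (b × b) lattice-index grid: counts summed,
    coordinates averaged, region = majority label (ties lexicographic)."""
    if bin_width_spots < 1:
        raise ValueError("bin width must be >= 1")
    b = bin_width_spots
    spots = grid.spots
    gkey = list(zip(spots["array_row"] // b, spots["array_col"] // b))
    sample_id = spots["sample_id"].iloc[0]
    order = counts.spot_ids.get_indexer(spots["spot_id"])
    rows, meta_values = [], []
    for key in sorted(set(gkey)):
        mask = np.array([k == key for k in gkey])
        members = spots[mask]
        region = members["region"].value_counts()
        top = region[region == region.max()].index.min()
        rows.append(
            {
                "spot_id": f"{sample_id}-MS{key[0]:03d}_{key[1]:03d}",
                "array_row": int(key[0]),
                "array_col": int(key[1]),
                "x_um": members["x_um"].mean(),
                "y_um": members["y_um"].mean(),
                "region": top,
                "sample_id": sample_id,
            }
        )
        meta_values.append(counts.values[:, order[mask]].sum(axis=1))
    meta_spots = pd.DataFrame(rows)
    meta_grid = SpotGrid(meta_spots, spacing_um=grid.spacing_um * b,
                         diameter_um=grid.diameter_um)
    meta_counts = CountsTable(
        gene_ids=counts.gene_ids,
        spot_ids=pd.Index(meta_spots["spot_id"]),
        values=np.column_stack(meta_values),
        sample_ids=pd.Series(sample_id, index=pd.Index(meta_spots["spot_id"])),
        sample_meta=counts.sample_meta,
    )
    return meta_grid, meta_counts


def consensus_tom(toms: Sequence[pd.DataFrame], quantile: float = 0.95) -> pd.DataFrame:
    """Element-wise minimum of per-region TOMs after quantile scaling.

    Each TOM is power-scaled so its ``quantile`` off-diagonal value matches
    the first TOM's, then the element-wise minimum is taken (shared genes
    only) — the classical conservative consensus.
    """
    if len(toms) < 2:
        warnings.warn("fewer than 2 TOMs: identity passthrough", stacklevel=2)
        return toms[0].copy()
    shared = set(toms[0].index)
    for t in toms[1:]:
        shared &= set(t.index)
    genes = [g for g in toms[0].index if g in shared]  # keep reference order
    mats = [t.loc[genes, genes].to_numpy(float) for t in toms]
    off = ~np.eye(len(genes), dtype=bool)
    q_ref = np.quantile(mats[0][off], quantile)
    scaled = [mats[0]]
    for m in mats[1:]:
        q = np.quantile(m[off], quantile)
        if 0 < q < 1 and 0 < q_ref < 1:
            m = m ** (np.log(q_ref) / np.log(q))
        scaled.append(m)
    cons = np.minimum.reduce(scaled)
    np.fill_diagonal(cons, 1.0)
    return pd.DataFrame(cons, index=pd.Index(genes), columns=pd.Index(genes))


@dataclass
class ModuleSet:
    """Named modules of one region: assignments, eigengenes, connectivity."""

    region: str
    assignments: pd.Series  # gene -> "<region>-M<k>" or "unassigned"
    me: pd.DataFrame  # observations × modules
    kme: pd.DataFrame  # genes × modules

    def module_genes(self) -> dict[str, list[str]]:
        return _assignments_to_modules(self.assignments)


def build_region_network(
    pseudobulk: pd.DataFrame,
    region: str,
    spot_expr: pd.DataFrame,
    candidate_powers: Sequence[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    min_module_size: int = 50,
    merge_height: float = 0.1,
    cut_height: float = 0.995,
    network_type: str = "signed",
) -> tuple[ModuleSet, NetworkConfig]:
    """Per-region driver: soft power on the region's pseudobulk rows, TOM,
    module detection, then MEs/kME on spot-level expression (modules are
    derived from pseudobulk, summarized per spot)."""
    expr_r = pseudobulk.xs(region, level="region")
    cfg = select_soft_power(expr_r, candidate_powers, network_type=network_type)
    tom = tom_matrix(expr_r, cfg.chosen_power, network_type)
    labels = detect_modules(tom, expr_r, min_module_size, merge_height, cut_height)
    named = labels.map(lambda m: f"{region}-{m}" if m != UNASSIGNED else UNASSIGNED)
    mods = _assignments_to_modules(named)
    if mods:
        me = module_eigengenes(spot_expr, mods)
        kme = module_kme(spot_expr[[g for g in named.index if g in spot_expr.columns]], me)
    else:
        me = pd.DataFrame(index=spot_expr.index)
        kme = pd.DataFrame(index=named.index)
    cfg.min_module_size = min_module_size
    cfg.merge_height = merge_height
    return ModuleSet(region=region, assignments=named, me=me, kme=kme), cfg
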