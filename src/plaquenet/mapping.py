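"""Consensus cell-to-region annotation from multi-sample spatial mappings.

Upstream tools predict, per (cell, ST sample), a spatial coordinate; here
each mapped cell is labeled by the majority region of its ten nearest spots,
samples with extreme gray/white-matter composition are excluded via the
normalized difference metric (n_GM − n_WM)/n_total with retention bounds
[−0.3, 0.9] (boundary inclusive), and each cell receives the region it was
most frequently mapped to across the retained samples. All ties break
lexicographically so results are independent of input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from plaquenet.types import SpotGrid

DEFAULT_SIMPLIFY = {
    "L1": "upper cortical",
    "L2/3": "upper cortical",
    "L3/4": "upper cortical",
    "L3-L5": "lower cortical",
    "L5/6": "lower cortical",
    "L6b": "lower cortical",
    "WM": "WM",
}


def assign_regions_knn(
    cells: pd.DataFrame, grid: SpotGrid, k: int = 10
) -> pd.Series:
    """Label each mapped cell with the modal region of its k nearest spots.

    ``cells`` needs columns cell_id, x_um, y_um. Distance ties at the k-th
    neighbor resolve by spot order (KD-tree order = table order); modal ties
    resolve to the lexicographically smallest region.
    """
    if len(grid) < k:
        import warnings

        warnings.warn(f"only {len(grid)} spots; using k={len(grid)}", stacklevel=2)
        k = len(grid)
    tree = cKDTree(grid.coords)
    regions = grid.spots["region"].to_numpy()
    _, idx = tree.query(cells[["x_um", "y_um"]].to_numpy(float), k=k)
    idx = np.atleast_2d(idx)
    labels = []
    for row in idx:
        counts = pd.Series(regions[row]).value_counts()
        top = counts[counts == counts.max()].index.min()
        labels.append(top)
    return pd.Series(labels, index=cells["cell_id"].to_numpy(), name="region_label")


@dataclass
class SampleComposition:
    sample_id: str
    n_gm: int
    n_wm: int
    n_total: int
    metric: float
    retained: bool = True


def sample_composition(
    grid: SpotGrid, gm_labels: Sequence[str], wm_labels: Sequence[str]
) -> SampleComposition:
    """Normalized GM/WM difference: (n_GM − n_WM) / n_total over all spots."""
    if len(grid) == 0:
        raise ValueError("grid has no spots")
    regions = grid.spots["region"]
    n_gm = int(regions.isin(list(gm_labels)).sum())
    n_wm = int(regions.isin(list(wm_labels)).sum())
    n_total = len(grid)
    return SampleComposition(
        sample_id=str(grid.spots["sample_id"].iloc[0]),
        n_gm=n_gm,
        n_wm=n_wm,
        n_total=n_total,
        metric=(n_gm - n_wm) / n_total,
    )


def filter_samples(
    compositions: Sequence[SampleComposition],
    upper: float = 0.9,
    lower: float = -0.3,
) -> set[str]:
    """Retain samples with lower ≤ metric ≤ upper (strictly-outside excluded)."""
    retained = set()
    for comp in compositions:
        comp.retained = lower <= comp.metric <= upper
        if comp.retained:
            retained.add(comp.sample_id)
    return retained


def consensus_region(
    mappings: pd.DataFrame,
    retained: set[str] | None = None,
    simplify_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Majority vote over retained samples per cell.

    ``mappings`` columns: cell_id, st_sample_id, region_label. Ties break
    lexicographically. Cells with zero retained mappings are reported with
    consensus NaN. Output columns: cell_id, consensus_region, simplified,
    n_votes, n_samples.
    """
    simplify = DEFAULT_SIMPLIFY if simplify_map is None else dict(simplify_map)
    df = mappings
    if retained is not None:
        df = df[df["st_sample_id"].isin(retained)]
    rows = []
    all_cells = pd.unique(mappings["cell_id"])
    votes_by_cell = {c: sub for c, sub in df.groupby("cell_id")}
    for cell in sorted(all_cells):
        sub = votes_by_cell.get(cell)
        if sub is None or len(sub) == 0:
            rows.append((cell, np.nan, np.nan, 0, 0))
            continue
        counts = sub["region_label"].value_counts()
        top = counts[counts == counts.max()].index.min()
        rows.append((cell, top, simplify.get(top, np.nan), int(counts.max()), int(len(sub))))
    return pd.DataFrame(
        rows, columns=["cell_id", "consensus_region", "simplified", "n_votes", "n_samples"]
    )
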