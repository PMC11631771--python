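"""Attribution of spatial DEGs to cell populations via marker tables.

Each spatially differential gene is assigned to the cell population in
whose marker set it appears; among multiple candidate populations the one
with the highest marker effect size wins (exact ties break to the
lexicographically smallest population); genes in no marker set get "none".
Per (region, direction) the population proportions of the assigned DEGs
are summarized.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from plaquenet.types import ValidationError

NONE_LABEL = "none"


def deconvolve_degs(
    degs: pd.DataFrame,
    markers: pd.DataFrame,
    effect_column: str = "avg_log2FC",
    marker_fdr_max: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign DEGs to populations and summarize proportions.

    ``degs`` columns: gene, unit (spatial region), avg_log2FC (direction =
    its sign); ``markers`` columns: gene, population, ``effect_column``
    (optionally fdr, filtered when ``marker_fdr_max`` is set). Returns
    (per-DEG assignment table, per-(unit, direction) proportion table whose
    proportions sum to 1).
    """
    if len(degs) == 0 or len(markers) == 0:
        raise ValueError("degs and markers must be non-empty")
    if markers.duplicated(subset=["gene", "population"]).any():
        raise ValidationError("duplicate (gene, population) marker row")
    mk = markers
    if marker_fdr_max is not None:
        mk = mk[mk["fdr"] <= marker_fdr_max]

    best: dict[str, str] = {}
    for gene, sub in mk.groupby("gene"):
        top = sub[effect_column].max()
        best[gene] = sub.loc[sub[effect_column] == top, "population"].min()

    assigned = degs.copy()
    assigned["population"] = assigned["gene"].map(best).fillna(NONE_LABEL)
    assigned["direction"] = np.sign(assigned["avg_log2FC"]).astype(int)

    rows = []
    for (unit, direction), sub in assigned.groupby(["unit", "direction"]):
        counts = sub["population"].value_counts()
        total = counts.sum()
        for pop in sorted(counts.index):
            rows.append((unit, int(direction), pop, int(counts[pop]), counts[pop] / total))
    proportions = pd.DataFrame(
        rows, columns=["unit", "direction", "population", "n_degs", "proportion"]
    )
    return assigned, proportions
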