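"""Synthetic data with planted ground truth.

Generates every input the pipeline consumes: a hexagonal Visium-style
lattice (55 μm spots on a 100 μm pitch by default), clustered amyloid
binaries, negative-binomial UMI counts with region-restricted co-expression
modules and amyloid-responsive genes, and noisy multi-sample cell-to-region
mappings. Ground truth (module membership, amyloid coefficients, true cell
regions) is recorded so downstream recovery is testable.

Count model, per gene g and spot s:

    mu_gs = L_s * exp(alpha_g + lambda_g * f_m(g) * 1[s in home region of m(g)]
                      + beta_g * a_s)

where ``L_s`` is a log-normal library-size factor, ``f_m`` a per-module
latent factor drawn once per generator call (one call = one sample) and
applied to all spots of the module's home region, ``a_s`` the standardized
per-spot total amyloid area (the same score the downstream caller regresses
on) and ``beta_g`` the planted amyloid coefficient. Counts are negative
binomial with size ``nb_dispersion``. A shared per-sample factor — rather
than an i.i.d. per-spot one — is what makes module genes covary across
samples after pseudobulk summation, which is where the networks are built.

Each generator takes an explicit seed (defaulting to the config's) and uses
a single local :class:`numpy.random.Generator`; there is no hidden global
state, and identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from plaquenet.types import AmyloidBinaryTable, CountsTable, SpotGrid, BINARY_COLUMNS

DEFAULT_REGIONS = ("L1", "L2/3", "L3/4", "L3-L5", "L5/6", "L6b", "WM")

ROW_PITCH = math.sqrt(3.0) / 2.0  # hex lattice: row spacing / column pitch


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with defaults defining its conditions."""

    seed: int = 0
    # lattice
    n_rows: int = 20
    n_cols: int = 20
    spacing_um: float = 100.0
    diameter_um: float = 55.0
    region_layout: tuple[str, ...] = DEFAULT_REGIONS
    # expression
    n_genes: int = 200
    n_modules: int = 2
    module_size: int = 60
    factor_sd: float = 1.0
    module_loading: float = 1.0
    gene_log_mean: float | tuple[float, ...] = math.log(5.0)  # scalar or per gene
    nb_dispersion: float = 10.0
    libsize_logmean: float = 0.0
    libsize_logsd: float = 0.3
    amyloid_beta: tuple[float, ...] | None = None  # per gene; None = all zero
    # amyloid point process
    n_amyloid_centers: int = 5
    binaries_per_center: int = 30
    center_spread_um: float = 150.0
    area_logmean: float = math.log(50.0)
    area_logsd: float = 0.6

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice dimensions must be >= 1")
        if not (self.spacing_um > self.diameter_um > 0):
            raise ValueError("need spacing_um > diameter_um > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.module_size < 2:
            raise ValueError("module_size must be >= 2")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules exceed n_genes")
        for name in ("factor_sd", "module_loading", "libsize_logmean",
                     "libsize_logsd", "center_spread_um", "area_logmean",
                     "area_logsd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if np.ndim(self.gene_log_mean) > 0:
            self.gene_log_mean = tuple(float(v) for v in self.gene_log_mean)
            if len(self.gene_log_mean) != self.n_genes:
                raise ValueError("per-gene gene_log_mean must have length n_genes")
        if not np.all(np.isfinite(np.atleast_1d(self.gene_log_mean))):
            raise ValueError("gene_log_mean must be finite")
        if self.amyloid_beta is not None:
            self.amyloid_beta = tuple(float(b) for b in self.amyloid_beta)
            if len(self.amyloid_beta) != self.n_genes:
                raise ValueError("amyloid_beta length must equal n_genes")
        self.region_layout = tuple(self.region_layout)

    def beta_vector(self) -> np.ndarray:
        if self.amyloid_beta is None:
            return np.zeros(self.n_genes)
        return np.asarray(self.amyloid_beta, float)

    def log_mean_vector(self) -> np.ndarray:
        return np.broadcast_to(
            np.atleast_1d(np.asarray(self.gene_log_mean, float)), (self.n_genes,)
        ).copy()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(self).items()}
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators."""

    gene_module: dict[str, str] = field(default_factory=dict)
    gene_beta: dict[str, float] = field(default_factory=dict)
    module_region: dict[str, str] = field(default_factory=dict)
    cell_region: dict[str, str] = field(default_factory=dict)
    binary_center: dict[int, int] = field(default_factory=dict)
    amyloid_score: pd.Series | None = None  # the a_s field used in simulation


def make_hex_grid(config: SimulationConfig, sample_id: str = "S1") -> SpotGrid:
    """Triangular lattice: odd rows offset by half a pitch, rows √3/2 apart.

    All six nearest-neighbor center distances equal ``spacing_um`` exactly.
    Region labels are assigned from ``region_layout`` by contiguous row band.
    """
    rows = np.repeat(np.arange(config.n_rows), config.n_cols)
    cols = np.tile(np.arange(config.n_cols), config.n_rows)
    x = cols * config.spacing_um + (rows % 2) * (config.spacing_um / 2.0)
    y = rows * config.spacing_um * ROW_PITCH
    bands = np.array_split(np.arange(config.n_rows), len(config.region_layout))
    row_region = {}
    for label, band in zip(config.region_layout, bands):
        for r in band:
            row_region[int(r)] = label
    spots = pd.DataFrame(
        {
            "spot_id": [f"{sample_id}-R{r:03d}C{c:03d}" for r, c in zip(rows, cols)],
            "array_row": rows,
            "array_col": cols,
            "x_um": x,
            "y_um": y,
            "region": [row_region[int(r)] for r in rows],
            "sample_id": sample_id,
        }
    )
    return SpotGrid(spots, spacing_um=config.spacing_um, diameter_um=config.diameter_um)


def simulate_amyloid_binaries(
    grid: SpotGrid,
    config: SimulationConfig,
    stain: str = "AmyloGlo",
    seed: int | None = None,
    truth: GroundTruth | None = None,
) -> AmyloidBinaryTable:
    """Clustered amyloid objects: uniform cluster centers over the grid's
    bounding box, isotropic Gaussian displacement (sd ``center_spread_um``),
    log-normal areas, diameter = 2·sqrt(area/π)."""
    if len(grid) == 0:
        raise ValueError("grid is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_amyloid_centers * config.binaries_per_center
    if n == 0:
        empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
            BINARY_COLUMNS, [str, float, float, float, float, str])})
        return AmyloidBinaryTable(empty)
    xy = grid.coords
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    centers = rng.uniform(lo, hi, size=(config.n_amyloid_centers, 2))
    center_idx = np.repeat(np.arange(config.n_amyloid_centers), config.binaries_per_center)
    disp = rng.normal(0.0, config.center_spread_um, size=(n, 2))
    pos = centers[center_idx] + disp
    area = rng.lognormal(config.area_logmean, config.area_logsd, size=n)
    sample_id = grid.spots["sample_id"].iloc[0]
    table = pd.DataFrame(
        {
            "stain": stain,
            "x_um": pos[:, 0],
            "y_um": pos[:, 1],
            "area_um2": area,
            "diameter_um": 2.0 * np.sqrt(area / math.pi),
            "sample_id": sample_id,
        }
    )
    if truth is not None:
        truth.binary_center = {int(i): int(c) for i, c in enumerate(center_idx)}
    return AmyloidBinaryTable(table)


def _standardized_area_score(grid: SpotGrid, binaries: AmyloidBinaryTable) -> pd.Series:
    """Per-spot total amyloid area via the same intersection rule the caller
    uses, standardized to zero mean / unit sd (zeros if constant)."""
    from plaquenet.amyloid import score_spots

    score = score_spots(grid, binaries)["total_area_um2"]
    sd = score.std(ddof=0)
    if sd == 0:
        return pd.Series(0.0, index=score.index)
    return (score - score.mean()) / sd


def planted_gene_table(config: SimulationConfig) -> pd.DataFrame:
    """Gene ids, module membership and home regions implied by a config.

    Genes are named g0000..; the first ``n_modules * module_size`` genes form
    contiguous planted modules; module m's home region is
    ``region_layout[m mod n_regions]``.
    """
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    module = np.array([""] * config.n_genes, dtype=object)
    region = np.array([""] * config.n_genes, dtype=object)
    for m in range(config.n_modules):
        sl = slice(m * config.module_size, (m + 1) * config.module_size)
        module[sl] = f"M{m + 1}"
        region[sl] = config.region_layout[m % len(config.region_layout)]
    return pd.DataFrame({"gene": genes, "module": module, "home_region": region})


def simulate_counts(
    grid: SpotGrid,
    binaries: AmyloidBinaryTable,
    config: SimulationConfig,
    truth: GroundTruth | None = None,
    seed: int | None = None,
) -> CountsTable:
    """Negative-binomial UMI counts under the log-linear model above."""
    if len(grid) == 0:
        raise ValueError("grid is empty")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_spots = len(grid)
    gene_tab = planted_gene_table(config)
    beta = config.beta_vector()

    a_s = _standardized_area_score(grid, binaries).to_numpy()
    lib = np.exp(rng.normal(config.libsize_logmean, config.libsize_logsd, size=n_spots))
    factors = rng.normal(0.0, config.factor_sd, size=config.n_modules)

    log_mu = np.repeat(config.log_mean_vector()[:, None], n_spots, axis=1)
    region = grid.spots["region"].to_numpy()
    for m in range(config.n_modules):
        sl = slice(m * config.module_size, (m + 1) * config.module_size)
        home = config.region_layout[m % len(config.region_layout)]
        log_mu[sl, region == home] += config.module_loading * factors[m]
    log_mu += np.outer(beta, a_s)
    mu = lib[None, :] * np.exp(log_mu)

    theta = config.nb_dispersion
    p = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p)

    if truth is not None:
        for _, row in gene_tab.iterrows():
            if row["module"]:
                truth.gene_module[row["gene"]] = row["module"]
                truth.module_region[row["module"]] = row["home_region"]
        truth.gene_beta = dict(zip(gene_tab["gene"], beta))
        truth.amyloid_score = pd.Series(a_s, index=grid.spot_ids, name="amyloid_score")

    sample_id = grid.spots["sample_id"].iloc[0]
    meta = pd.DataFrame({"sample_id": [sample_id]}).set_index("sample_id")
    return CountsTable(
        gene_ids=pd.Index(gene_tab["gene"]),
        spot_ids=grid.spot_ids,
        values=counts,
        sample_ids=pd.Series(sample_id, index=grid.spot_ids),
        sample_meta=meta,
    )


@dataclass
class SampleData:
    """One simulated sample: lattice, binaries, counts and its truth."""

    grid: SpotGrid
    binaries: AmyloidBinaryTable
    counts: CountsTable
    truth: GroundTruth


def simulate_sample(
    config: SimulationConfig, sample_id: str = "S1", seed: int | None = None
) -> SampleData:
    """Generate a coherent (grid, binaries, counts, truth) tuple for one sample."""
    base = config.seed if seed is None else seed
    truth = GroundTruth()
    grid = make_hex_grid(config, sample_id=sample_id)
    binaries = simulate_amyloid_binaries(grid, config, seed=base, truth=truth)
    counts = simulate_counts(grid, binaries, config, truth=truth, seed=base + 1)
    return SampleData(grid=grid, binaries=binaries, counts=counts, truth=truth)


def simulate_cohort(config: SimulationConfig, n_samples: int) -> list[SampleData]:
    """Independent samples S1..Sn with seeds derived from the config seed."""
    return [
        simulate_sample(config, sample_id=f"S{i + 1}", seed=config.seed + 1000 * i)
        for i in range(n_samples)
    ]


def combine_samples(samples: Sequence[SampleData]) -> tuple[CountsTable, pd.Series, pd.Series]:
    """Stack a cohort into one CountsTable plus aligned per-spot region and
    amyloid-score series (scores standardized within each sample)."""
    vals = np.hstack([s.counts.values for s in samples])
    spot_ids = pd.Index(np.concatenate([s.counts.spot_ids for s in samples]))
    sids = np.concatenate([np.asarray(s.counts.sample_ids) for s in samples])
    meta = pd.concat([s.counts.sample_meta for s in samples])
    counts = CountsTable(samples[0].counts.gene_ids, spot_ids, vals, sids, meta)
    regions = pd.Series(
        np.concatenate([s.grid.spots["region"].to_numpy() for s in samples]), index=spot_ids
    )
    scores = pd.concat([s.truth.amyloid_score for s in samples])
    return counts, regions, scores


def simulate_cell_mappings(
    true_regions: Mapping[str, str],
    n_samples: int,
    flip_prob: float,
    seed: int,
    region_universe: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Noisy per-sample region labels: each (cell, sample) keeps the true
    region with probability 1 − flip_prob, else draws uniformly from the
    other regions."""
    if not (0.0 <= flip_prob <= 1.0):
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    regions = sorted(set(region_universe) if region_universe is not None
                     else set(true_regions.values()))
    cells = list(true_regions)
    rows = []
    for s in range(n_samples):
        sid = f"ST{s + 1}"
        flips = rng.random(len(cells)) < flip_prob
        for cell, flip in zip(cells, flips):
            true = true_regions[cell]
            if flip and len(regions) > 1:
                others = [r for r in regions if r != true]
                label = others[rng.integers(len(others))]
            else:
                label = true
            rows.append((cell, sid, label))
    return pd.DataFrame(rows, columns=["cell_id", "st_sample_id", "region_label"])
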