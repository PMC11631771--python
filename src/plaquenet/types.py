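"""Core in-memory containers shared across the pipeline.

Coordinates are micrometers everywhere; pixel-to-μm conversion happens only
at ingest (see :mod:`plaquenet.io`). Count matrices are oriented genes ×
spots internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant (readers reject, never repair)."""


class DegenerateFieldError(ValueError):
    """A score field is constant, so a spatial z-statistic is undefined.

    Raised (rather than returning NaN) so callers can skip a stain or
    sample explicitly — e.g. wild-type mouse sections with no amyloid.
    """


SPOT_COLUMNS = ["spot_id", "array_row", "array_col", "x_um", "y_um", "region", "sample_id"]
BINARY_COLUMNS = ["stain", "x_um", "y_um", "area_um2", "diameter_um", "sample_id"]


@dataclass
class SpotGrid:
    """Hexagonal spot lattice for one sample.

    ``spots`` columns: spot_id, array_row, array_col, x_um, y_um, region,
    sample_id. Spot diameter must be smaller than the lattice pitch.
    """

    spots: pd.DataFrame
    spacing_um: float = 100.0
    diameter_um: float = 55.0

    def __post_init__(self) -> None:
        missing = [c for c in SPOT_COLUMNS if c not in self.spots.columns]
        if missing:
            raise FormatError(f"spot table missing column(s): {', '.join(missing)}")
        if not (self.spacing_um > self.diameter_um > 0):
            raise ValidationError(
                f"need spacing_um > diameter_um > 0, got {self.spacing_um}, {self.diameter_um}"
            )
        if self.spots["spot_id"].duplicated().any():
            dup = self.spots.loc[self.spots["spot_id"].duplicated(), "spot_id"].iloc[0]
            raise ValidationError(f"duplicate spot barcode: {dup!r}")
        xy = self.spots[["x_um", "y_um"]].to_numpy(float)
        if not np.isfinite(xy).all():
            raise ValidationError("non-finite spot coordinate")

    def __len__(self) -> int:
        return len(self.spots)

    @property
    def spot_ids(self) -> pd.Index:
        return pd.Index(self.spots["spot_id"])

    @property
    def coords(self) -> np.ndarray:
        """Spot centers, shape (n_spots, 2), μm."""
        return self.spots[["x_um", "y_um"]].to_numpy(float)


@dataclass
class CountsTable:
    """UMI counts, genes × spots, with per-sample metadata.

    ``values`` is a dense non-negative integer matrix (the pipeline's gene
    panels are small enough that sparsity buys nothing); ``sample_meta`` is
    one row per sample (diagnosis, sex, PMI, RIN, batch — whatever is
    available) and may be empty.
    """

    gene_ids: pd.Index
    spot_ids: pd.Index
    values: np.ndarray
    sample_ids: pd.Series  # per spot, aligned to spot_ids
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.gene_ids = pd.Index(self.gene_ids)
        self.spot_ids = pd.Index(self.spot_ids)
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.gene_ids), len(self.spot_ids)):
            raise ValidationError(
                f"counts shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.spot_ids)} spots"
            )
        if self.gene_ids.duplicated().any():
            raise ValidationError("duplicate gene identifier")
        if self.spot_ids.duplicated().any():
            raise ValidationError("duplicate spot identifier")
        if np.issubdtype(self.values.dtype, np.floating):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValidationError("counts must be integers")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise ValidationError("negative count entry")
        self.sample_ids = pd.Series(
            np.asarray(self.sample_ids), index=self.spot_ids, name="sample_id"
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_spots(self) -> int:
        return len(self.spot_ids)

    def total_umi(self) -> pd.Series:
        """Per-spot total UMI, recomputed from the matrix."""
        return pd.Series(self.values.sum(axis=0), index=self.spot_ids, name="total_umi")

    def to_anndata(self):
        """Convenience export (spots × genes, the single-cell convention)."""
        import anndata as ad

        obs = pd.DataFrame({"sample_id": self.sample_ids.to_numpy()}, index=self.spot_ids)
        return ad.AnnData(
            X=self.values.T.astype(np.float32),
            obs=obs,
            var=pd.DataFrame(index=self.gene_ids),
        )


STAINS = ("AmyloGlo", "OC")


@dataclass
class AmyloidBinaryTable:
    """Segmented amyloid objects for one sample: stain, center, area, diameter."""

    binaries: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in BINARY_COLUMNS if c not in self.binaries.columns]
        if missing:
            raise FormatError(f"binary table missing column(s): {', '.join(missing)}")
        bad_stain = set(self.binaries["stain"]) - set(STAINS)
        if bad_stain:
            raise ValidationError(f"unknown stain label(s): {sorted(bad_stain)}")
        area = self.binaries["area_um2"].to_numpy(float)
        diam = self.binaries["diameter_um"].to_numpy(float)
        if (area <= 0).any():
            row = int(np.flatnonzero(area <= 0)[0])
            raise ValidationError(f"non-positive area at row {row}")
        if (diam <= 0).any():
            row = int(np.flatnonzero(diam <= 0)[0])
            raise ValidationError(f"non-positive diameter at row {row}")

    def __len__(self) -> int:
        return len(self.binaries)

    def for_stain(self, stain: str) -> "AmyloidBinaryTable":
        if stain not in STAINS:
            raise ValueError(f"stain must be one of {STAINS}")
        return AmyloidBinaryTable(self.binaries[self.binaries["stain"] == stain].reset_index(drop=True))
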