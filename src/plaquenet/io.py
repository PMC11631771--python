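"""Readers and writers for every on-disk format the pipeline touches.

Formats: 10x-style tissue-positions CSV (internal headered dialect, plus
auto-detection of the headerless ``tissue_positions_list.csv`` pixel dialect
given a pixels-per-μm scale), MatrixMarket counts with gene/barcode sidecar
files, amyloid-binary CSV exports (NIS-Elements header remapping supported),
and plain TSV results. Readers reject malformed input rather than repairing
it; every writer round-trips through its paired reader.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from plaquenet.types import (
    AmyloidBinaryTable,
    CountsTable,
    FormatError,
    SpotGrid,
    ValidationError,
    BINARY_COLUMNS,
)

POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um"]


def read_tissue_positions(
    path: str | Path,
    spacing_um: float = 100.0,
    diameter_um: float = 55.0,
    sample_id: str | None = None,
    region_column: str = "region",
    pixels_per_um: float | None = None,
) -> SpotGrid:
    """Read a positions CSV; only ``in_tissue == 1`` rows are retained.

    A headerless 10x ``tissue_positions_list`` (barcode, in_tissue,
    array_row, array_col, pxl_row, pxl_col) is auto-detected and converted
    to μm, which requires ``pixels_per_um``.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if "barcode" in first:
        df = pd.read_csv(path)
        missing = [c for c in POSITION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"{path.name}: missing column(s): {', '.join(missing)}")
    else:
        if pixels_per_um is None:
            raise FormatError(
                f"{path.name}: headerless 10x positions file requires pixels_per_um"
            )
        df = pd.read_csv(
            path,
            header=None,
            names=["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"],
        )
        df["x_um"] = df["pxl_col"] / pixels_per_um
        df["y_um"] = df["pxl_row"] / pixels_per_um
        df = df.drop(columns=["pxl_row", "pxl_col"])
    df = df[df["in_tissue"] == 1].reset_index(drop=True)
    if df["barcode"].duplicated().any():
        dup = df.loc[df["barcode"].duplicated(), "barcode"].iloc[0]
        raise ValidationError(f"{path.name}: duplicate barcode {dup!r}")
    sid = sample_id if sample_id is not None else path.stem
    spots = pd.DataFrame(
        {
            "spot_id": df["barcode"],
            "array_row": df["array_row"].astype(int),
            "array_col": df["array_col"].astype(int),
            "x_um": df["x_um"].astype(float),
            "y_um": df["y_um"].astype(float),
            "region": df[region_column] if region_column in df.columns else "NA",
            "sample_id": df["sample_id"] if "sample_id" in df.columns else sid,
        }
    )
    return SpotGrid(spots, spacing_um=spacing_um, diameter_um=diameter_um)


def write_tissue_positions(grid: SpotGrid, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "barcode": grid.spots["spot_id"],
            "in_tissue": 1,
            "array_row": grid.spots["array_row"],
            "array_col": grid.spots["array_col"],
            "x_um": grid.spots["x_um"],
            "y_um": grid.spots["y_um"],
            "region": grid.spots["region"],
            "sample_id": grid.spots["sample_id"],
        }
    )
    out.to_csv(path, index=False, float_format="%.10g")


def read_counts_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    sample_ids: pd.Series | Mapping[str, str] | None = None,
    sample_meta: pd.DataFrame | None = None,
) -> CountsTable:
    """MatrixMarket triplets (genes × spots) with one-column sidecar files."""
    matrix_path = Path(matrix_path)
    try:
        mat = scipy.io.mmread(matrix_path)
    except Exception as exc:  # noqa: BLE001 - scipy raises bare ValueError
        raise FormatError(f"{matrix_path.name}: not valid MatrixMarket: {exc}") from exc
    mat = scipy.sparse.coo_matrix(mat)
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str)
    if mat.shape == (len(barcodes), len(genes)) and mat.shape[0] != mat.shape[1]:
        mat = mat.T  # spots × genes on disk; internal orientation is genes × spots
    if mat.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{matrix_path.name}: matrix is {mat.shape} but sidecars give "
            f"{len(genes)} genes × {len(barcodes)} barcodes"
        )
    if (mat.data < 0).any():
        raise ValidationError(f"{matrix_path.name}: negative count value")
    dense = np.asarray(mat.todense())
    if sample_ids is None:
        sids = pd.Series("S1", index=pd.Index(barcodes))
    else:
        sids = pd.Series(sample_ids)
        sids = sids.reindex(barcodes)
    return CountsTable(
        gene_ids=pd.Index(genes),
        spot_ids=pd.Index(barcodes),
        values=dense,
        sample_ids=sids,
        sample_meta=sample_meta if sample_meta is not None else pd.DataFrame(),
    )


def write_counts_mtx(
    counts: CountsTable,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    sparse = scipy.sparse.coo_matrix(counts.values)
    scipy.io.mmwrite(str(matrix_path), sparse, field="integer")
    pd.Series(counts.gene_ids).to_csv(genes_path, sep="\t", index=False, header=False)
    pd.Series(counts.spot_ids).to_csv(barcodes_path, sep="\t", index=False, header=False)


DEFAULT_BINARY_COLUMN_MAP = {
    "stain": "stain",
    "x_um": "x_um",
    "y_um": "y_um",
    "area_um2": "area_um2",
    "diameter_um": "diameter_um",
    "sample_id": "sample_id",
}


def read_binaries_csv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    stain: str | None = None,
    sample_id: str | None = None,
) -> AmyloidBinaryTable:
    """Amyloid binary CSV; ``column_map`` maps internal names to the file's
    headers (NIS-Elements exports use e.g. "Center X"). ``stain`` /
    ``sample_id`` fill those fields when the export lacks the column."""
    path = Path(path)
    cmap = dict(DEFAULT_BINARY_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    out = {}
    for internal in BINARY_COLUMNS:
        src = cmap[internal]
        if src in df.columns:
            out[internal] = df[src]
        elif internal == "stain" and stain is not None:
            out[internal] = stain
        elif internal == "sample_id" and sample_id is not None:
            out[internal] = sample_id
        else:
            raise FormatError(f"{path.name}: missing column {src!r} (for {internal})")
    table = pd.DataFrame(out)
    area = table["area_um2"].to_numpy(float)
    if (area <= 0).any():
        row = int(np.flatnonzero(area <= 0)[0])
        raise ValidationError(f"{path.name}: non-positive area at data row {row}")
    return AmyloidBinaryTable(table)


def write_binaries_csv(binaries: AmyloidBinaryTable, path: str | Path) -> None:
    binaries.binaries[BINARY_COLUMNS].to_csv(path, index=False, float_format="%.10g")


def write_results_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Plain TSV with header, fixed column order as given, no index."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g",
                 quoting=csv.QUOTE_MINIMAL)


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fixture(directory: str | Path, sample) -> dict[str, Path]:
    """Write one simulated sample as the full on-disk fixture set."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "positions": directory / "tissue_positions.csv",
        "matrix": directory / "matrix.mtx",
        "genes": directory / "genes.tsv",
        "barcodes": directory / "barcodes.tsv",
        "binaries": directory / "binaries.csv",
        "truth_modules": directory / "truth_gene_modules.tsv",
        "truth_beta": directory / "truth_gene_beta.tsv",
    }
    write_tissue_positions(sample.grid, paths["positions"])
    write_counts_mtx(sample.counts, paths["matrix"], paths["genes"], paths["barcodes"])
    write_binaries_csv(sample.binaries, paths["binaries"])
    truth = sample.truth
    write_results_tsv(
        pd.DataFrame(sorted(truth.gene_module.items()), columns=["gene", "module"]),
        paths["truth_modules"],
    )
    write_results_tsv(
        pd.DataFrame(sorted(truth.gene_beta.items()), columns=["gene", "beta"]),
        paths["truth_beta"],
    )
    return paths
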