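"""Readers, writers and the shared data model.

All tabular formats are plain tab-delimited text with headers; sequences are
FASTA. Readers validate and reject malformed input rather than repairing it,
and every error message names the offending record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

# Controlled vocabularies --------------------------------------------------

#: depth layers for isolates (photic pools surface + DCM)
ISOLATE_LAYERS = frozenset({"PHOTIC", "MESO", "BATHY"})
#: depth layers for amplicon samples
SAMPLE_LAYERS = frozenset({"SRF", "DCM", "MESO", "BATHY"})
#: plankton size fractions (µm), including the pooled particle fraction
SIZE_FRACTIONS = frozenset({"0.2-0.8", "0.8-3", "3-5", "5-20", "20-200", "0.8-20"})

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS_DNA = frozenset("ACGT")


class FormatError(ValueError):
    """Malformed or contract-violating input."""


# Records ------------------------------------------------------------------


@dataclass(frozen=True)
class IsolateRecord:
    """One cultured strain: a partial 16S sequence plus provenance."""

    isolate_id: str
    sequence: str
    station_id: str = ""
    layer: str | None = None
    genus: str | None = None
    medium: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"isolate {self.isolate_id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"isolate {self.isolate_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.layer is not None and self.layer not in ISOLATE_LAYERS:
            raise FormatError(
                f"isolate {self.isolate_id!r}: layer {self.layer!r} not in "
                f"{sorted(ISOLATE_LAYERS)}"
            )


@dataclass(frozen=True)
class ASVRecord:
    """A denoised amplicon sequence variant (zero-radius OTU)."""

    asv_id: str
    sequence: str
    taxonomy: str | None = None  # semicolon-separated ranks, domain..genus

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"ASV {self.asv_id!r}: empty sequence")
        bad = set(self.sequence) - UNAMBIGUOUS_DNA
        if bad:
            raise FormatError(
                f"ASV {self.asv_id!r}: ambiguous/invalid characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class StationCounts:
    """Plate counts and cytometry counts for one station."""

    station_id: str
    layer: str
    cfu_per_ml: float
    cells_per_ml: float

    def __post_init__(self) -> None:
        if self.cfu_per_ml < 0:
            raise FormatError(f"station {self.station_id!r}: negative cfu/ml")
        if self.cells_per_ml <= 0:
            raise FormatError(f"station {self.station_id!r}: cells/ml must be > 0")


@dataclass
class AbundanceTable:
    """Integer read counts, samples as rows and ASVs as columns."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicated sample id {dup!r}")
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise FormatError(f"duplicated ASV id {dup!r}")
        arr = df.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.integer):
            if np.isnan(arr.astype(float)).any():
                raise FormatError("missing count cell")
            if np.any(arr.astype(float) % 1 != 0):
                raise FormatError("non-integer count")
            self.counts = df = df.astype(np.int64)
        if arr.size and (df.to_numpy() < 0).any():
            raise FormatError("negative count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    def row_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def drop_empty_samples(self) -> "AbundanceTable":
        keep = self.counts.sum(axis=1) > 0
        return AbundanceTable(self.counts.loc[keep])


# FASTA --------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA into ordered (id, sequence) pairs.

    The id is the header token before the first whitespace; sequences are
    uppercased and U is normalised to T. Duplicate ids and empty sequences
    are hard errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r}: empty sequence")
        seen.add(rec.id)
        records.append((rec.id, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_isolate_fasta(path: str | Path) -> dict[str, str]:
    """FASTA of isolate partial 16S sequences, keyed by isolate id."""
    return dict(read_fasta(path))


def read_asv_fasta(path: str | Path, taxonomy: dict[str, str] | None = None) -> list[ASVRecord]:
    taxonomy = taxonomy or {}
    return [ASVRecord(i, s, taxonomy.get(i)) for i, s in read_fasta(path)]


# Count table ----------------------------------------------------------------


def read_count_table(path: str | Path, asv_rows: bool = True) -> AbundanceTable:
    """Read a tab-delimited count table.

    Orientation is declared, never guessed: with ``asv_rows=True`` (default)
    the first column holds ASV ids and the remaining columns are samples;
    with ``asv_rows=False`` the layout is transposed.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    col_ids = header[1:]
    if len(set(col_ids)) != len(col_ids):
        dup = next(c for c in col_ids if col_ids.count(c) > 1)
        raise FormatError(f"duplicated column id {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    df.columns = col_ids
    if df.isna().any().any():
        raise FormatError("missing count cell")
    df = df.T if asv_rows else df
    df.index.name = None
    df.columns.name = None
    return AbundanceTable(df)


def write_count_table(table: AbundanceTable, path: str | Path, asv_rows: bool = True) -> None:
    df = table.counts.T if asv_rows else table.counts
    df.to_csv(path, sep="\t", index_label="asv_id" if asv_rows else "sample_id")


# Metadata tables ------------------------------------------------------------

_SAMPLE_COLS = ["sample_id", "dataset", "layer", "size_fraction", "station_id"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def read_sample_metadata(path: str | Path | io.StringIO) -> pd.DataFrame:
    """Per-sample metadata, indexed by sample_id.

    Columns: dataset, layer (SRF/DCM/MESO/BATHY), size_fraction (µm label or
    empty), station_id.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, _SAMPLE_COLS, "sample metadata")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicated sample id {dup!r}")
    for _, row in df.iterrows():
        if row["layer"] not in SAMPLE_LAYERS:
            raise FormatError(
                f"sample {row['sample_id']!r}: layer {row['layer']!r} not in "
                f"{sorted(SAMPLE_LAYERS)}"
            )
        if row["size_fraction"] and row["size_fraction"] not in SIZE_FRACTIONS:
            raise FormatError(
                f"sample {row['sample_id']!r}: size fraction "
                f"{row['size_fraction']!r} not in {sorted(SIZE_FRACTIONS)}"
            )
    return df.set_index("sample_id")


def check_metadata_covers(table: AbundanceTable, meta: pd.DataFrame) -> None:
    """Every sample in the count table must carry exactly one metadata row."""
    missing = [s for s in table.sample_ids if s not in meta.index]
    if missing:
        raise FormatError(f"samples missing from metadata: {missing}")


def read_isolate_metadata(path: str | Path | io.StringIO) -> pd.DataFrame:
    """Per-isolate metadata (station_id, layer, genus, medium), indexed by isolate_id."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    _require_columns(df, ["isolate_id", "station_id", "layer"], "isolate metadata")
    if df["isolate_id"].duplicated().any():
        dup = df.loc[df["isolate_id"].duplicated(), "isolate_id"].iloc[0]
        raise FormatError(f"duplicated isolate id {dup!r}")
    for _, row in df.iterrows():
        if row["layer"] and row["layer"] not in ISOLATE_LAYERS:
            raise FormatError(
                f"isolate {row['isolate_id']!r}: layer {row['layer']!r} not in "
                f"{sorted(ISOLATE_LAYERS)}"
            )
    return df.set_index("isolate_id")


def load_isolates(fasta_path: str | Path, meta_path: str | Path) -> list[IsolateRecord]:
    """Join an isolate FASTA with its metadata table into IsolateRecords."""
    seqs = read_isolate_fasta(fasta_path)
    meta = read_isolate_metadata(meta_path)
    records = []
    for iso_id, seq in seqs.items():
        if iso_id not in meta.index:
            raise FormatError(f"isolate {iso_id!r} absent from metadata")
        row = meta.loc[iso_id]
        records.append(
            IsolateRecord(
                isolate_id=iso_id,
                sequence=seq,
                station_id=row["station_id"],
                layer=row["layer"] or None,
                genus=row.get("genus", "") or None,
                medium=row.get("medium", "") or None,
            )
        )
    return records


def read_station_counts(path: str | Path | io.StringIO) -> list[StationCounts]:
    """Per-station cfu/ml and cells/ml pairs."""
    df = pd.read_csv(path, sep="\t", dtype={"station_id": str, "layer": str})
    _require_columns(df, ["station_id", "layer", "cfu_per_ml", "cells_per_ml"], "station counts")
    return [
        StationCounts(r.station_id, r.layer, float(r.cfu_per_ml), float(r.cells_per_ml))
        for r in df.itertuples()
    ]


def read_copy_numbers(path: str | Path | io.StringIO) -> pd.Series:
    """Per-genus rRNA operon copy numbers (all >= 1), as a Series."""
    df = pd.read_csv(path, sep="\t", dtype={"genus": str})
    _require_columns(df, ["genus", "copy_number"], "copy-number table")
    if df["genus"].duplicated().any():
        dup = df.loc[df["genus"].duplicated(), "genus"].iloc[0]
        raise FormatError(f"duplicated genus {dup!r}")
    ser = df.set_index("genus")["copy_number"].astype(float)
    if (ser < 1).any():
        bad = ser.index[ser < 1][0]
        raise FormatError(f"genus {bad!r}: copy number < 1")
    return ser


def median_copy_number(copy_numbers: pd.Series) -> float:
    """Median over represented genera (midpoint rule for even counts)."""
    return float(np.median(copy_numbers.to_numpy()))
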