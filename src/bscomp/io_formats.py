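"""Readers and writers for the external formats the pipeline touches.

Conventions fixed here and relied on everywhere else:

* coordinates are 0-based half-open internally; 1-based formats (GFF3) are
  converted at the boundary;
* sequences are uppercase DNA over ``ACGTN``; RNA input (``U``) is mapped to
  ``T`` on read;
* tables are tab-separated with a header row and ``NA`` as the missing-value
  token.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"

_RNA_TO_DNA = str.maketrans("Uu", "Tt")

#: required columns of a per-contrast splicing event table
CONTRAST_COLUMNS = ["event_id", "gene_id", "event_type", "dpsi", "mv_dpsi95"]

#: required columns of a normalized-spectral-count (DDA proteomics) table
NSC_CHANNELS = ["NE", "WT", "upDEL", "dnDEL", "2xDEL", "APT"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class IntronRecord:
    """A genomic intron in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    intron_id: str
    group: str = "none"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"intron {self.intron_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"intron {self.intron_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GenomeSequence:
    """In-memory genome: mapping from sequence name to uppercase DNA."""

    sequences: dict[str, str] = field(default_factory=dict)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self.sequences:
            raise KeyError(f"unknown sequence {chrom!r}")
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"window {chrom}:{start}-{end} out of range (length {len(seq)})"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def normalize_sequence(seq: str) -> str:
    """Uppercase and map RNA U to DNA T."""
    return seq.translate(_RNA_TO_DNA).upper()


def load_fasta(path: str | Path) -> GenomeSequence:
    """Load a FASTA file into memory.

    Sequence names are the first whitespace-delimited token of each header;
    duplicate names and empty files are errors.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    sequences[name] = normalize_sequence("".join(chunks))
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header")
                if name in sequences:
                    raise FormatError(f"{path}: duplicate sequence name {name!r}")
                chunks = []
            elif line:
                if name is None:
                    raise FormatError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    if name is not None:
        if name in sequences:
            raise FormatError(f"{path}: duplicate sequence name {name!r}")
        sequences[name] = normalize_sequence("".join(chunks))
    if not sequences:
        raise FormatError(f"{path}: empty FASTA file")
    return GenomeSequence(sequences)


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_intron_annotation(path: str | Path, format: str = "bed6") -> list[IntronRecord]:
    """Read intron records from BED6 or GFF3.

    BED coordinates are kept 0-based half-open; GFF3 1-based inclusive
    coordinates are converted to half-open (start-1, end). A '.' strand is an
    error because the 3'ss cannot be resolved without strand.
    """
    path = Path(path)
    records: list[IntronRecord] = []
    seen: set[str] = set()

    def _add(chrom: str, start: int, end: int, strand: str, intron_id: str) -> None:
        if strand == ".":
            raise FormatError(f"{path}: strand '.' for {intron_id!r}; strand is required")
        if intron_id in seen:
            raise FormatError(f"{path}: duplicate intron_id {intron_id!r}")
        seen.add(intron_id)
        records.append(IntronRecord(chrom, start, end, strand, intron_id))

    with open(path) as fh:
        if format == "bed6":
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 6:
                    raise FormatError(f"{path}:{ln}: BED6 needs 6 columns, got {len(fields)}")
                chrom, start, end, name, _score, strand = fields[:6]
                _add(chrom, int(start), int(end), strand, name)
        elif format == "gff3":
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns, got {len(fields)}")
                chrom, _src, ftype, start, end, _score, strand, _phase, attrs = fields
                if ftype != "intron":
                    continue
                attr_map = dict(
                    kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
                )
                intron_id = attr_map.get("ID") or attr_map.get("Name")
                if not intron_id:
                    raise FormatError(f"{path}:{ln}: intron row without ID attribute")
                _add(chrom, int(start) - 1, int(end), strand, intron_id)
        else:
            raise ValueError(f"unknown annotation format {format!r}")
    return records


def write_intron_bed(records: Iterable[IntronRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(
                f"{rec.chrom}\t{rec.start}\t{rec.end}\t{rec.intron_id}\t0\t{rec.strand}\n"
            )


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_contrast_table(path: str | Path) -> pd.DataFrame:
    """Read a per-contrast splicing event table (TSV).

    Required columns: event_id, gene_id, event_type, dpsi, mv_dpsi95.
    base_mean is optional (it may arrive in a separate table). Rows whose
    dpsi cannot be parsed as a number are dropped with a logged count; extra
    columns pass through untouched.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    _require_columns(df, CONTRAST_COLUMNS, path)
    for col in ("dpsi", "mv_dpsi95", "base_mean"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    n_bad = int(df["dpsi"].isna().sum())
    if n_bad:
        logger.info("%s: dropped %d row(s) with non-numeric dpsi", path, n_bad)
        df = df[df["dpsi"].notna()]
    return df.reset_index(drop=True)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any pipeline table as TSV with NA for missing values."""
    df.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


def read_table(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False)
    if required is not None:
        _require_columns(df, required, path)
    return df


def read_nsc_table(path: str | Path) -> pd.DataFrame:
    """Read a normalized-spectral-count table.

    Required: protein_id plus the six channels (NE, WT, upDEL, dnDEL, 2xDEL,
    APT). Missing values stay NaN and are distinct from zero throughout.
    """
    path = Path(path)
    df = read_table(path, required=["protein_id"] + NSC_CHANNELS)
    for col in NSC_CHANNELS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_membership_list(path: str | Path) -> set[str]:
    """Read a one-column protein membership list (e.g. E/U2 components)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    return set(df.iloc[:, 0].astype(str))


def write_truth(truth: dict, path: str | Path) -> None:
    """Serialize a generator's ground-truth record as JSON."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
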