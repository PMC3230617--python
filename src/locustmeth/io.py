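"""Input/output for unigene FASTA sets, GO annotation tables and result tables.

Sequences are normalized on read to the {A, C, G, T, N} alphabet: lower case is
uppercased and any IUPAC ambiguity code other than N (R, Y, S, W, K, M, B, D,
H, V) is converted to N, with the number of such conversions counted.  This is
deliberately permissive — EST-derived unigene sets routinely contain ambiguity
calls, and the downstream O/E statistics already correct for Ns.

Tabular data is TSV throughout (UTF-8, Unix newlines): annotations as a
headerless two-column ``gene_id<TAB>go_term`` file, result tables as headered
TSV written at full float precision so that write → read round-trips.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

logger = logging.getLogger(__name__)

VALID_ALPHABET = frozenset("ACGTN")

# IUPAC nucleotide ambiguity codes collapsed to N on read.
_AMBIGUITY = frozenset("RYSWKMBDHVU")

__all__ = [
    "SequenceRecord",
    "read_fasta",
    "read_annotations",
    "read_gene_subset",
    "write_table",
    "read_table",
    "FastaFormatError",
    "AnnotationFormatError",
]


class FastaFormatError(ValueError):
    """Raised for FASTA input the pipeline cannot accept."""


class AnnotationFormatError(ValueError):
    """Raised for annotation input with no usable rows."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide sequence over {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has zero length")
        bad = set(self.residues) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains invalid residues {sorted(bad)}; "
                "normalize through read_fasta or normalize_residues first"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(raw: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN IUPAC codes to N.

    Returns the normalized string and the number of residues converted to N.
    Characters outside the IUPAC nucleotide alphabet raise ValueError.
    """
    up = raw.upper()
    out = []
    converted = 0
    for ch in up:
        if ch in VALID_ALPHABET:
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
            converted += 1
        else:
            raise ValueError(f"invalid residue {ch!r} in sequence data")
    return "".join(out), converted


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into a list of normalized :class:`SequenceRecord`.

    Residues are uppercased; ambiguity codes other than N become N (total
    conversions logged as a warning).  Duplicate IDs and zero-length records
    are rejected.  Line-wrapped and single-line FASTA are both accepted; the
    record id is the first whitespace-delimited token of the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    total_converted = 0
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            rec_id = header.split()[0] if header.split() else ""
            if not rec_id:
                raise FastaFormatError(f"{path}: FASTA record with empty id")
            if rec_id in seen:
                raise FastaFormatError(f"{path}: duplicate sequence id {rec_id!r}")
            seen.add(rec_id)
            if not seq:
                raise FastaFormatError(f"{path}: zero-length sequence {rec_id!r}")
            residues, converted = normalize_residues(seq)
            total_converted += converted
            records.append(SequenceRecord(id=rec_id, residues=residues))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    if total_converted:
        logger.warning(
            "%s: converted %d ambiguous residues to N", path, total_converted
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as line-wrapped FASTA."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                handle.write(rec.residues[i : i + width] + "\n")


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column gene_id<TAB>go_term TSV into gene → term-set mapping.

    Repeated (gene, term) pairs are de-duplicated.  Malformed lines (wrong
    column count, empty fields) are counted and reported via a logged warning;
    a file with zero valid lines is an error.  Empty term sets are never
    stored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table: dict[str, set[str]] = {}
    malformed = 0
    n_valid = 0
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                malformed += 1
                continue
            gene, term = parts[0].strip(), parts[1].strip()
            table.setdefault(gene, set()).add(term)
            n_valid += 1
    if malformed:
        logger.warning("%s: skipped %d malformed annotation lines", path, malformed)
    if n_valid == 0:
        raise AnnotationFormatError(f"{path}: no valid annotation lines")
    return table


def read_gene_subset(path: str | Path) -> list[str]:
    """Read an ordered one-id-per-line gene subset list (blank lines ignored)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not ids:
        raise ValueError(f"{path}: empty gene subset list")
    return ids


def _as_row(record) -> Mapping:
    if dataclasses.is_dataclass(record) and not isinstance(record, type):
        return dataclasses.asdict(record)
    if isinstance(record, Mapping):
        return record
    raise TypeError(f"cannot serialize record of type {type(record).__name__}")


def write_table(rows: Sequence, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dataclasses or mappings) as headered TSV.

    Floats are serialized with repr precision so that a write → read cycle is
    lossless.  An empty row list with explicit ``columns`` yields a
    header-only file.
    """
    if rows:
        frame = pd.DataFrame([_as_row(r) for r in rows])
        if columns is not None:
            frame = frame[list(columns)]
    else:
        if columns is None:
            raise ValueError("columns required to write an empty table")
        frame = pd.DataFrame(columns=list(columns))
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
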