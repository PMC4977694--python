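"""Readers and writers for the reference and read formats the pipeline touches.

The internal sequence alphabet is DNA: input sequences are uppercased and
``U`` is normalised to ``T`` at the file boundary, so miRBase-style RNA
references and DNA references can be mixed freely.  Human-facing reports may
re-emit RNA (see :func:`to_rna`).

Coordinates are 0-based half-open everywhere inside the package.  GFF3 input
(1-based, inclusive) is converted on read and back-converted on write; the
documented TSV fallback for mature annotations is already 0-based half-open.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from io import TextIOWrapper
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from gffutils.feature import feature_from_line

__all__ = [
    "Precursor",
    "MatureAnnotation",
    "SequencedRead",
    "FormatError",
    "read_precursor_fasta",
    "write_precursor_fasta",
    "read_mature_annotations",
    "write_mature_gff3",
    "write_mature_tsv",
    "read_fastq",
    "write_fastq",
    "read_utr_fasta",
    "read_matrix_tsv",
    "to_rna",
    "to_dna",
]

_DNA_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


class FormatError(ValueError):
    """A file did not conform to the expected dialect."""


def to_dna(sequence: str) -> str:
    """Uppercase and normalise U->T."""
    return sequence.upper().replace("U", "T")


def to_rna(sequence: str) -> str:
    """Render an internal DNA sequence as RNA for human-facing reports."""
    return sequence.upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    """Reverse complement; the input alphabet (DNA or RNA) is preserved."""
    seq = sequence.upper()
    if "U" in seq:
        if not set(seq) <= frozenset("ACGU"):
            raise ValueError(f"non-nucleotide character in {sequence!r}")
        return seq.translate(_RNA_COMPLEMENT)[::-1]
    if not set(seq) <= _DNA_ALPHABET:
        raise ValueError(f"non-nucleotide character in {sequence!r}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Precursor:
    """A miRNA hairpin (stem-loop) reference sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_dna(self.sequence))
        if len(self.sequence) < 40:
            raise ValueError(
                f"precursor {self.id!r}: length {len(self.sequence)} < 40"
            )
        bad = set(self.sequence) - _DNA_ALPHABET
        if bad:
            raise ValueError(
                f"precursor {self.id!r}: non-ACGTU characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class MatureAnnotation:
    """A canonical mature miRNA located on a precursor.

    ``start``/``end`` are 0-based half-open coordinates on the precursor;
    ``sequence`` is the precursor substring at those coordinates.
    """

    mirna_name: str
    precursor_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", to_dna(self.sequence))
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"{self.mirna_name}: invalid interval [{self.start}, {self.end})"
            )
        length = self.end - self.start
        if not 18 <= length <= 26:
            raise ValueError(
                f"{self.mirna_name}: mature length {length} outside [18, 26]"
            )

    @property
    def arm(self) -> str:
        """'5p', '3p' or '' when the name does not encode the arm."""
        lower = self.mirna_name.lower()
        if lower.endswith("-5p"):
            return "5p"
        if lower.endswith("-3p"):
            return "3p"
        return ""

    @classmethod
    def from_precursor(
        cls, mirna_name: str, precursor: Precursor, start: int, end: int
    ) -> "MatureAnnotation":
        if end > len(precursor.sequence):
            raise FormatError(
                f"{mirna_name}: end {end} beyond precursor "
                f"{precursor.id!r} (length {len(precursor.sequence)})"
            )
        return cls(
            mirna_name=mirna_name,
            precursor_id=precursor.id,
            start=start,
            end=end,
            sequence=precursor.sequence[start:end],
        )


@dataclass(frozen=True)
class SequencedRead:
    """One sequencing read; quality is optional (absent for FASTA input)."""

    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


# ---------------------------------------------------------------------------
# FASTA


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_precursor_fasta(path: str | Path) -> dict[str, Precursor]:
    """Read a hairpin FASTA into a mapping id -> :class:`Precursor`.

    The first whitespace-separated header token is the id (miRBase headers
    carry accession and species after it).  Duplicate ids are rejected.
    """
    precursors: dict[str, Precursor] = {}
    with _open_text(path) as handle:
        # manual pre-scan so malformed input fails with a line number
        first = handle.readline()
        if first and not first.startswith(">"):
            raise FormatError(f"{path}: line 1: expected '>' header, got {first!r}")
        handle.seek(0)
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in precursors:
                raise FormatError(f"{path}: duplicate precursor id {record.id!r}")
            precursors[record.id] = Precursor(id=record.id, sequence=str(record.seq))
    return precursors


def write_precursor_fasta(
    precursors: Mapping[str, Precursor] | Iterable[Precursor],
    path: str | Path,
    *,
    rna: bool = False,
) -> None:
    if isinstance(precursors, Mapping):
        precursors = precursors.values()
    with open(path, "w") as out:
        for pre in precursors:
            seq = to_rna(pre.sequence) if rna else pre.sequence
            out.write(f">{pre.id}\n{seq}\n")


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """Read 3'UTR sequences keyed by the first header token (DNA-normalised)."""
    utrs: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in utrs:
                raise FormatError(f"{path}: duplicate UTR id {record.id!r}")
            utrs[record.id] = to_dna(str(record.seq))
    return utrs


def write_utr_fasta(utrs: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as out:
        for gene_id, seq in utrs.items():
            out.write(f">{gene_id}\n{seq}\n")


# ---------------------------------------------------------------------------
# Mature annotations (GFF3 and TSV dialects)


def read_mature_annotations(
    path: str | Path, precursors: Mapping[str, Precursor]
) -> list[MatureAnnotation]:
    """Read mature miRNA coordinates from GFF3 or the TSV fallback.

    GFF3 rows with feature type ``miRNA`` are used; the seqid column names the
    precursor and coordinates are 1-based inclusive.  The TSV fallback has
    columns (mirna_name, precursor_id, start, end) in 0-based half-open
    coordinates.  Every annotation's sequence is filled in from the precursor;
    rows referencing unknown precursors or out-of-range coordinates raise.
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        return _read_mature_gff3(path, precursors)
    return _read_mature_tsv(path, precursors)


def _require_precursor(
    precursors: Mapping[str, Precursor], pid: str, context: str
) -> Precursor:
    try:
        return precursors[pid]
    except KeyError:
        raise FormatError(f"{context}: unknown precursor id {pid!r}") from None


def _read_mature_gff3(
    path: Path, precursors: Mapping[str, Precursor]
) -> list[MatureAnnotation]:
    annotations: list[MatureAnnotation] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                feature = feature_from_line(line)
            except Exception as exc:
                raise FormatError(f"{path}:{lineno}: unparseable GFF3 row: {exc}")
            if feature.featuretype != "miRNA":
                continue
            name = (
                feature.attributes.get("Name", [None])[0]
                or feature.attributes.get("ID", [None])[0]
            )
            if name is None:
                raise FormatError(f"{path}:{lineno}: miRNA row without Name or ID")
            pre = _require_precursor(precursors, feature.seqid, f"{path}:{lineno}")
            # GFF3 1-based inclusive -> 0-based half-open
            annotations.append(
                MatureAnnotation.from_precursor(
                    name, pre, feature.start - 1, feature.end
                )
            )
    return annotations


def _read_mature_tsv(
    path: Path, precursors: Mapping[str, Precursor]
) -> list[MatureAnnotation]:
    table = pd.read_csv(path, sep="\t", dtype={"mirna_name": str, "precursor_id": str})
    required = {"mirna_name", "precursor_id", "start", "end"}
    missing = required - set(table.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    annotations: list[MatureAnnotation] = []
    for row in table.itertuples(index=False):
        pre = _require_precursor(precursors, row.precursor_id, str(path))
        ann = MatureAnnotation.from_precursor(
            row.mirna_name, pre, int(row.start), int(row.end)
        )
        if "sequence" in table.columns:
            stated = to_dna(str(getattr(row, "sequence")))
            if stated != ann.sequence:
                raise FormatError(
                    f"{path}: {row.mirna_name}: stated sequence {stated} does not "
                    f"match precursor substring {ann.sequence}"
                )
        annotations.append(ann)
    return annotations


def write_mature_gff3(
    annotations: Iterable[MatureAnnotation], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for ann in annotations:
            # back-convert 0-based half-open -> 1-based inclusive
            out.write(
                f"{ann.precursor_id}\tisomirkit\tmiRNA\t{ann.start + 1}\t{ann.end}"
                f"\t.\t+\t.\tID={ann.mirna_name};Name={ann.mirna_name};"
                f"Derives_from={ann.precursor_id}\n"
            )


def write_mature_tsv(annotations: Iterable[MatureAnnotation], path: str | Path) -> None:
    rows = [
        (a.mirna_name, a.precursor_id, a.start, a.end, a.sequence)
        for a in annotations
    ]
    pd.DataFrame(
        rows, columns=["mirna_name", "precursor_id", "start", "end", "sequence"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> Iterator[SequencedRead]:
    """Stream reads from a (optionally gzipped) 4-line FASTQ file.

    Truncated records raise :class:`FormatError` naming the record index.
    """
    index = 0
    with _open_text(path) as handle:
        try:
            for record in SeqIO.parse(handle, "fastq"):
                quality = "".join(
                    chr(q + 33) for q in record.letter_annotations["phred_quality"]
                )
                yield SequencedRead(
                    id=record.id, sequence=str(record.seq), quality=quality
                )
                index += 1
        except ValueError as exc:
            raise FormatError(f"{path}: record {index + 1}: {exc}") from exc


def write_fastq(reads: Iterable[SequencedRead], path: str | Path) -> int:
    """Write reads as 4-line FASTQ (gzipped iff the path ends in .gz)."""
    n = 0
    path = Path(path)
    if path.suffix == ".gz":
        # mtime=0 keeps output byte-identical across runs of a seeded generator
        handle = TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
    else:
        handle = open(path, "w")
    with handle as out:
        for read in reads:
            quality = read.quality if read.quality is not None else "I" * len(read.sequence)
            out.write(f"@{read.id}\n{read.sequence}\n+\n{quality}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# Expression-matrix TSV (rows: mirna_name, offset5; columns: samples)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    """Read an isoform expression table indexed by (mirna_name, offset5).

    Non-sample annotation columns (e.g. a seed column) are dropped; the
    offset5 column accepts the signed notation ("+1", "0", "-2").
    """
    table = pd.read_csv(path, sep="\t")
    if "mirna_name" not in table.columns or "offset5" not in table.columns:
        raise FormatError(f"{path}: expected 'mirna_name' and 'offset5' columns")
    table["offset5"] = table["offset5"].astype(str).str.replace("+", "", regex=False)
    table["offset5"] = table["offset5"].astype(int)
    table = table.set_index(["mirna_name", "offset5"])
    numeric = table.select_dtypes("number")
    if numeric.shape[1] == 0:
        raise FormatError(f"{path}: no numeric sample columns")
    return numeric


def write_matrix_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index = pd.MultiIndex.from_tuples(
        [(name, f"{d5:+d}" if d5 else "0") for name, d5 in out.index],
        names=["mirna_name", "offset5"],
    )
    out.reset_index().to_csv(path, sep="\t", index=False)
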