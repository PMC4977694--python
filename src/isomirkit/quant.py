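"""Raw small-RNA reads to an isoform expression matrix.

The pipeline is: adapter trimming (exact suffix/prefix match), exact-match
placement on precursor sequences (sense strand only, zero mismatches),
5'/3' offset assignment in the ``d5|d3`` notation relative to the annotated
mature miRNA, collapsing of 3' variants into (miRNA, 5'-offset) isoform
groups for reads of 18-24 nt, fractional counting of multi-mapping reads,
and reads-per-million (rpm) normalisation.

Everything here is deterministic given its inputs; randomness lives in
:mod:`isomirkit.simulate`.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MatureAnnotation, Precursor, SequencedRead, read_fastq

__all__ = [
    "TrimOptions",
    "TrimResult",
    "IsomiRAssignment",
    "IsoformKey",
    "IsoformExpressionMatrix",
    "PrecursorIndex",
    "trim_adapter",
    "map_read",
    "assign_offsets",
    "collapse_to_isoform",
    "quantify",
    "offset_notation",
]

logger = logging.getLogger(__name__)

COLLAPSE_MIN_LENGTH = 18
COLLAPSE_MAX_LENGTH = 24
DEFAULT_MAX_OFFSET5 = 5


def offset_notation(value: int) -> str:
    """Signed rendering of one offset: +1, 0, -2."""
    return f"{value:+d}" if value else "0"


@dataclass(frozen=True)
class TrimOptions:
    """Adapter-trimming and length-window parameters."""

    adapter: str = ""
    min_overlap: int = 6
    min_length: int = 15
    max_length: int = 30

    def __post_init__(self) -> None:
        if self.adapter and self.min_overlap < 3:
            raise ValueError("min_overlap must be >= 3")
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")


@dataclass(frozen=True)
class TrimResult:
    """Outcome of trimming one read; ``rejected`` is None for accepted reads."""

    read: SequencedRead
    rejected: str | None = None

    @property
    def accepted(self) -> bool:
        return self.rejected is None


def trim_adapter(read: SequencedRead, options: TrimOptions) -> TrimResult:
    """Remove a 3' adapter by exact suffix/prefix match.

    The longest read suffix that exactly equals a prefix of the adapter (of
    length >= ``min_overlap``) is removed; reads without such a suffix pass
    through unchanged.  Reads outside [min_length, max_length] after trimming
    are rejected with reason ``too_short`` / ``too_long``.
    """
    seq = read.sequence
    trimmed = read
    if options.adapter:
        adapter = options.adapter.upper()
        # longest suffix first: scan candidate suffix starts left to right
        limit = len(seq) - options.min_overlap
        for start in range(0, limit + 1):
            suffix = seq[start:]
            if adapter.startswith(suffix[: len(adapter)]) and len(suffix) <= len(
                adapter
            ):
                quality = read.quality[:start] if read.quality else None
                if start == 0:
                    return TrimResult(read, rejected="adapter_only")
                trimmed = SequencedRead(read.id, seq[:start], quality)
                break
    if len(trimmed.sequence) < options.min_length:
        return TrimResult(trimmed, rejected="too_short")
    if len(trimmed.sequence) > options.max_length:
        return TrimResult(trimmed, rejected="too_long")
    return TrimResult(trimmed)


class PrecursorIndex:
    """Exact-substring index over a precursor set.

    Every substring with length in [min_length, max_length] is keyed to its
    (precursor id, start) occurrences, so lookups are O(1) per read.  The
    references this pipeline handles (miRNA hairpins) are short, keeping the
    index small.
    """

    def __init__(
        self,
        precursors: Mapping[str, Precursor] | Iterable[Precursor],
        min_length: int = 15,
        max_length: int = 30,
    ) -> None:
        if isinstance(precursors, Mapping):
            precursors = list(precursors.values())
        else:
            precursors = list(precursors)
        self.min_length = min_length
        self.max_length = max_length
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for pre in precursors:
            seq = pre.sequence
            for length in range(min_length, min(max_length, len(seq)) + 1):
                for start in range(len(seq) - length + 1):
                    self._index[seq[start : start + length]].append((pre.id, start))

    def lookup(self, sequence: str) -> list[tuple[str, int]]:
        return list(self._index.get(sequence, ()))


def map_read(
    read: SequencedRead | str, index: PrecursorIndex
) -> list[tuple[str, int]]:
    """All exact sense-strand occurrences of the read in the reference.

    Returns (precursor_id, 0-based start) pairs; empty for unmapped reads.
    """
    seq = read if isinstance(read, str) else read.sequence
    if not (index.min_length <= len(seq) <= index.max_length):
        return []
    return index.lookup(seq)


@dataclass(frozen=True)
class IsomiRAssignment:
    """A read placed on a precursor, expressed as offsets from a mature.

    ``offset5`` = read start - mature start; ``offset3`` = read end - mature
    end.  A +1|+2 assignment is a read starting one base into the mature and
    running two bases past its 3' end.
    """

    read_sequence: str
    mirna_name: str
    precursor_id: str
    offset5: int
    offset3: int
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.weight <= 1:
            raise ValueError(f"weight {self.weight} outside (0, 1]")

    @property
    def notation(self) -> str:
        return f"{offset_notation(self.offset5)}|{offset_notation(self.offset3)}"


@dataclass(frozen=True)
class IsoformKey:
    """A collapsed isoform group: all 18-24 nt 3' variants sharing a 5' end."""

    mirna_name: str
    offset5: int

    @property
    def label(self) -> str:
        return f"{self.mirna_name} {offset_notation(self.offset5)}|x"


def assign_offsets(
    hit: tuple[str, int],
    read_sequence: str,
    annotations: Sequence[MatureAnnotation],
    max_offset5: int = DEFAULT_MAX_OFFSET5,
) -> IsomiRAssignment | None:
    """Assign a mapped read to the nearest mature annotation on its precursor.

    Among the precursor's annotations the one minimising \\|offset5\\| is
    chosen (ties: smaller \\|offset3\\|, then the 5p arm).  Reads further than
    ``max_offset5`` from every mature 5' end return None.
    """
    precursor_id, start = hit
    candidates = [a for a in annotations if a.precursor_id == precursor_id]
    if not candidates:
        logger.warning("precursor %s carries no mature annotation", precursor_id)
        return None
    end = start + len(read_sequence)

    def rank(ann: MatureAnnotation) -> tuple[int, int, int]:
        return (
            abs(start - ann.start),
            abs(end - ann.end),
            0 if ann.arm == "5p" else 1,
        )

    best = min(candidates, key=rank)
    offset5 = start - best.start
    offset3 = end - best.end
    if abs(offset5) > max_offset5:
        return None
    return IsomiRAssignment(
        read_sequence=read_sequence,
        mirna_name=best.mirna_name,
        precursor_id=precursor_id,
        offset5=offset5,
        offset3=offset3,
    )


def collapse_to_isoform(assignment: IsomiRAssignment) -> IsoformKey | None:
    """Collapse 3' variants: reads of 18-24 nt keyed by (miRNA, 5' offset).

    Reads outside the length window return None (recorded upstream as
    ``length_out_of_window``).
    """
    length = len(assignment.read_sequence)
    if COLLAPSE_MIN_LENGTH <= length <= COLLAPSE_MAX_LENGTH:
        return IsoformKey(assignment.mirna_name, assignment.offset5)
    return None


@dataclass
class IsoformExpressionMatrix:
    """Counts and rpm per (miRNA, 5'-offset) isoform group per sample.

    ``counts`` and ``rpm`` are DataFrames indexed by a (mirna_name, offset5)
    MultiIndex with one column per sample; ``library_sizes`` is the total
    collapsed read weight per sample, so each rpm column sums to 1e6.
    """

    counts: pd.DataFrame
    rpm: pd.DataFrame
    library_sizes: pd.Series
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)
    rejections: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def keys(self) -> list[IsoformKey]:
        return [IsoformKey(name, d5) for name, d5 in self.counts.index]


_AUDIT_FIELDS = ["input", "trimmed", "mapped", "assigned", "collapsed"]


def _resolve_reads(source) -> Iterable[SequencedRead]:
    if isinstance(source, (str, Path)):
        return read_fastq(source)
    return source


def quantify(
    reads_by_sample: Mapping[str, Iterable[SequencedRead] | str | Path],
    precursors: Mapping[str, Precursor],
    annotations: Sequence[MatureAnnotation],
    options: TrimOptions | None = None,
    max_offset5: int = DEFAULT_MAX_OFFSET5,
) -> IsoformExpressionMatrix:
    """Run trim -> map -> assign -> collapse -> count -> rpm per sample.

    A read whose surviving assignments span n distinct miRNA names
    contributes weight 1/n to each; hits to the same miRNA via duplicate
    precursors count once.  The rpm denominator is the collapsed weight of
    the sample, making per-sample rpm sum to exactly 1e6.
    """
    if not reads_by_sample:
        raise ValueError("no samples supplied")
    if not precursors:
        raise ValueError("empty precursor reference")
    options = options or TrimOptions()
    index = PrecursorIndex(precursors, options.min_length, options.max_length)

    counts: dict[str, Counter] = {}
    audits: dict[str, dict[str, int]] = {}
    rejection_rows: list[tuple[str, str, int]] = []

    for sample, source in reads_by_sample.items():
        sample_counts: Counter = Counter()
        audit = dict.fromkeys(_AUDIT_FIELDS, 0)
        rejections: Counter = Counter()
        for read in _resolve_reads(source):
            audit["input"] += 1
            trim = trim_adapter(read, options)
            if not trim.accepted:
                rejections[trim.rejected] += 1
                continue
            audit["trimmed"] += 1
            hits = map_read(trim.read, index)
            if not hits:
                rejections["unmapped"] += 1
                continue
            audit["mapped"] += 1
            assignments = [
                a
                for hit in hits
                if (a := assign_offsets(hit, trim.read.sequence, annotations, max_offset5))
                is not None
            ]
            if not assignments:
                rejections["no_assignment"] += 1
                continue
            audit["assigned"] += 1
            # dedupe by miRNA name (duplicate precursors of one family count once)
            keys = {
                key
                for a in assignments
                if (key := collapse_to_isoform(a)) is not None
            }
            if not keys:
                rejections["length_out_of_window"] += 1
                continue
            audit["collapsed"] += 1
            by_name: dict[str, list[IsoformKey]] = defaultdict(list)
            for key in keys:
                by_name[key.mirna_name].append(key)
            name_weight = 1.0 / len(by_name)
            for name_keys in by_name.values():
                for key in name_keys:
                    sample_counts[key] += name_weight / len(name_keys)
        if not sample_counts:
            raise ValueError(f"sample {sample!r}: library size 0 (no read collapsed)")
        counts[sample] = sample_counts
        audits[sample] = audit
        rejection_rows.extend((sample, reason, n) for reason, n in rejections.items())

    all_keys = sorted(
        {key for sample_counts in counts.values() for key in sample_counts},
        key=lambda k: (k.mirna_name, k.offset5),
    )
    samples = list(reads_by_sample)
    matrix = pd.DataFrame(
        [[counts[s].get(k, 0.0) for s in samples] for k in all_keys],
        index=pd.MultiIndex.from_tuples(
            [(k.mirna_name, k.offset5) for k in all_keys],
            names=["mirna_name", "offset5"],
        ),
        columns=samples,
        dtype=float,
    )
    library_sizes = matrix.sum(axis=0)
    rpm = matrix / library_sizes * 1e6
    audit_frame = pd.DataFrame(audits).T[_AUDIT_FIELDS]
    audit_frame.index.name = "sample"
    rejection_frame = pd.DataFrame(
        rejection_rows, columns=["sample", "reason", "count"]
    )
    return IsoformExpressionMatrix(
        counts=matrix,
        rpm=rpm,
        library_sizes=library_sizes,
        audit=audit_frame,
        rejections=rejection_frame,
    )
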