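"""Highly expressed miRNA/5'isomiR pair detection and shifted-seed target scanning.

A 5'isomiR whose start is shifted by +1 relative to the canonical mature
carries a seed (nucleotides 2-8) equal to positions 3-9 of the canonical
sequence, so the two isoforms recognise different 7-mer target sites in
3'UTRs.  This module detects expression pairs from an isoform rpm matrix,
derives seeds and target sites, scans UTRs for (possibly overlapping) site
occurrences, and tests whether downregulated genes are enriched for
site-bearing UTRs with a one-sided Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import reverse_complement, to_dna
from .quant import IsoformExpressionMatrix

__all__ = [
    "PairCriteria",
    "PairCandidate",
    "SeedMatch",
    "EnrichmentResult",
    "seed_of",
    "target_site_of",
    "scan_utr",
    "detect_pairs",
    "enrichment_test",
    "load_breast_panel_rpm",
    "load_breast_panel_matures",
]

SEED_START = 1  # 0-based: seed is positions 2-8 in 1-based miRNA numbering
SEED_END = 8


@dataclass(frozen=True)
class PairCriteria:
    """Thresholds defining a highly expressed miRNA/5'isomiR pair.

    Defaults: mean canonical expression of at least 100 rpm and an
    isomiR:canonical ratio of at least 1:5 (0.2), with the 5'isomiR defined
    as the +1 5'-offset group.
    """

    min_canonical_mean_rpm: float = 100.0
    min_ratio: float = 0.2
    isomir_offset: int = 1

    def __post_init__(self) -> None:
        if self.min_canonical_mean_rpm <= 0 or self.min_ratio <= 0:
            raise ValueError("criteria thresholds must be positive")


@dataclass(frozen=True)
class PairCandidate:
    """One miRNA's canonical/5'isomiR expression pair with its verdict."""

    mirna_name: str
    canonical_mean_rpm: float
    isomir_mean_rpm: float
    ratio: float
    passes: bool
    per_sample_canonical: tuple[float, ...]
    per_sample_isomir: tuple[float, ...]


@dataclass(frozen=True)
class SeedMatch:
    """One 7-mer target-site occurrence within a 3'UTR (0-based start)."""

    gene_id: str
    utr_position: int
    site_sequence: str
    seed_owner: str  # "canonical" or "isomir"


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided Fisher exact test of seed-site presence in a gene set."""

    odds_ratio: float
    p_value: float
    table: tuple[tuple[int, int], tuple[int, int]]
    dropped_genes: tuple[str, ...] = ()


def seed_of(mature_sequence: str) -> str:
    """Seed sequence: nucleotides 2-8 (1-based) of a mature miRNA."""
    if len(mature_sequence) < 8:
        raise ValueError(
            f"sequence of length {len(mature_sequence)} has no full seed (need >= 8)"
        )
    return mature_sequence[SEED_START:SEED_END].upper()


def target_site_of(seed: str) -> str:
    """The 7-mer a seed pairs with: its reverse complement (alphabet preserved)."""
    if len(seed) != 7:
        raise ValueError(f"seed must be a 7-mer, got {len(seed)}")
    return reverse_complement(seed)


def scan_utr(
    utr_sequence: str,
    seed: str,
    gene_id: str = "",
    seed_owner: str = "isomir",
) -> list[SeedMatch]:
    """All (possibly overlapping) target-site occurrences in one 3'UTR.

    Matching is on the DNA-normalised sequence; positions are 0-based and
    ascending.
    """
    if not utr_sequence:
        raise ValueError("empty UTR sequence")
    site = to_dna(target_site_of(seed))
    utr = to_dna(utr_sequence)
    matches = []
    start = utr.find(site)
    while start != -1:
        matches.append(
            SeedMatch(
                gene_id=gene_id,
                utr_position=start,
                site_sequence=site,
                seed_owner=seed_owner,
            )
        )
        start = utr.find(site, start + 1)  # overlapping occurrences
    return matches


def _rpm_frame(matrix: IsoformExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    if isinstance(matrix, IsoformExpressionMatrix):
        return matrix.rpm
    return matrix


def detect_pairs(
    matrix: IsoformExpressionMatrix | pd.DataFrame,
    criteria: PairCriteria | None = None,
    ratio_of_means: bool = True,
) -> list[PairCandidate]:
    """Evaluate every miRNA carrying both a canonical and a 5'isomiR group.

    The expression ratio is by default the ratio of per-sample means
    (isomiR mean / canonical mean); ``ratio_of_means=False`` switches to the
    mean of per-sample ratios.  Candidates are returned sorted by name with
    pass/fail flags; a pair passes iff canonical mean rpm >=
    ``min_canonical_mean_rpm`` and ratio >= ``min_ratio``.
    """
    criteria = criteria or PairCriteria()
    rpm = _rpm_frame(matrix)
    if rpm.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    candidates: list[PairCandidate] = []
    for name in sorted(rpm.index.get_level_values("mirna_name").unique()):
        block = rpm.loc[name]
        if 0 not in block.index or criteria.isomir_offset not in block.index:
            continue
        canonical = block.loc[0].to_numpy(dtype=float)
        isomir = block.loc[criteria.isomir_offset].to_numpy(dtype=float)
        canonical_mean = float(canonical.mean())
        isomir_mean = float(isomir.mean())
        if ratio_of_means:
            ratio = isomir_mean / canonical_mean if canonical_mean > 0 else np.inf
        else:
            with np.errstate(divide="ignore"):
                ratio = float(np.mean(isomir / canonical))
        passes = (
            canonical_mean >= criteria.min_canonical_mean_rpm
            and ratio >= criteria.min_ratio
        )
        candidates.append(
            PairCandidate(
                mirna_name=name,
                canonical_mean_rpm=canonical_mean,
                isomir_mean_rpm=isomir_mean,
                ratio=ratio,
                passes=passes,
                per_sample_canonical=tuple(canonical),
                per_sample_isomir=tuple(isomir),
            )
        )
    return candidates


def pair_table(candidates: Sequence[PairCandidate]) -> pd.DataFrame:
    """Tabular view of detect_pairs output for TSV export."""
    return pd.DataFrame(
        [
            (
                c.mirna_name,
                c.canonical_mean_rpm,
                c.isomir_mean_rpm,
                c.ratio,
                c.passes,
            )
            for c in candidates
        ],
        columns=["mirna_name", "canonical_mean_rpm", "isomir_mean_rpm", "ratio", "passes"],
    )


def enrichment_test(
    downregulated_genes: Iterable[str],
    background_genes: Iterable[str],
    seed: str,
    utrs: Mapping[str, str],
) -> EnrichmentResult:
    """Are seed-site-bearing genes over-represented among downregulated ones?

    Builds the 2x2 table (downregulated x has >= 1 target site in its 3'UTR)
    over the background set and applies a one-sided Fisher exact test for
    over-representation.  Background genes without a UTR are dropped with a
    warning; the downregulated set must be a subset of the background.
    """
    down = set(downregulated_genes)
    background = set(background_genes)
    if not down:
        raise ValueError("empty downregulated gene set")
    if not down <= background:
        raise ValueError("downregulated genes must be a subset of the background")
    dropped = tuple(sorted(g for g in background if g not in utrs))
    usable = background - set(dropped)
    down &= usable
    if not down:
        raise ValueError("no downregulated gene has a UTR available")
    has_site = {g for g in usable if scan_utr(utrs[g], seed, gene_id=g)}
    a = len(down & has_site)
    b = len(down - has_site)
    c = len(has_site - down)
    d = len(usable - has_site - down)
    odds_ratio, p_value = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        odds_ratio=float(odds_ratio),
        p_value=float(p_value),
        table=((a, b), (c, d)),
        dropped_genes=dropped,
    )


# ---------------------------------------------------------------------------
# Packaged worked-example fixtures


def load_breast_panel_rpm() -> pd.DataFrame:
    """The packaged 12-row x 8-cell-line rpm matrix of candidate pairs.

    Rows are (mirna_name, offset5 in {0, +1}); the seed annotation column is
    dropped (see :func:`load_breast_panel_matures` for deriving seeds).
    """
    with resources.as_file(
        resources.files("isomirkit.data") / "breast_panel_rpm.tsv"
    ) as path:
        table = pd.read_csv(path, sep="\t")
    table["offset5"] = table["offset5"].astype(str).str.replace("+", "", regex=False)
    table["offset5"] = table["offset5"].astype(int)
    return table.set_index(["mirna_name", "offset5"]).drop(columns=["seed"])


def load_breast_panel_seeds() -> pd.Series:
    """The printed seed column of the packaged pair table, keyed like the rpm."""
    with resources.as_file(
        resources.files("isomirkit.data") / "breast_panel_rpm.tsv"
    ) as path:
        table = pd.read_csv(path, sep="\t")
    table["offset5"] = table["offset5"].astype(str).str.replace("+", "", regex=False)
    table["offset5"] = table["offset5"].astype(int)
    return table.set_index(["mirna_name", "offset5"])["seed"]


def load_breast_panel_matures() -> dict[str, str]:
    """Canonical mature sequences (DNA) for the six packaged pair miRNAs."""
    with resources.as_file(
        resources.files("isomirkit.data") / "breast_panel_matures.tsv"
    ) as path:
        table = pd.read_csv(path, sep="\t")
    return dict(zip(table["mirna_name"], table["mature_sequence"]))
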