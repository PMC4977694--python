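"""Synthetic inputs with recorded ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:
random hairpin references with embedded matures, reads drawn per miRNA from
a log-normal expression model with a per-miRNA (5',3')-offset spectrum,
adapter-contaminated raw reads with optional per-base corruption, DE tables
with planted downregulated genes, and patient cohorts with a bivariate
log-normal expression pair at a configured Pearson correlation plus
quartile-dependent exponential survival.

Every operation takes a :class:`numpy.random.Generator` derived from a
single integer seed, and truth tables record all planted quantities, so
downstream recovery tests never reach into generator internals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io import (
    MatureAnnotation,
    Precursor,
    SequencedRead,
    write_fastq,
    write_mature_gff3,
    write_precursor_fasta,
)
from .quant import COLLAPSE_MAX_LENGTH, COLLAPSE_MIN_LENGTH

__all__ = [
    "CohortConfig",
    "SimulationConfig",
    "Reference",
    "simulate_reference",
    "simulate_reads",
    "simulate_de_table",
    "simulate_cohort",
    "simulate_to_dir",
    "load_config",
]

_BASES = np.array(list("ACGT"))

DEFAULT_OFFSET_SPECTRUM: dict[tuple[int, int], float] = {
    (0, 0): 0.40,
    (0, -1): 0.10,
    (0, 1): 0.10,
    (0, 2): 0.05,
    (1, 0): 0.20,
    (1, 1): 0.10,
    (1, 2): 0.05,
}


@dataclass(frozen=True)
class CohortConfig:
    """Patient-cohort generation parameters.

    ``target_correlation`` is the Pearson correlation of the two isoform
    expressions on the output (log-normal) scale; the latent normal
    correlation is solved analytically from the log-normal moment relation.
    ``er_fraction`` is the fraction of ER-positive patients; ER-negative
    patients receive ``er_effect_size`` added to both log-expressions (and
    metastatic patients the same magnitude subtracted), so a zero effect
    leaves the correlation target exact.  Survival is exponential with the
    high-expression quartile's hazard scaled by ``hazard_ratio_high_vs_low``
    relative to the low quartile; censoring is independent exponential
    calibrated so the expected censored fraction equals ``censoring_rate``.
    """

    n_patients: int = 616
    target_correlation: float = 0.85
    er_fraction: float = 0.75
    metastasis_fraction: float = 0.10
    er_effect_size: float = 0.4
    hazard_ratio_high_vs_low: float = 0.5
    censoring_rate: float = 0.5
    meanlog: float = math.log(300.0)
    sdlog: float = 0.5
    median_survival_days: float = 2000.0

    def __post_init__(self) -> None:
        if not -1 < self.target_correlation < 1:
            raise ValueError("target_correlation must lie in (-1, 1)")
        for name in ("er_fraction", "metastasis_fraction", "censoring_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Top-level generator parameters (defaults are the study conditions)."""

    seed: int = 0
    n_mirnas: int = 5
    precursor_length: int = 80
    samples: tuple[str, ...] = ("S1", "S2")
    depth_per_sample: int = 20_000
    expression_meanlog: float = math.log(100.0)
    expression_sdlog: float = 1.0
    offset_spectrum: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_SPECTRUM)
    )
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    error_rate: float = 0.0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        total = sum(self.offset_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"offset spectrum probabilities sum to {total}, not 1")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must lie in [0, 0.05]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class Reference:
    precursors: dict[str, Precursor]
    annotations: tuple[MatureAnnotation, ...]
    truth: pd.DataFrame  # mirna_name, precursor_id, start, end, sequence


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def simulate_reference(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Reference:
    """Random precursors, each embedding one mature at a recorded position.

    Matures are 20-23 nt, flanked by >= 5 nt, pairwise non-substring of one
    another, and occur exactly once across the whole reference (candidates
    violating either are redrawn) so reads map unambiguously unless a test
    plants ambiguity on purpose.
    """
    if config.n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    rng = rng if rng is not None else config.rng()
    precursors: dict[str, Precursor] = {}
    annotations: list[MatureAnnotation] = []
    matures: list[str] = []
    for i in range(1, config.n_mirnas + 1):
        pid = f"syn-mir-{i:03d}"
        name = f"syn-miR-{i:03d}-3p"
        for _ in range(1000):
            mature_length = int(rng.integers(20, 24))
            start = int(
                rng.integers(5, config.precursor_length - 5 - mature_length + 1)
            )
            seq = _random_sequence(rng, config.precursor_length)
            mature = seq[start : start + mature_length]
            if any(mature in m or m in mature for m in matures):
                continue
            hairpins = list(precursors.values()) + [Precursor(pid, seq)]
            occurrences = sum(h.sequence.count(mature) for h in hairpins)
            if occurrences != 1:
                continue
            if any(
                sum(h.sequence.count(m) for h in hairpins) != 1 for m in matures
            ):
                continue
            precursor = hairpins[-1]
            precursors[pid] = precursor
            annotations.append(
                MatureAnnotation.from_precursor(
                    name, precursor, start, start + mature_length
                )
            )
            matures.append(mature)
            break
        else:
            raise RuntimeError(f"could not place a unique mature for {pid}")
    truth = pd.DataFrame(
        [
            (a.mirna_name, a.precursor_id, a.start, a.end, a.sequence)
            for a in annotations
        ],
        columns=["mirna_name", "precursor_id", "start", "end", "sequence"],
    )
    return Reference(
        precursors=precursors, annotations=tuple(annotations), truth=truth
    )


def _corrupt(rng: np.random.Generator, sequence: str, error_rate: float) -> tuple[str, bool]:
    if error_rate <= 0:
        return sequence, False
    mask = rng.random(len(sequence)) < error_rate
    if not mask.any():
        return sequence, False
    chars = np.array(list(sequence))
    for pos in np.flatnonzero(mask):
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(3))]
    return "".join(chars), True


def simulate_reads(
    config: SimulationConfig,
    reference: Reference,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[SequencedRead]], pd.DataFrame]:
    """Draw reads per sample from the expression model and offset spectrum.

    Each read is the exact precursor substring at its drawn (d5, d3) offsets
    from the mature, with the adapter appended and optional per-base
    corruption at ``error_rate`` (corrupted reads become unmappable under the
    0-mismatch policy by design).  The truth table records drawn and
    corrupted counts per (sample, miRNA, d5, d3).
    """
    rng = rng if rng is not None else config.rng()
    by_annotation = {a.mirna_name: a for a in reference.annotations}
    offsets = list(config.offset_spectrum.keys())
    probs = np.array([config.offset_spectrum[o] for o in offsets], dtype=float)

    # sanity: every offset must stay within every precursor
    for ann in reference.annotations:
        pre_len = len(reference.precursors[ann.precursor_id].sequence)
        for d5, d3 in offsets:
            if ann.start + d5 < 0 or ann.end + d3 > pre_len:
                raise ValueError(
                    f"offset ({d5}, {d3}) falls outside precursor for {ann.mirna_name}"
                )

    reads: dict[str, list[SequencedRead]] = {}
    truth_rows: list[tuple] = []
    names = sorted(by_annotation)
    for sample in config.samples:
        weights = rng.lognormal(
            config.expression_meanlog, config.expression_sdlog, size=len(names)
        )
        weights /= weights.sum()
        mirna_counts = rng.multinomial(config.depth_per_sample, weights)
        sample_reads: list[SequencedRead] = []
        serial = 0
        for name, count in zip(names, mirna_counts):
            if count == 0:
                continue
            ann = by_annotation[name]
            precursor_seq = reference.precursors[ann.precursor_id].sequence
            offset_counts = rng.multinomial(count, probs)
            for (d5, d3), n in zip(offsets, offset_counts):
                corrupted = 0
                insert = precursor_seq[ann.start + d5 : ann.end + d3]
                for _ in range(n):
                    serial += 1
                    raw = insert + config.adapter
                    raw, was_corrupted = _corrupt(rng, raw, config.error_rate)
                    corrupted += was_corrupted
                    sample_reads.append(
                        SequencedRead(
                            id=f"{sample}_r{serial:07d}",
                            sequence=raw,
                            quality="I" * len(raw),
                        )
                    )
                if n:
                    truth_rows.append((sample, name, d5, d3, int(n), corrupted))
        reads[sample] = sample_reads
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "mirna_name", "offset5", "offset3", "count", "corrupted"],
    )
    return reads, truth


def truth_collapsed(truth: pd.DataFrame, reference: Reference) -> pd.DataFrame:
    """Expected collapsed counts per (sample, miRNA, d5): uncorrupted reads
    whose insert length falls in the 18-24 nt collapsing window."""
    lengths = {
        a.mirna_name: a.end - a.start for a in reference.annotations
    }
    rows = truth.copy()
    rows["length"] = (
        rows["mirna_name"].map(lengths) - rows["offset5"] + rows["offset3"]
    )
    rows = rows[
        (rows["length"] >= COLLAPSE_MIN_LENGTH)
        & (rows["length"] <= COLLAPSE_MAX_LENGTH)
    ]
    rows["expected"] = rows["count"] - rows["corrupted"]
    return (
        rows.groupby(["sample", "mirna_name", "offset5"])["expected"]
        .sum()
        .reset_index()
    )


# ---------------------------------------------------------------------------
# DE tables


def simulate_de_table(
    rng: np.random.Generator,
    n_genes: int = 500,
    cell_lines: Sequence[str] = ("LineA", "LineB"),
    conditions: Sequence[str] = ("canonical", "isomir"),
    planted: Mapping[str, int] | None = None,
) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """A ratio+p DE table with planted downregulated genes.

    ``planted`` maps each condition (and the special key "shared") to a gene
    count.  Planted hits get fold ratios in [0.40, 0.62] and raw p-values at
    most 1e-6 in every listed cell line, which survive Benjamini-Hochberg
    correction at alpha 0.05 for any table of this size; null genes get
    ratios in [0.70, 1.30], strictly above the 0.65 threshold, so recovery
    at default thresholds is exact.
    """
    planted = dict(planted or {})
    gene_ids = [f"g{i:05d}" for i in range(1, n_genes + 1)]
    pool = list(gene_ids)
    assignments: dict[str, frozenset[str]] = {}
    for key in list(conditions) + ["shared"]:
        n = planted.get(key, 0)
        if n > len(pool):
            raise ValueError("more planted hits than genes")
        chosen = [pool.pop(0) for _ in range(n)]
        assignments[key] = frozenset(chosen)

    rows = []
    for line in cell_lines:
        for condition in conditions:
            hit_genes = assignments[condition] | assignments["shared"]
            for gene in gene_ids:
                if gene in hit_genes:
                    ratio = rng.uniform(0.40, 0.62)
                    p = 10.0 ** -rng.uniform(6.5, 10.0)
                else:
                    ratio = rng.uniform(0.70, 1.30)
                    p = rng.uniform(0.0, 1.0)
                rows.append((gene, line, condition, ratio, p))
    table = pd.DataFrame(
        rows, columns=["gene_id", "cell_line", "condition", "ratio", "p"]
    )
    return table, assignments


# ---------------------------------------------------------------------------
# Patient cohorts


def _latent_correlation(target: float, sdlog: float) -> float:
    """Normal-scale correlation giving ``target`` Pearson r after exp().

    Uses the log-normal moment relation
    r = (exp(rho * s^2) - 1) / (exp(s^2) - 1) for equal log-sd s, solved for
    rho in closed form.
    """
    s2 = sdlog * sdlog
    rho = math.log1p(target * math.expm1(s2)) / s2
    if not -1 <= rho <= 1:
        raise ValueError(
            f"target correlation {target} infeasible for sdlog {sdlog}"
        )
    return rho


def simulate_cohort(
    cohort: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Patient table with planted correlation, group effects and survival.

    Expressions are bivariate log-normal at the configured output-scale
    Pearson correlation; ER-negative patients get ``er_effect_size`` added
    to both log-expressions and metastatic patients the same magnitude
    subtracted (set it to 0 to keep the correlation target exact).  Survival
    is exponential; the upper expression quartile's hazard is scaled by
    ``hazard_ratio_high_vs_low`` (the middle half geometrically in between)
    and censoring is independent exponential at the configured expected rate.
    """
    n = cohort.n_patients
    rho = _latent_correlation(cohort.target_correlation, cohort.sdlog)
    cov = cohort.sdlog**2 * np.array([[1.0, rho], [rho, 1.0]])
    latent = rng.multivariate_normal([cohort.meanlog] * 2, cov, size=n)

    er_negative = rng.random(n) < (1.0 - cohort.er_fraction)
    metastasis = rng.random(n) < cohort.metastasis_fraction
    shift = cohort.er_effect_size * (
        er_negative.astype(float) - metastasis.astype(float)
    )
    log_expr = latent + shift[:, None]
    expr = np.exp(log_expr)

    # quartile-dependent exponential survival on the isomiR expression
    baseline = math.log(2.0) / cohort.median_survival_days
    isomir = expr[:, 1]
    q1, q3 = np.quantile(isomir, [0.25, 0.75], method="median_unbiased")
    hr = cohort.hazard_ratio_high_vs_low
    hazard = np.full(n, baseline * math.sqrt(hr))
    hazard[isomir <= q1] = baseline
    hazard[isomir >= q3] = baseline * hr
    event_time = rng.exponential(1.0 / hazard)
    if cohort.censoring_rate > 0:
        censor_rate = hazard * cohort.censoring_rate / (1.0 - cohort.censoring_rate)
        censor_time = rng.exponential(1.0 / censor_rate)
    else:
        censor_time = np.full(n, np.inf)
    observed = event_time <= censor_time

    table = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(1, n + 1)],
            "mir_rpm": expr[:, 0],
            "isomir_rpm": expr[:, 1],
            "er_status": np.where(er_negative, "negative", "positive"),
            "metastasis": np.where(metastasis, "yes", "no"),
            "survival_time": np.minimum(event_time, censor_time),
            "event": np.where(observed, "death", "censored"),
        }
    )
    truth = {
        **asdict(cohort),
        "latent_correlation": rho,
        "baseline_hazard": baseline,
        "n_er_negative": int(er_negative.sum()),
        "n_metastasis": int(metastasis.sum()),
        "n_events": int(observed.sum()),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Config files and on-disk generation (CLI surface)


def load_config(path: str | Path) -> SimulationConfig:
    """Read a YAML simulate config; offset spectrum keys are "d5,d3" strings."""
    with open(path) as handle:
        raw = yaml.safe_load(handle) or {}
    if "offset_spectrum" in raw:
        raw["offset_spectrum"] = {
            tuple(int(x) for x in key.split(",")): float(value)
            for key, value in raw["offset_spectrum"].items()
        }
    if "samples" in raw:
        raw["samples"] = tuple(raw["samples"])
    if "cohort" in raw:
        raw["cohort"] = CohortConfig(**raw["cohort"])
    return SimulationConfig(**raw)


def simulate_to_dir(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate reference, reads, DE table and cohort into ``out_dir``.

    Deterministic for a fixed config seed; returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    reference = simulate_reference(config, rng)
    reads, read_truth = simulate_reads(config, reference, rng)
    de_table, de_truth = simulate_de_table(rng)
    cohort_table, cohort_truth = simulate_cohort(config.cohort, rng)

    paths: dict[str, Path] = {}
    paths["precursors"] = out_dir / "precursors.fa"
    write_precursor_fasta(reference.precursors, paths["precursors"])
    paths["matures"] = out_dir / "matures.gff3"
    write_mature_gff3(reference.annotations, paths["matures"])
    paths["reference_truth"] = out_dir / "reference_truth.tsv"
    reference.truth.to_csv(paths["reference_truth"], sep="\t", index=False)
    for sample, sample_reads in reads.items():
        key = f"reads_{sample}"
        paths[key] = out_dir / f"{sample}.fastq.gz"
        write_fastq(sample_reads, paths[key])
    paths["read_truth"] = out_dir / "read_truth.tsv"
    read_truth.to_csv(paths["read_truth"], sep="\t", index=False)
    paths["de_table"] = out_dir / "de_table.tsv"
    de_table.to_csv(paths["de_table"], sep="\t", index=False)
    de_sets = pd.DataFrame(
        [(key, gene) for key, genes in de_truth.items() for gene in sorted(genes)],
        columns=["set", "gene_id"],
    )
    paths["de_truth"] = out_dir / "de_truth.tsv"
    de_sets.to_csv(paths["de_truth"], sep="\t", index=False)
    paths["cohort"] = out_dir / "cohort.tsv"
    cohort_table.to_csv(paths["cohort"], sep="\t", index=False)
    paths["cohort_truth"] = out_dir / "cohort_truth.tsv"
    pd.Series(cohort_truth).rename("value").to_frame().to_csv(
        paths["cohort_truth"], sep="\t"
    )
    return paths
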