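"""Downstream statistics: the downregulation filter with Venn intersections,
isoform-isoform correlation, group comparisons, and quartile survival analysis.

The downregulation filter keeps a gene for a condition when, in *every*
required cell line, treated/control expression is strictly below the fold
threshold (default 0.65, i.e. at least 35 % reduction) and the
multiplicity-corrected p-value is strictly below alpha (default 0.05).

Survival analysis forms 'high' and 'low' groups from the upper and lower
quartiles of an expression vector and compares them with the two-group
log-rank test in its observed-versus-expected risk-table form.  The log-rank
statistic is computed in-repo (vectorised over event times) because the
calibration checks run it thousands of times; Kaplan-Meier curves come from
lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PatientRecord",
    "SurvivalGroups",
    "DownregulationResult",
    "bh_adjust",
    "downregulated_genes",
    "correlate_isoforms",
    "compare_groups",
    "logrank_statistic",
    "quartile_survival",
    "load_patient_table",
]

FOLD_THRESHOLD = 0.65
ALPHA = 0.05


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient isoform expression plus clinical annotations."""

    patient_id: str
    mir_rpm: float
    isomir_rpm: float
    er_status: str = "unknown"  # positive | negative | unknown
    metastasis: str = "unknown"  # yes | no | unknown
    survival_time: float | None = None  # days
    event: str | None = None  # death | censored

    def __post_init__(self) -> None:
        if self.event is not None and self.survival_time is None:
            raise ValueError(
                f"patient {self.patient_id!r}: event without survival_time"
            )


# ---------------------------------------------------------------------------
# Multiple-testing correction


def bh_adjust(p_values: Sequence[float] | np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (Bonferroni via method=...).

    Values outside [0, 1] raise; order of the input is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method=method)[1]


# ---------------------------------------------------------------------------
# Downregulation filter and Venn intersection


@dataclass(frozen=True)
class DownregulationResult:
    """Per-condition downregulated gene sets and their Venn partition."""

    gene_sets: dict[str, frozenset[str]]
    venn: dict[str, int]

    def genes_specific_to(self, condition: str) -> frozenset[str]:
        others: set[str] = set()
        for name, genes in self.gene_sets.items():
            if name != condition:
                others |= genes
        return frozenset(self.gene_sets[condition] - others)


def _per_line_stats(de_table: pd.DataFrame) -> pd.DataFrame:
    """Reduce a DE table to one (gene, cell line, condition) row with ratio+p.

    Accepts either the ratio-level schema (gene_id, cell_line, condition,
    ratio, p) or the replicate-level schema (gene_id, cell_line, condition,
    replicate, expression) with a 'control' condition, from which the ratio
    of means and a two-tailed unpaired t-test p-value are computed.
    """
    cols = set(de_table.columns)
    if {"ratio", "p"} <= cols:
        return de_table[["gene_id", "cell_line", "condition", "ratio", "p"]].copy()
    if not {"replicate", "expression"} <= cols:
        raise ValueError(
            "DE table needs (ratio, p) or (replicate, expression) columns"
        )
    rows = []
    for (gene, line), block in de_table.groupby(["gene_id", "cell_line"], sort=False):
        control = block.loc[block["condition"] == "control", "expression"].to_numpy()
        if control.size == 0:
            raise ValueError(f"gene {gene!r} in line {line!r}: no control replicates")
        for condition, sub in block[block["condition"] != "control"].groupby(
            "condition", sort=False
        ):
            treated = sub["expression"].to_numpy(dtype=float)
            ratio = treated.mean() / control.mean()
            t_p = stats.ttest_ind(treated, control).pvalue if (
                treated.size > 1 and control.size > 1
            ) else 1.0
            rows.append((gene, line, condition, ratio, float(t_p)))
    return pd.DataFrame(
        rows, columns=["gene_id", "cell_line", "condition", "ratio", "p"]
    )


def downregulated_genes(
    de_table: pd.DataFrame,
    cell_lines: Sequence[str],
    conditions: Sequence[str] | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
    alpha: float = ALPHA,
    correction: str = "fdr_bh",
) -> DownregulationResult:
    """Genes downregulated in every listed cell line, per condition, with Venn.

    A gene qualifies for a condition when treated/control < ``fold_threshold``
    (strict) and the corrected p < ``alpha`` (strict) in *every* listed cell
    line.  Correction is applied within each (cell line, condition) stratum
    across genes.  With two conditions the Venn partition reports
    condition-specific and shared counts.
    """
    if not cell_lines:
        raise ValueError("at least one cell line required")
    table = _per_line_stats(de_table)
    if conditions is None:
        conditions = sorted(table["condition"].unique())
    table = table[table["cell_line"].isin(cell_lines)].copy()
    table["p_adj"] = np.nan
    for _, idx in table.groupby(["cell_line", "condition"], sort=False).groups.items():
        table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p"], method=correction)

    gene_sets: dict[str, frozenset[str]] = {}
    for condition in conditions:
        sub = table[table["condition"] == condition]
        per_line: list[set[str]] = []
        for line in cell_lines:
            line_block = sub[sub["cell_line"] == line].set_index("gene_id")
            missing = set(sub["gene_id"].unique()) - set(line_block.index)
            if missing:
                raise ValueError(
                    f"gene {sorted(missing)[0]!r} missing in cell line {line!r}"
                )
            hits = line_block[
                (line_block["ratio"] < fold_threshold) & (line_block["p_adj"] < alpha)
            ]
            per_line.append(set(hits.index))
        gene_sets[condition] = frozenset(set.intersection(*per_line)) if per_line else frozenset()

    venn: dict[str, int] = {}
    if len(conditions) == 2:
        a, b = conditions
        shared = gene_sets[a] & gene_sets[b]
        venn = {
            f"{a}_specific": len(gene_sets[a] - shared),
            f"{b}_specific": len(gene_sets[b] - shared),
            "shared": len(shared),
        }
    else:
        venn = {c: len(gene_sets[c]) for c in conditions}
    return DownregulationResult(gene_sets=gene_sets, venn=venn)


# ---------------------------------------------------------------------------
# Correlation and group comparison


def _patient_frame(patients) -> pd.DataFrame:
    if isinstance(patients, pd.DataFrame):
        return patients
    return pd.DataFrame([vars(p) for p in patients])


def correlate_isoforms(
    patients,
    method: str = "pearson",
    log_transform: bool = False,
) -> tuple[float, float, int]:
    """Correlation of canonical and 5'isomiR expression across patients.

    Returns (coefficient, two-sided p, n used); rows with a missing value in
    either expression are dropped.  ``log_transform`` applies log2(x + 1)
    first; a constant vector raises (undefined coefficient).
    """
    frame = _patient_frame(patients)[["mir_rpm", "isomir_rpm"]].dropna()
    n = len(frame)
    if n < 3:
        raise ValueError(f"need >= 3 complete patients, have {n}")
    x = frame["mir_rpm"].to_numpy(dtype=float)
    y = frame["isomir_rpm"].to_numpy(dtype=float)
    if log_transform:
        x, y = np.log2(x + 1), np.log2(y + 1)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant expression vector: correlation undefined")
    if method == "pearson":
        result = stats.pearsonr(x, y)
    elif method == "spearman":
        result = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(result.statistic), float(result.pvalue), n


def compare_groups(
    patients,
    grouping: str,
    expression_field: str,
    groups: tuple[str, str] | None = None,
) -> dict:
    """Two-tailed unpaired Student's t test between two patient groups.

    ``grouping`` names a categorical column (e.g. er_status, metastasis);
    'unknown' rows are dropped.  Returns the t statistic, two-sided p, group
    means and sizes, and the direction of the difference.
    """
    frame = _patient_frame(patients)[[grouping, expression_field]].dropna()
    frame = frame[frame[grouping] != "unknown"]
    if groups is None:
        labels = sorted(frame[grouping].unique())
        if len(labels) != 2:
            raise ValueError(
                f"grouping {grouping!r} has {len(labels)} levels; pass groups="
            )
        groups = (labels[0], labels[1])
    a = frame.loc[frame[grouping] == groups[0], expression_field].to_numpy(float)
    b = frame.loc[frame[grouping] == groups[1], expression_field].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 members")
    t_stat, p = stats.ttest_ind(a, b)
    means = {groups[0]: float(a.mean()), groups[1]: float(b.mean())}
    return {
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "group_means": means,
        "group_ns": {groups[0]: len(a), groups[1]: len(b)},
        "higher_in": groups[0] if means[groups[0]] >= means[groups[1]] else groups[1],
    }


# ---------------------------------------------------------------------------
# Quartile survival analysis


@dataclass(frozen=True)
class SurvivalGroups:
    """Upper/lower expression quartile membership; middle half excluded."""

    high: frozenset[str]
    low: frozenset[str]
    excluded: frozenset[str]


@dataclass
class SurvivalResult:
    groups: SurvivalGroups
    statistic: float
    p_value: float
    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    warning: str | None = None


def logrank_statistic(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> float:
    """Two-group log-rank chi-square statistic (observed vs expected form).

    At each distinct event time t the expected group-1 events are
    d_t * n1_t / n_t and the hypergeometric variance is
    d_t (n1_t/n_t)(1 - n1_t/n_t)(n_t - d_t)/(n_t - 1); the statistic is
    (O1 - E1)^2 / V.  Censored-only times contribute nothing.  Returns 0.0
    when no events occur or the variance vanishes.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)  # True = group 1
    if not event.any():
        return 0.0
    event_times = np.unique(time[event])
    # risk sets and event counts at each event time (vectorised)
    at_risk = time[None, :] >= event_times[:, None]
    n_t = at_risk.sum(axis=1).astype(float)
    n1_t = (at_risk & group[None, :]).sum(axis=1).astype(float)
    died = (time[None, :] == event_times[:, None]) & event[None, :]
    d_t = died.sum(axis=1).astype(float)
    d1_t = (died & group[None, :]).sum(axis=1).astype(float)
    expected = d_t * n1_t / n_t
    with np.errstate(invalid="ignore", divide="ignore"):
        variance = (
            d_t * (n1_t / n_t) * (1 - n1_t / n_t) * (n_t - d_t) / (n_t - 1)
        )
    variance = np.nan_to_num(variance)
    total_var = variance.sum()
    if total_var == 0:
        return 0.0
    return float((d1_t.sum() - expected.sum()) ** 2 / total_var)


def quartile_groups(
    expression: pd.Series, quantile_method: str = "median_unbiased"
) -> SurvivalGroups:
    """Split patients at the Q1/Q3 cut points of an expression vector.

    'low' is expression <= Q1 and 'high' is expression >= Q3 (ties at a cut
    point join the group on the lower side of the cut, i.e. they are
    included rather than excluded); the middle half is excluded.
    """
    values = expression.to_numpy(dtype=float)
    q1, q3 = np.quantile(values, [0.25, 0.75], method=quantile_method)
    low = frozenset(expression.index[values <= q1].astype(str))
    high = frozenset(expression.index[values >= q3].astype(str)) - low
    excluded = frozenset(expression.index.astype(str)) - low - high
    return SurvivalGroups(high=high, low=low, excluded=excluded)


def quartile_survival(
    patients,
    expression_field: str = "isomir_rpm",
    quantile_method: str = "median_unbiased",
    fit_km: bool = True,
) -> SurvivalResult:
    """Compare survival between upper- and lower-quartile expression groups.

    Returns the group membership, the two-group log-rank statistic with its
    chi-square p on 1 df, and Kaplan-Meier survival curves per group.  When
    every subject in both groups is censored the statistic is 0 with a
    warning.
    """
    frame = _patient_frame(patients)
    frame = frame.dropna(subset=[expression_field, "survival_time", "event"])
    if len(frame) < 8:
        raise ValueError(f"need >= 8 patients with survival data, have {len(frame)}")
    frame = frame.set_index("patient_id")
    groups = quartile_groups(frame[expression_field], quantile_method)

    selected = frame.loc[list(groups.high | groups.low)]
    is_high = selected.index.isin(groups.high)
    time = selected["survival_time"].to_numpy(dtype=float)
    observed = (selected["event"] == "death").to_numpy()

    warning = None
    if not observed.any():
        statistic, p_value = 0.0, 1.0
        warning = "all events censored in both groups; log-rank undefined"
    else:
        statistic = logrank_statistic(time, observed, is_high)
        p_value = float(stats.chi2.sf(statistic, df=1))

    km_curves: dict[str, pd.DataFrame] = {}
    if fit_km:
        for label, mask in (("high", is_high), ("low", ~is_high)):
            fitter = KaplanMeierFitter()
            fitter.fit(time[mask], observed[mask], label=label)
            km_curves[label] = fitter.survival_function_
    return SurvivalResult(
        groups=groups,
        statistic=statistic,
        p_value=p_value,
        km_curves=km_curves,
        warning=warning,
    )


# ---------------------------------------------------------------------------
# Patient-table loading


DEFAULT_PATIENT_COLUMNS = {
    "patient_id": "patient_id",
    "mir_rpm": "mir_rpm",
    "isomir_rpm": "isomir_rpm",
    "er_status": "er_status",
    "metastasis": "metastasis",
    "survival_time": "survival_time",
    "event": "event",
}


def load_patient_table(
    path,
    column_map: Mapping[str, str] | None = None,
    event_codes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load a patient TSV into the canonical column layout.

    ``column_map`` maps canonical field names to the file's column names, so
    deposit-specific layouts (e.g. a clinical supplement with its own
    headers) load without reshaping; ``event_codes`` remaps event values
    (e.g. {"1": "death", "0": "censored"}).
    """
    column_map = {**DEFAULT_PATIENT_COLUMNS, **(column_map or {})}
    table = pd.read_csv(path, sep="\t")
    missing = [v for v in column_map.values() if v not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    frame = pd.DataFrame(
        {canonical: table[source] for canonical, source in column_map.items()}
    )
    if event_codes:
        frame["event"] = frame["event"].astype(str).map(event_codes)
    frame["patient_id"] = frame["patient_id"].astype(str)
    return frame
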