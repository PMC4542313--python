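"""Cohort-level statistics for clonal hemopoiesis screening.

Age-binned prevalence of mutation carriage with exact (Clopper-Pearson)
confidence intervals, summaries of clone VAF distributions, detection of
individuals carrying more than one mutation (with a convergent-evolution
flag when two or more are spliceosome-gene mutations), unpaired
two-sample comparisons of blood indices (Welch by default), and a
parameterised projection from hotspot-restricted prevalence to total
clonal-hemopoiesis prevalence.

Prevalence counts *individuals*, not clones: a person with two called
mutations contributes once to k.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import MutationCall
from .table2 import ClonalMutationRecord

#: RNA-splicing-factor genes whose mutations found MDS-like clones.
SPLICEOSOME_GENES = frozenset({"SRSF2", "SF3B1"})

DEFAULT_AGE_BINS = (
    (17, 29),
    (30, 39),
    (40, 49),
    (50, 59),
    (60, 69),
    (70, 79),
    (80, 89),
    (90, 98),
)


class AgeBinError(ValueError):
    """Ages that do not fall into exactly one bin."""


@dataclass(frozen=True)
class AgeBinSpec:
    """Ordered, non-overlapping closed integer age intervals."""

    bins: tuple[tuple[int, int], ...] = DEFAULT_AGE_BINS

    def __post_init__(self) -> None:
        prev_hi = None
        for lo, hi in self.bins:
            if hi < lo:
                raise AgeBinError(f"bin ({lo}, {hi}) has hi < lo")
            if prev_hi is not None and lo <= prev_hi:
                raise AgeBinError(f"bins overlap or are out of order at ({lo}, {hi})")
            prev_hi = hi

    @classmethod
    def from_string(cls, text: str) -> "AgeBinSpec":
        """Parse e.g. ``"17-29,30-39,40-49"``."""
        bins = []
        for part in text.split(","):
            lo, hi = part.strip().split("-")
            bins.append((int(lo), int(hi)))
        return cls(tuple(bins))

    def labels(self) -> list[str]:
        return [f"{lo}-{hi}" for lo, hi in self.bins]

    def index_of(self, age: int) -> int | None:
        for i, (lo, hi) in enumerate(self.bins):
            if lo <= age <= hi:
                return i
        return None


@dataclass
class CohortTable:
    """Screened individuals plus their mutation calls.

    ``individuals``: one row per screened person (``sample_id``,
    ``age_years``, optional ``hemoglobin`` / ``platelets``).
    ``calls``: one row per sample x hotspot outcome with at least
    ``sample_id``, ``gene``, ``hotspot``, ``called`` columns.
    """

    individuals: pd.DataFrame
    calls: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ids = self.individuals["sample_id"]
        if ids.duplicated().any():
            dupes = sorted(ids[ids.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dupes}")
        if (self.individuals["age_years"] < 0).any():
            raise ValueError("negative ages in cohort")

    @classmethod
    def from_calls(
        cls, individuals: pd.DataFrame, calls: Iterable[MutationCall]
    ) -> "CohortTable":
        rows = [
            {
                "sample_id": c.sample_id,
                "gene": c.hotspot_label.split()[0],
                "hotspot": c.hotspot_label,
                "vaf": c.vaf,
                "called": c.called,
            }
            for c in calls
        ]
        return cls(individuals, pd.DataFrame(rows))


def _clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=confidence, method="exact")
    return float(ci.low), float(ci.high)


def prevalence_by_age(
    cohort: CohortTable,
    bins: AgeBinSpec | None = None,
    class_filter: Sequence[str] | None = None,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-age-bin carrier prevalence with exact binomial CIs.

    ``class_filter`` restricts the numerator to calls whose gene *or*
    hotspot label is in the given set.  k counts individuals with at
    least one qualifying called mutation; every individual must fall in
    exactly one bin (ages outside all bins raise, listing the offenders).
    Display percentages are rounded to one decimal.
    """
    bins = bins if bins is not None else AgeBinSpec()
    ages = cohort.individuals["age_years"]
    bin_idx = ages.map(bins.index_of)
    if bin_idx.isna().any():
        stray = sorted(ages[bin_idx.isna()].unique())
        raise AgeBinError(f"ages outside all bins: {stray}")

    calls = cohort.calls
    if len(calls) and "called" in calls:
        hit = calls[calls["called"].astype(bool)]
        if class_filter is not None:
            wanted = set(class_filter)
            hit = hit[hit["gene"].isin(wanted) | hit["hotspot"].isin(wanted)]
        carriers = set(hit["sample_id"])
    else:
        carriers = set()

    rows = []
    labels = bins.labels()
    for i, label in enumerate(labels):
        members = cohort.individuals.loc[bin_idx == i, "sample_id"]
        n = len(members)
        k = sum(1 for sid in members if sid in carriers)
        if n > 0:
            lo, hi = _clopper_pearson(k, n, confidence)
            prev = k / n
        else:
            lo = hi = prev = float("nan")
        rows.append(
            {
                "age_bin": label,
                "n": n,
                "k": k,
                "prevalence": prev,
                "pct": round(100.0 * prev, 1) if n else float("nan"),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CloneSummary:
    total: int
    at_or_below_cut: int
    cut_percent: float
    gene_set: frozenset[str] | None = None


def summarize_clones(
    records: Sequence[ClonalMutationRecord],
    vaf_cut_percent: float,
    gene_set: Iterable[str] | None = None,
) -> CloneSummary:
    """Count clones at or below a VAF cut (inclusive), optionally by gene set."""
    if not records:
        raise ValueError("no clone records to summarise")
    genes = frozenset(gene_set) if gene_set is not None else None
    pool = [r for r in records if genes is None or r.gene in genes]
    low = [r for r in pool if r.vaf_percent <= vaf_cut_percent]
    return CloneSummary(len(pool), len(low), vaf_cut_percent, genes)


@dataclass(frozen=True)
class MutationGroup:
    """Mutations found in the same individual (>= 2 of them)."""

    key: str
    records: tuple[ClonalMutationRecord, ...]
    n_spliceosome: int

    @property
    def convergent_spliceosome(self) -> bool:
        """Two or more independent spliceosome-gene mutations in one person."""
        return self.n_spliceosome >= 2


def multi_mutation_groups(
    records: Sequence[ClonalMutationRecord],
) -> list[MutationGroup]:
    """Group records by same-sample symbol; return groups of size >= 2."""
    by_key: dict[str, list[ClonalMutationRecord]] = {}
    for r in records:
        if r.sample_symbol:
            by_key.setdefault(r.sample_symbol, []).append(r)
    groups = []
    for key in sorted(by_key):
        members = by_key[key]
        if len(members) < 2:
            continue
        n_sp = sum(1 for r in members if r.gene in SPLICEOSOME_GENES)
        groups.append(MutationGroup(key, tuple(members), n_sp))
    return groups


def distinct_individuals(records: Sequence[ClonalMutationRecord]) -> int:
    """Number of distinct mutation carriers: singletons plus symbol groups."""
    grouped = [r for r in records if r.sample_symbol]
    singles = len(records) - len(grouped)
    return singles + len({r.sample_symbol for r in grouped})


def min_age_by_class(
    records: Sequence[ClonalMutationRecord], gene_set: Iterable[str]
) -> int:
    """Youngest carrier age among records of the given gene class."""
    genes = set(gene_set)
    ages = [r.age_years for r in records if r.gene in genes]
    if not ages:
        raise ValueError(f"no records for gene class {sorted(genes)}")
    return min(ages)


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> TTestResult:
    """Unpaired two-sample t test (Welch unequal-variance by default).

    Welch is the default because screened-group comparisons here are
    heavily unbalanced (e.g. ~100 carriers vs ~3,500 non-carriers); the
    classical pooled test is available via ``equal_var=True``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite values in input")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            raise ValueError("both groups constant and equal: t test undefined")
        raise ValueError("both groups have zero variance: t test undefined")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def project_total_incidence(
    p_hotspot: float, driver_ratio: float, mode: str = "independent-union"
) -> dict:
    """Project hotspot-restricted prevalence to all-driver prevalence.

    The screen interrogates a fixed set of hotspots; if the full driver
    landscape holds ``driver_ratio`` (r >= 1) times as many equally
    behaving mutation targets, independent acquisition gives a projected
    prevalence of ``1 - (1 - p)^r`` (mode ``independent-union``), while a
    small-p linear extrapolation capped at 1 gives ``min(1, r * p)``
    (mode ``linear-capped``).  The two agree to first order as p -> 0.
    """
    if not 0.0 <= p_hotspot <= 1.0:
        raise ValueError(f"p_hotspot must be in [0, 1], got {p_hotspot}")
    if driver_ratio < 1.0:
        raise ValueError(f"driver_ratio must be >= 1, got {driver_ratio}")
    if mode == "independent-union":
        value = 1.0 - (1.0 - p_hotspot) ** driver_ratio
    elif mode == "linear-capped":
        value = min(1.0, driver_ratio * p_hotspot)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return {"projected_prevalence": value, "mode": mode, "driver_ratio": driver_ratio}


def plot_prevalence(prev: pd.DataFrame, ax=None):
    """Bar chart of prevalence by age bin with exact-CI error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    x = np.arange(len(prev))
    ax.bar(x, 100 * prev["prevalence"], color="#4878a8")
    yerr = np.vstack(
        [
            100 * (prev["prevalence"] - prev["ci_low"]),
            100 * (prev["ci_high"] - prev["prevalence"]),
        ]
    )
    ax.errorbar(x, 100 * prev["prevalence"], yerr=yerr, fmt="none", ecolor="black", capsize=3)
    ax.set_xticks(x, prev["age_bin"], rotation=45)
    ax.set_xlabel("Age group (years)")
    ax.set_ylabel("Carrier prevalence (%)")
    return ax
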