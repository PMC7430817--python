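"""Cross-level sex-ratio and sex-linkage statistics.

Works on offspring genotyping tables from controlled crosses: one row per
offspring with a phenotype (male / female / undifferentiated, the last from
gonads too immature to score) and a positive/negative call per Y-marker
primer. Provides the descriptive summaries (female:male ratio, percent
males, marker-positive tallies), Fisher's exact test of genotype-phenotype
sex linkage, the chi-square test of a 1:1 sex ratio, and the
female-to-male sex-reversal rate with its Clopper-Pearson interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

MALE = "male"
FEMALE = "female"
UNDIFFERENTIATED = "undifferentiated"
POSITIVE = "positive"
NEGATIVE = "negative"

_META_COLUMNS = {"offspring_id", "id", "cross", "phenotype"}


def marker_columns(records: pd.DataFrame) -> list[str]:
    """Columns holding per-primer marker calls (everything but metadata)."""
    return [c for c in records.columns if c not in _META_COLUMNS]


def read_cross_table(path: str | Path) -> pd.DataFrame:
    records = pd.read_csv(path)
    if "phenotype" not in records.columns:
        raise ValueError("cross table needs a 'phenotype' column")
    if not marker_columns(records):
        raise ValueError("cross table needs at least one marker column")
    return records


@dataclass(frozen=True)
class CrossSummary:
    """Cohort counts and the derived printed-style ratios.

    ratio_female_male is reported truncated toward zero at one decimal
    (e.g. 83:7 -> 11.8) and is None when there are no males;
    percent_males (among sexed offspring) uses half-up rounding to one
    decimal and is None when no offspring are sexed.
    """

    n_males: int
    n_females: int
    n_undifferentiated: int
    ratio_female_male: float | None
    percent_males: float | None
    marker_positive: dict = field(default_factory=dict)

    @property
    def cohort_size(self) -> int:
        return self.n_males + self.n_females + self.n_undifferentiated


def _truncated_ratio(n_females: int, n_males: int) -> float | None:
    if n_males == 0:
        return None
    return (10 * n_females // n_males) / 10


def _percent_males(n_males: int, n_females: int) -> float | None:
    sexed = n_males + n_females
    if sexed == 0:
        return None
    percent = Decimal(100 * n_males) / Decimal(sexed)
    return float(percent.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_cross(records: pd.DataFrame) -> CrossSummary:
    """Phenotype counts, printed-style ratios, marker-positive tallies."""
    if len(records) == 0:
        raise ValueError("empty cohort")
    phen = records["phenotype"]
    unknown = set(phen) - {MALE, FEMALE, UNDIFFERENTIATED}
    if unknown:
        raise ValueError(f"unknown phenotypes: {sorted(unknown)}")
    n_males = int((phen == MALE).sum())
    n_females = int((phen == FEMALE).sum())
    n_undiff = int((phen == UNDIFFERENTIATED).sum())
    positives: dict[str, dict[str, tuple[int, int]]] = {}
    for col in marker_columns(records):
        positives[col] = {
            cls: (
                int(((phen == cls) & (records[col] == POSITIVE)).sum()),
                int((phen == cls).sum()),
            )
            for cls in (MALE, FEMALE, UNDIFFERENTIATED)
        }
    return CrossSummary(
        n_males=n_males,
        n_females=n_females,
        n_undifferentiated=n_undiff,
        ratio_female_male=_truncated_ratio(n_females, n_males),
        percent_males=_percent_males(n_males, n_females),
        marker_positive=positives,
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 count table.

    Uses the standard two-sided definition: the sum of hypergeometric
    probabilities of all tables (with the observed margins) no more likely
    than the observed one.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0):
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("table entries must be integers")
        arr = np.round(arr).astype(np.int64)
    p = stats.fisher_exact(arr, alternative="two-sided").pvalue
    return float(min(p, 1.0))


@dataclass(frozen=True)
class LinkageResult:
    """Fisher test of phenotype (male/female) x marker (positive/negative)."""

    marker: str
    table: tuple[tuple[int, int], tuple[int, int]]
    p: float
    significant: bool

    @property
    def label(self) -> str:
        return "linked" if self.significant else "NS"


def sex_linkage_test(
    records: pd.DataFrame, marker: str, alpha: float = 0.05
) -> LinkageResult:
    """Test whether a marker's calls segregate with phenotypic sex.

    Undifferentiated offspring are excluded (they are reported separately by
    :func:`summarize_cross`); a cohort with no sexed offspring is refused.
    """
    if marker not in records.columns:
        raise ValueError(f"unknown marker column {marker!r}")
    sexed = records[records["phenotype"].isin([MALE, FEMALE])]
    if len(sexed) == 0:
        raise ValueError("no differentiated offspring: linkage test undefined")
    calls = sexed[marker]
    unknown = set(calls) - {POSITIVE, NEGATIVE}
    if unknown:
        raise ValueError(f"unknown marker calls: {sorted(unknown)}")
    table = (
        (
            int(((sexed["phenotype"] == MALE) & (calls == POSITIVE)).sum()),
            int(((sexed["phenotype"] == MALE) & (calls == NEGATIVE)).sum()),
        ),
        (
            int(((sexed["phenotype"] == FEMALE) & (calls == POSITIVE)).sum()),
            int(((sexed["phenotype"] == FEMALE) & (calls == NEGATIVE)).sum()),
        ),
    )
    p = fisher_exact_2x2(table)
    return LinkageResult(marker=marker, table=table, p=p, significant=p < alpha)


@dataclass(frozen=True)
class SexRatioResult:
    chi2: float
    p: float


def sex_ratio_test(n_males: int, n_females: int) -> SexRatioResult:
    """Chi-square goodness of fit of the sexed counts to a 1:1 ratio.

    One degree of freedom, no continuity correction.
    """
    if n_males < 0 or n_females < 0:
        raise ValueError("counts must be non-negative")
    if n_males + n_females == 0:
        raise ValueError("no sexed offspring")
    result = stats.chisquare([n_males, n_females])
    return SexRatioResult(chi2=float(result.statistic), p=float(result.pvalue))


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial confidence interval for k successes of n."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n with n > 0")
    alpha = 1.0 - confidence
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class SexReversalEstimate:
    """Female-to-male sex-reversal rate among sexed offspring of an XX sire."""

    n_males: int
    n_sexed: int
    rate: float
    ci_low: float
    ci_high: float

    @property
    def percent(self) -> float:
        """Rate as a percentage, half-up rounded to one decimal."""
        value = Decimal(100 * self.n_males) / Decimal(self.n_sexed)
        return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def estimate_sex_reversal(
    records: pd.DataFrame, confidence: float = 0.95
) -> SexReversalEstimate:
    """Sex-reversal rate males/(males+females) with its exact binomial CI.

    In an XX-sired cross every offspring is genetically female, so every
    phenotypic male is a sex-reversed neomale. Undifferentiated offspring
    are excluded; a cohort with none sexed is refused.
    """
    phen = records["phenotype"]
    n_males = int((phen == MALE).sum())
    n_sexed = n_males + int((phen == FEMALE).sum())
    if n_sexed == 0:
        raise ValueError("no sexed offspring: rate undefined")
    lo, hi = clopper_pearson(n_males, n_sexed, confidence)
    return SexReversalEstimate(
        n_males=n_males,
        n_sexed=n_sexed,
        rate=n_males / n_sexed,
        ci_low=lo,
        ci_high=hi,
    )
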