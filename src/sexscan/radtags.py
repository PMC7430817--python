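"""Per-individual RAD-tag presence/absence analysis.

A RAD tag is an exact sequence unit scored per individual as a depth count.
In a male-heterogametic (XX/XY) system, tags anchored in the non-recombining
Y region are carried only by XY individuals, so a tag present in many
phenotypic males and absent from all females is a candidate Y-linked marker.
This module thresholds depths into presence calls, tabulates the joint
(males, females) carrier distribution, tests each tag for sex bias with a
Pearson chi-square (Bonferroni-corrected over carried tags), extracts
male-specific markers, and classifies phenotypic males into Y-carriers (XY)
versus putative neomales (sex-reversed XX) from their marker complement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

MALE = "male"
FEMALE = "female"
_SEX_LABELS = {MALE, FEMALE}


@dataclass
class TagMatrix:
    """Per-individual tag depths plus sex labels.

    depths
        integer DataFrame, rows indexed by unique tag id, one column per
        individual.
    sexes
        Series mapping every individual (column) to "male" or "female".
    sequences
        optional Series of tag sequences indexed like ``depths``.
    """

    depths: pd.DataFrame
    sexes: pd.Series
    sequences: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.depths.index.has_duplicates:
            raise ValueError("tag ids must be unique")
        if (self.depths.to_numpy() < 0).any():
            raise ValueError("tag depths must be non-negative")
        missing = [c for c in self.depths.columns if c not in self.sexes.index]
        if missing:
            raise ValueError(f"individuals without a sex label: {missing}")
        bad = set(self.sexes.loc[list(self.depths.columns)]) - _SEX_LABELS
        if bad:
            raise ValueError(f"unknown sex labels: {sorted(bad)}")

    @property
    def individuals(self) -> list[str]:
        return list(self.depths.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = self.depths.copy()
        seq = (
            self.sequences.reindex(out.index)
            if self.sequences is not None
            else pd.Series("", index=out.index)
        )
        out.insert(0, "sequence", seq)
        out.index.name = "tag_id"
        out.to_csv(path, sep="\t")


def read_tag_matrix(
    matrix_path: str | Path, registry_path: str | Path
) -> TagMatrix:
    """Load a tag-depth TSV and a sex-registry CSV into a :class:`TagMatrix`.

    The TSV carries tag_id, sequence, then one depth column per individual;
    the registry CSV carries id and phenotype columns.
    """
    table = pd.read_csv(matrix_path, sep="\t", index_col="tag_id")
    table.index.name = None
    sequences = table["sequence"].fillna("").astype(str)
    depths = table.drop(columns=["sequence"]).astype(np.int64)
    registry = pd.read_csv(registry_path)
    sexes = registry.set_index("id")["phenotype"]
    return TagMatrix(depths=depths, sexes=sexes, sequences=sequences)


@dataclass(frozen=True)
class RadSexParams:
    """Thresholds of the presence/absence analysis.

    min_depth: reads needed to call a tag present in an individual.
    min_males / max_females: bounds defining a male-specific tag (inclusive).
    alpha: significance level applied after Bonferroni correction over the
    number of distinct carried tags.
    """

    min_depth: int = 1
    min_males: int = 12
    max_females: int = 0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.min_males < 0 or self.max_females < 0:
            raise ValueError("carrier bounds must be non-negative")


@dataclass
class TagDistribution:
    """Grid d[x, y] = number of tags carried by exactly x males and y females."""

    grid: np.ndarray
    n_males: int
    n_females: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.grid,
            index=pd.RangeIndex(self.n_males + 1, name="n_males"),
            columns=pd.RangeIndex(self.n_females + 1, name="n_females"),
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_presence(matrix: TagMatrix, min_depth: int = 1) -> pd.DataFrame:
    """Boolean presence table: present iff depth >= min_depth."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return matrix.depths >= min_depth


def _split_by_sex(
    presence: pd.DataFrame, sexes: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    missing = [c for c in presence.columns if c not in sexes.index]
    if missing:
        raise ValueError(f"individuals without a sex label: {missing}")
    labels = sexes.loc[list(presence.columns)]
    bad = set(labels) - _SEX_LABELS
    if bad:
        raise ValueError(f"unknown sex labels: {sorted(bad)}")
    males = presence.loc[:, labels[labels == MALE].index]
    females = presence.loc[:, labels[labels == FEMALE].index]
    return males, females


def tag_distribution(presence: pd.DataFrame, sexes: pd.Series) -> TagDistribution:
    """Tabulate tags by their number of male and female carriers.

    The (0, 0) cell stays zero: tags absent from every individual are not
    counted, so the grid total equals the number of carried tags.
    """
    if presence.shape[1] == 0:
        raise ValueError("presence table has no individuals")
    males, females = _split_by_sex(presence, sexes)
    x = males.sum(axis=1).to_numpy(dtype=np.int64)
    y = females.sum(axis=1).to_numpy(dtype=np.int64)
    n_males = males.shape[1]
    n_females = females.shape[1]
    grid = np.zeros((n_males + 1, n_females + 1), dtype=np.int64)
    carried = (x + y) > 0
    np.add.at(grid, (x[carried], y[carried]), 1)
    return TagDistribution(grid=grid, n_males=n_males, n_females=n_females)


def sex_bias_test(x_males: int, y_females: int, n_males: int, n_females: int) -> float:
    """Pearson chi-square p-value (1 df, no continuity correction) for sex bias.

    The 2x2 table contrasts carriers and non-carriers between the sexes:
    [[x, n_males - x], [y, n_females - y]]. Degenerate tables (no carriers,
    or carriers in every individual, or one sex absent) return 1.0.
    """
    if min(x_males, y_females, n_males, n_females) < 0:
        raise ValueError("counts must be non-negative")
    if x_males > n_males or y_females > n_females:
        raise ValueError("carriers cannot exceed group size")
    carriers = x_males + y_females
    non_carriers = (n_males - x_males) + (n_females - y_females)
    if carriers == 0 or non_carriers == 0 or n_males == 0 or n_females == 0:
        return 1.0
    table = [
        [x_males, n_males - x_males],
        [y_females, n_females - y_females],
    ]
    result = stats.chi2_contingency(table, correction=False)
    return float(result.pvalue)


def association_table(presence: pd.DataFrame, sexes: pd.Series) -> pd.DataFrame:
    """Per-tag carrier counts and sex-bias p-values.

    Bonferroni correction runs over the number of distinct carried tags
    (tags with at least one carrier); uncarried tags get p = p_adj = 1.
    """
    males, females = _split_by_sex(presence, sexes)
    x = males.sum(axis=1)
    y = females.sum(axis=1)
    n_males = males.shape[1]
    n_females = females.shape[1]
    n_tests = int(((x + y) > 0).sum())
    pvals = np.array(
        [
            sex_bias_test(int(xi), int(yi), n_males, n_females)
            for xi, yi in zip(x, y)
        ]
    )
    p_adj = np.minimum(pvals * max(n_tests, 1), 1.0)
    return pd.DataFrame(
        {"tag_id": presence.index, "x": x.to_numpy(), "y": y.to_numpy(),
         "p": pvals, "p_adj": p_adj}
    ).set_index("tag_id")


def significant_tags(
    presence: pd.DataFrame, sexes: pd.Series, params: RadSexParams
) -> pd.DataFrame:
    """Tags significantly associated with sex after Bonferroni correction.

    Returns the association table restricted to tags with p_adj < alpha,
    sorted by tag id.
    """
    table = association_table(presence, sexes)
    hits = table[table["p_adj"] < params.alpha]
    return hits.sort_index()


def male_specific_tags(
    presence: pd.DataFrame, sexes: pd.Series, params: RadSexParams
) -> list[str]:
    """Tags present in >= min_males males and <= max_females females (sorted)."""
    males, females = _split_by_sex(presence, sexes)
    x = males.sum(axis=1)
    y = females.sum(axis=1)
    keep = presence.index[(x >= params.min_males) & (y <= params.max_females)]
    return sorted(keep)


@dataclass
class NeomaleSummary:
    """Y-carrier tally among phenotypic males."""

    n_pheno_males: int
    n_y_carriers: int

    @property
    def neomale_fraction(self) -> float:
        return 1.0 - self.n_y_carriers / self.n_pheno_males


def classify_individuals(
    presence: pd.DataFrame,
    sexes: pd.Series,
    male_tags: Sequence[str],
    min_carry_fraction: float = 0.5,
) -> tuple[pd.DataFrame, NeomaleSummary]:
    """Call each individual Y-carrier or non-carrier from the marker panel.

    An individual is a Y-carrier when it carries at least min_carry_fraction
    of the male-specific tags (tolerating tag dropout). The summary reports
    the putative neomale fraction among phenotypic males: 1 - carriers/males.
    """
    male_tags = list(male_tags)
    if not male_tags:
        raise ValueError("male_tags must be nonempty")
    missing = [t for t in male_tags if t not in presence.index]
    if missing:
        raise ValueError(f"marker tags absent from presence table: {missing}")
    labels = sexes.loc[list(presence.columns)]
    carried = presence.loc[male_tags].sum(axis=0)
    fraction = carried / len(male_tags)
    calls = pd.DataFrame(
        {
            "phenotype": labels,
            "n_markers": len(male_tags),
            "n_carried": carried,
            "carry_fraction": fraction,
            "call": np.where(
                fraction >= min_carry_fraction, "Y-carrier", "non-carrier"
            ),
        }
    )
    calls.index.name = "id"
    n_males = int((labels == MALE).sum())
    if n_males == 0:
        raise ValueError("no phenotypic males: neomale summary undefined")
    n_carriers = int((calls.loc[labels == MALE, "call"] == "Y-carrier").sum())
    return calls, NeomaleSummary(n_pheno_males=n_males, n_y_carriers=n_carriers)


def write_marker_fasta(
    matrix: TagMatrix, tag_ids: Sequence[str], path: str | Path
) -> None:
    """Write marker tag sequences as FASTA (tags without sequence are skipped)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    if matrix.sequences is None:
        raise ValueError("tag matrix carries no sequences")
    records = [
        SeqRecord(Seq(str(matrix.sequences.loc[t])), id=str(t), description="")
        for t in tag_ids
        if str(matrix.sequences.loc[t])
    ]
    seqio_write(records, str(path), "fasta")
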