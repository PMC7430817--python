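"""Seeded generators of ground-truthed synthetic inputs.

The generators emulate the statistical structure the analysis assumes: a
male-heterogametic (XX/XY) population in which some phenotypic males are
sex-reversed XX neomales (an environmental effect), a genome with one
planted non-recombining Y-divergent region (SDR), shared background
polymorphism, RAD-tag dropout, and pooled sequencing of each sex. Every
generator draws from its own child stream of a single integer seed, so all
outputs are byte-identical across runs with the same parameters, and the
planted truth is returned alongside the data.

Depth models: tag depths are shifted Poisson (minimum 1 when present); pool
site depths are Poisson(pool_depth) independently per pool. Y-divergent
sites are biallelic (reference allele plus one Y allele). Sex reversal is
applied only female-to-male (XX neomales); XY individuals never develop as
females except through marker-call discordance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .poolscan import SyncRecord, write_sync  # noqa: F401  (re-exported writer)
from .radtags import TagMatrix

_BASES = "ATCG"
# distinct child-stream keys so each generator has an independent stream
_STREAMS = {"individuals": 1, "tags": 2, "sync": 3, "cross": 4}

XX = "XX"
XY = "XY"


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    key = (_STREAMS[stream], extra)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass(frozen=True)
class GenomeModel:
    """Stand-in genome: linkage groups with one planted Y-divergent region.

    linkage_groups
        ordered (name, length in bp) pairs.
    sdr
        (linkage group, start, end), a 1-based closed interval.
    background_snp_rate
        expected shared-polymorphism sites per bp, genome-wide.
    y_divergent_rate
        expected Y-specific divergent sites per bp inside the SDR.
    """

    linkage_groups: tuple[tuple[str, int], ...]
    sdr: tuple[str, int, int]
    background_snp_rate: float = 1e-4
    y_divergent_rate: float = 5e-4

    def __post_init__(self) -> None:
        if not self.linkage_groups:
            raise ValueError("genome must have at least one linkage group")
        lengths = dict(self.linkage_groups)
        if len(lengths) != len(self.linkage_groups):
            raise ValueError("linkage group names must be unique")
        if any(length < 1 for length in lengths.values()):
            raise ValueError("linkage group lengths must be >= 1")
        chrom, start, end = self.sdr
        if chrom not in lengths:
            raise ValueError(f"SDR chromosome {chrom!r} not in genome")
        if not (1 <= start <= end <= lengths[chrom]):
            raise ValueError("SDR interval must lie within its linkage group")
        for rate in (self.background_snp_rate, self.y_divergent_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("site rates must lie in [0, 1]")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return dict(self.linkage_groups)

    @property
    def sdr_length(self) -> int:
        return self.sdr[2] - self.sdr[1] + 1


def default_genome() -> GenomeModel:
    """Desk-scale default: 5 x 40 Mb linkage groups, 12 Mb SDR on LG22.

    Site rates are deliberately sparse (one background SNP per 10 kb, five
    Y-divergent sites per 10 kb inside the SDR) so whole-genome scans run in
    seconds while keeping ~50 divergent sites per 100 kb window.
    """
    names = ("LG03", "LG09", "LG22", "LG35", "LG47")
    return GenomeModel(
        linkage_groups=tuple((n, 40_000_000) for n in names),
        sdr=("LG22", 14_000_001, 26_000_000),
        background_snp_rate=1e-4,
        y_divergent_rate=5e-4,
    )


@dataclass(frozen=True)
class PopulationParams:
    """Population, noise and sequencing parameters of the simulation.

    neomale_rate
        probability that a phenotypic male is genetically XX (sex-reversed).
    undiff_rate
        probability that an offspring's gonad is undifferentiated at sexing.
    discordance
        probability that a marker call contradicts the true genotype.
    pool_depth
        mean per-site sequencing depth of each pool (Poisson).
    tag_dropout
        probability that a truly present RAD tag has depth 0 in an individual.
    """

    n_pheno_males: int = 30
    n_pheno_females: int = 30
    neomale_rate: float = 0.5
    undiff_rate: float = 0.1
    discordance: float = 0.01
    pool_depth: float = 50.0
    tag_dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("neomale_rate", "undiff_rate", "discordance", "tag_dropout"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_pheno_males < 0 or self.n_pheno_females < 0:
            raise ValueError("individual counts must be non-negative")
        if self.pool_depth <= 0:
            raise ValueError("pool_depth must be positive")


@dataclass
class SimTruth:
    """Planted ground truth accompanying every synthetic dataset."""

    genotypes: dict[str, str]
    phenotypes: dict[str, str]
    sdr: tuple[str, int, int] | None = None
    y_tag_ids: list[str] = field(default_factory=list)
    y_tag_positions: dict[str, tuple[str, int]] = field(default_factory=dict)
    site_classes: dict[tuple[str, int], str] = field(default_factory=dict)

    def ids_with_genotype(self, genotype: str) -> list[str]:
        return [i for i, g in self.genotypes.items() if g == genotype]


def simulate_individuals(params: PopulationParams) -> tuple[pd.DataFrame, SimTruth]:
    """Draw genotypes for a phenotyped population.

    Phenotypic females are all XX; each phenotypic male is XY with
    probability 1 - neomale_rate and XX (a neomale) otherwise. Returns the
    sex registry (id, phenotype) and the genotype truth.
    """
    if params.n_pheno_males == 0 or params.n_pheno_females == 0:
        raise ValueError("both sexes need at least one individual")
    rng = _rng(params.seed, "individuals")
    genotypes: dict[str, str] = {}
    phenotypes: dict[str, str] = {}
    for i in range(params.n_pheno_males):
        ind = f"M{i + 1:03d}"
        genotypes[ind] = XX if rng.random() < params.neomale_rate else XY
        phenotypes[ind] = "male"
    for i in range(params.n_pheno_females):
        ind = f"F{i + 1:03d}"
        genotypes[ind] = XX
        phenotypes[ind] = "female"
    registry = pd.DataFrame(
        {"id": list(genotypes), "phenotype": [phenotypes[i] for i in genotypes]}
    )
    return registry, SimTruth(genotypes=genotypes, phenotypes=phenotypes)


def simulate_tag_matrix(
    truth: SimTruth,
    genome: GenomeModel,
    params: PopulationParams,
    n_autosomal_tags: int = 500,
    n_y_tags: int = 32,
    mean_depth: float = 20.0,
    seq_length: int = 60,
) -> TagMatrix:
    """Simulate the per-individual RAD-tag depth matrix.

    Autosomal tags are present in every individual; Y tags are present only
    in XY individuals and anchored at positions drawn inside the SDR. Both
    are thinned by the dropout probability, and present tags draw a shifted
    Poisson depth (minimum 1). Updates ``truth`` with the planted Y-tag ids
    and positions.
    """
    if n_y_tags < 0 or n_autosomal_tags < 0:
        raise ValueError("tag counts must be non-negative")
    if mean_depth < 1:
        raise ValueError("mean_depth must be >= 1")
    rng = _rng(params.seed, "tags")
    individuals = list(truth.genotypes)
    is_xy = np.array([truth.genotypes[i] == XY for i in individuals])

    auto_ids = [f"tag_a{i + 1:04d}" for i in range(n_autosomal_tags)]
    y_ids = [f"tag_y{i + 1:04d}" for i in range(n_y_tags)]
    tag_ids = auto_ids + y_ids
    n_tags = len(tag_ids)
    n_ind = len(individuals)

    present = np.ones((n_tags, n_ind), dtype=bool)
    present[n_autosomal_tags:, :] = is_xy[np.newaxis, :]
    depths = 1 + rng.poisson(mean_depth - 1.0, size=(n_tags, n_ind))
    dropout = rng.random((n_tags, n_ind)) < params.tag_dropout
    depths = np.where(present & ~dropout, depths, 0)

    sequences = pd.Series(
        ["".join(rng.choice(list(_BASES), size=seq_length)) for _ in range(n_tags)],
        index=tag_ids,
    )
    sdr_chrom, sdr_start, sdr_end = genome.sdr
    truth.sdr = genome.sdr
    truth.y_tag_ids = list(y_ids)
    truth.y_tag_positions = {
        t: (sdr_chrom, int(p))
        for t, p in zip(y_ids, rng.integers(sdr_start, sdr_end + 1, size=n_y_tags))
    }

    sexes = pd.Series({i: truth.phenotypes[i] for i in individuals})
    return TagMatrix(
        depths=pd.DataFrame(depths, index=tag_ids, columns=individuals),
        sexes=sexes,
        sequences=sequences,
    )


def _allele_counts(depth: np.ndarray, alt: np.ndarray, ref_idx: np.ndarray,
                   alt_idx: np.ndarray) -> np.ndarray:
    """Assemble (n, 6) A:T:C:G:N:del count rows from ref/alt draws."""
    n = len(depth)
    counts = np.zeros((n, 6), dtype=np.int64)
    counts[np.arange(n), ref_idx] = depth - alt
    counts[np.arange(n), alt_idx] += alt
    return counts


def simulate_sync(
    truth: SimTruth,
    genome: GenomeModel,
    params: PopulationParams,
    male_pool: Sequence[str] | None = None,
    female_pool: Sequence[str] | None = None,
) -> list[SyncRecord]:
    """Simulate the two-pool sync stream for the given pool memberships.

    Background sites are shared polymorphisms with a common allele frequency
    in both pools; Y-divergent sites (planted only inside the SDR) carry the
    Y allele at expected male-pool frequency n_XY / (2 * pool size) and are
    fixed for the reference allele in the female pool. Per-site pool depths
    are Poisson(pool_depth). Updates ``truth.site_classes`` with the per-site
    class ("background" / "y_divergent") keyed by (chrom, pos).
    """
    if male_pool is None:
        male_pool = [i for i, p in truth.phenotypes.items() if p == "male"]
    if female_pool is None:
        female_pool = [i for i, p in truth.phenotypes.items() if p == "female"]
    if len(male_pool) == 0 or len(female_pool) == 0:
        raise ValueError("both pools need at least one individual")
    unknown = [i for i in [*male_pool, *female_pool] if i not in truth.genotypes]
    if unknown:
        raise ValueError(f"pool members without genotype truth: {unknown}")

    rng = _rng(params.seed, "sync")
    n_xy = sum(truth.genotypes[i] == XY for i in male_pool)
    p_y = n_xy / (2 * len(male_pool))
    lam = params.pool_depth
    sdr_chrom, sdr_start, sdr_end = genome.sdr
    truth.sdr = genome.sdr

    records: list[SyncRecord] = []
    for chrom, length in genome.linkage_groups:
        n_bg = rng.poisson(length * genome.background_snp_rate)
        bg_pos = np.unique(rng.integers(1, length + 1, size=n_bg))
        if chrom == sdr_chrom:
            n_y = rng.poisson(genome.sdr_length * genome.y_divergent_rate)
            y_pos = np.unique(rng.integers(sdr_start, sdr_end + 1, size=n_y))
            bg_pos = np.setdiff1d(bg_pos, y_pos, assume_unique=True)
        else:
            y_pos = np.empty(0, dtype=np.int64)

        pos = np.concatenate([bg_pos, y_pos])
        is_y = np.concatenate(
            [np.zeros(len(bg_pos), dtype=bool), np.ones(len(y_pos), dtype=bool)]
        )
        order = np.argsort(pos, kind="stable")
        pos, is_y = pos[order], is_y[order]
        n = len(pos)
        if n == 0:
            continue

        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        depth_m = rng.poisson(lam, size=n)
        depth_f = rng.poisson(lam, size=n)
        freq_bg = rng.uniform(0.1, 0.9, size=n)
        p_m = np.where(is_y, p_y, freq_bg)
        p_f = np.where(is_y, 0.0, freq_bg)
        alt_m = rng.binomial(depth_m, p_m)
        alt_f = rng.binomial(depth_f, p_f)

        male_counts = _allele_counts(depth_m, alt_m, ref_idx, alt_idx)
        female_counts = _allele_counts(depth_f, alt_f, ref_idx, alt_idx)
        for j in range(n):
            records.append(
                SyncRecord(
                    chrom=chrom,
                    pos=int(pos[j]),
                    ref=_BASES[ref_idx[j]],
                    male=tuple(int(c) for c in male_counts[j]),
                    female=tuple(int(c) for c in female_counts[j]),
                )
            )
            truth.site_classes[(chrom, int(pos[j]))] = (
                "y_divergent" if is_y[j] else "background"
            )
    return records


def simulate_cross(
    sire_genotype: str,
    params: PopulationParams,
    n_offspring: int = 120,
    marker_names: Sequence[str] = ("yprimer1", "yprimer2", "yprimer3"),
    cross_id: str | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Simulate offspring phenotypes and marker calls for one cross.

    The dam is XX. An XY sire transmits Y to each offspring with probability
    0.5; an XX sire gives all-XX offspring. XY offspring are phenotypic
    males; XX offspring become males with probability neomale_rate; with
    probability undiff_rate the gonad is undifferentiated, overriding the
    phenotype. Marker calls follow genotype, flipped independently with
    probability discordance. Returns the records and the genotype truth.
    """
    if sire_genotype not in (XX, XY):
        raise ValueError("sire genotype must be 'XX' or 'XY' (dam is XX)")
    if n_offspring < 1:
        raise ValueError("need at least one offspring")
    if rng is None:
        rng = _rng(params.seed, "cross", extra=0 if sire_genotype == XX else 1)
    if cross_id is None:
        cross_id = f"P({sire_genotype})"

    is_xy = (
        rng.random(n_offspring) < 0.5
        if sire_genotype == XY
        else np.zeros(n_offspring, dtype=bool)
    )
    pheno = np.where(
        is_xy, "male", np.where(rng.random(n_offspring) < params.neomale_rate,
                                "male", "female")
    )
    undiff = rng.random(n_offspring) < params.undiff_rate
    pheno = np.where(undiff, "undifferentiated", pheno)

    data = {
        "offspring_id": [f"{cross_id}_{i + 1:03d}" for i in range(n_offspring)],
        "cross": cross_id,
        "phenotype": pheno,
    }
    for marker in marker_names:
        flip = rng.random(n_offspring) < params.discordance
        positive = is_xy ^ flip
        data[marker] = np.where(positive, "positive", "negative")
    records = pd.DataFrame(data)
    genotypes = {
        oid: (XY if xy else XX) for oid, xy in zip(data["offspring_id"], is_xy)
    }
    return records, genotypes


def write_sex_registry(
    registry: pd.DataFrame,
    path: str | Path,
    genotypes: dict[str, str] | None = None,
) -> None:
    """Write the sex registry CSV (id, phenotype, optional genotype)."""
    out = registry.copy()
    if genotypes is not None:
        out["genotype"] = out["id"].map(genotypes)
    out.to_csv(path, index=False)


def write_chrom_lengths(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, length in genome.linkage_groups:
            handle.write(f"{name}\t{length}\n")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """Serialise the planted truth to JSON (site keys become 'chrom:pos')."""
    payload = {
        "genotypes": truth.genotypes,
        "phenotypes": truth.phenotypes,
        "sdr": list(truth.sdr) if truth.sdr else None,
        "y_tag_ids": truth.y_tag_ids,
        "y_tag_positions": {
            t: [c, p] for t, (c, p) in truth.y_tag_positions.items()
        },
        "site_classes": {
            f"{c}:{p}": cls for (c, p), cls in truth.site_classes.items()
        },
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True)
        handle.write("\n")
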