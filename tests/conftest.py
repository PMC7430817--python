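import numpy as np
import pandas as pd
import pytest

from sexscan import simdata


@pytest.fixture
def small_genome():
    """Three 3 Mb linkage groups with a 600 kb Y-divergent region on LG1.

    The planted region is kept a small fraction (~7%) of the genome so the
    outlier-window flag rule sees it against a broad background, as on a
    full-size genome.
    """
    return simdata.GenomeModel(
        linkage_groups=(("LG1", 3_000_000), ("LG2", 3_000_000), ("LG3", 3_000_000)),
        sdr=("LG1", 1_200_001, 1_800_000),
        background_snp_rate=2e-4,
        y_divergent_rate=1e-3,
    )


def make_balanced_truth(n_xy=15, n_xx_males=15, n_females=30):
    """Deterministic truth: the first n_xy phenotypic males are XY."""
    genotypes, phenotypes = {}, {}
    for i in range(n_xy + n_xx_males):
        ind = f"M{i + 1:03d}"
        genotypes[ind] = simdata.XY if i < n_xy else simdata.XX
        phenotypes[ind] = "male"
    for i in range(n_females):
        ind = f"F{i + 1:03d}"
        genotypes[ind] = simdata.XX
        phenotypes[ind] = "female"
    return simdata.SimTruth(genotypes=genotypes, phenotypes=phenotypes)


@pytest.fixture
def balanced_truth():
    """30 phenotypic males (15 XY, 15 XX neomales) and 30 females."""
    return make_balanced_truth()


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Independent of scipy: sums the probabilities of every table with the
    observed margins whose probability does not exceed the observed one.
    """
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    denom = comb(n, c1)
    probs = [comb(r1, k) * comb(n - r1, c1 - k) / denom for k in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))


def brute_force_windows(sites, params, chrom_lengths):
    """O(n_points * n_sites) recount of window-level sex-specific SNP counts."""
    rows = []
    for chrom, length in chrom_lengths.items():
        sub = sites[sites["chrom"] == chrom]
        pos = sub["pos"].to_numpy()
        cls = sub["site_class"].to_numpy()
        half = params.window_size // 2
        for pt in range(params.output_resolution, length + 1,
                        params.output_resolution):
            lo, hi = max(pt - half, 1), min(pt + half, length)
            inside = (pos >= lo) & (pos <= hi)
            rows.append(
                (
                    chrom,
                    pt,
                    int((cls[inside] == "male_specific").sum()),
                    int((cls[inside] == "female_specific").sum()),
                )
            )
    return pd.DataFrame(rows, columns=["chrom", "pos", "male_snp", "female_snp"])
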