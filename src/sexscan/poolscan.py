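"""Two-pool (male vs female) genome scan for sex-differentiated regions.

The scan consumes a popoolation-style *sync* stream: one line per reference
position, ``chrom pos ref A:T:C:G:N:del A:T:C:G:N:del`` with the male pool
first. Each site is classified against the heterozygous/homozygous frequency
bands that define a sex-linked locus in an XX/XY system (heterozygous in the
male pool because XY males carry one Y and one X allele, homozygous in the
female pool), classified sites are counted in overlapping windows centred on
regularly spaced output points, and runs of outlier windows are merged into
sex-determining-region (SDR) calls.

Coordinates are 1-based closed intervals throughout; BED output converts to
0-based half-open.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

#: site classes, exhaustive and mutually exclusive
MALE_SPECIFIC = "male_specific"
FEMALE_SPECIFIC = "female_specific"
NONE = "none"
LOW_DEPTH = "low_depth"

_NUC = "ATCG"
_SYNC_COLUMNS = 6  # A, T, C, G, N, del


@dataclass
class SyncRecord:
    """Nucleotide composition of one reference position in the two pools.

    ``male`` and ``female`` are (A, T, C, G, N, del) count sextets.
    """

    chrom: str
    pos: int
    ref: str
    male: tuple[int, int, int, int, int, int]
    female: tuple[int, int, int, int, int, int]


@dataclass(frozen=True)
class PoolScanParams:
    """Numeric criteria of the pooled scan.

    min_depth
        minimum nucleotide depth (A+T+C+G) required in *both* pools.
    freq_het, range_het
        a pool counts as heterozygous for a sex-linked locus when it carries
        exactly two alleles, each at frequency within freq_het +/- range_het.
    freq_hom, range_hom
        the other pool must be homozygous: major allele frequency at least
        freq_hom - range_hom.
    window_size, output_resolution
        sliding-window width in bp and spacing of output points in bp.
    """

    min_depth: int = 10
    freq_het: float = 0.5
    range_het: float = 0.2
    freq_hom: float = 1.0
    range_hom: float = 0.02
    window_size: int = 100_000
    output_resolution: int = 500

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_het - self.range_het
                and self.freq_het + self.range_het < 1.0):
            raise ValueError("heterozygous band must lie strictly inside (0, 1)")
        if not self.freq_hom - self.range_hom > 0.5:
            raise ValueError("homozygous threshold must exceed 0.5")
        if self.window_size < self.output_resolution:
            raise ValueError("window_size must be >= output_resolution")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")

    @property
    def het_band(self) -> tuple[float, float]:
        return (self.freq_het - self.range_het, self.freq_het + self.range_het)

    @property
    def hom_threshold(self) -> float:
        return self.freq_hom - self.range_hom


@dataclass(frozen=True)
class SDRPolicy:
    """Delimitation policy for SDR calls from the window track.

    Windows whose male-specific SNP count exceeds mean + z_threshold * sd
    (moments taken genome-wide over all windows) are flagged; flagged windows
    closer than merge_gap bp are merged, and merged spans of at least
    min_span bp are reported.
    """

    z_threshold: float = 3.0
    merge_gap: int = 500_000
    min_span: int = 1_000_000

    def __post_init__(self) -> None:
        if self.merge_gap < 0 or self.min_span < 1:
            raise ValueError("merge_gap must be >= 0 and min_span >= 1")


@dataclass
class SDRCall:
    """One contiguous candidate sex-determining region (1-based closed)."""

    chrom: str
    start: int
    end: int
    n_windows: int
    mean_density: float
    peak_density: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _parse_sextet(field: str, lineno: int) -> tuple[int, ...]:
    parts = field.split(":")
    if len(parts) != _SYNC_COLUMNS:
        raise ValueError(
            f"sync line {lineno}: expected A:T:C:G:N:del sextet, got {field!r}"
        )
    try:
        counts = tuple(int(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"sync line {lineno}: non-integer count in {field!r}") from exc
    if any(c < 0 for c in counts):
        raise ValueError(f"sync line {lineno}: negative count in {field!r}")
    return counts


def read_sync(source: str | Path | IO[str] | Iterable[str]) -> Iterator[SyncRecord]:
    """Parse a two-pool sync stream into :class:`SyncRecord` objects.

    ``source`` may be a path, an open text handle, or an iterable of lines.
    Positions must be non-decreasing within each chromosome; malformed lines
    raise :class:`ValueError` with the offending line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as handle:
            yield from _read_sync_lines(handle)
    else:
        yield from _read_sync_lines(source)


def _read_sync_lines(lines: Iterable[str]) -> Iterator[SyncRecord]:
    last_pos: dict[str, int] = {}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise ValueError(
                f"sync line {lineno}: expected 5 tab-separated fields "
                f"(chrom, pos, ref, male pool, female pool), got {len(fields)}"
            )
        chrom, pos_s, ref = fields[0], fields[1], fields[2]
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ValueError(f"sync line {lineno}: bad position {pos_s!r}") from exc
        if pos < 1:
            raise ValueError(f"sync line {lineno}: position must be >= 1")
        if pos < last_pos.get(chrom, 0):
            raise ValueError(
                f"sync line {lineno}: position {pos} on {chrom} out of order "
                f"(previous {last_pos[chrom]})"
            )
        last_pos[chrom] = pos
        male = _parse_sextet(fields[3], lineno)
        female = _parse_sextet(fields[4], lineno)
        yield SyncRecord(chrom=chrom, pos=pos, ref=ref, male=male, female=female)


def write_sync(records: Iterable[SyncRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        for rec in records:
            male = ":".join(str(c) for c in rec.male)
            female = ":".join(str(c) for c in rec.female)
            out.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{male}\t{female}\n")


def _in_band_alleles(
    counts: Sequence[int], depth: int, band: tuple[float, float]
) -> list[int] | None:
    """Indices of the exactly-two alleles inside the heterozygous band.

    Returns None unless exactly two alleles fall inside the band and every
    other observed allele stays at or below 1 - band_high (tri-allelic noise
    above that level disqualifies the site).
    """
    lo, hi = band
    in_band: list[int] = []
    max_other = 0.0
    for i in range(4):
        if counts[i] == 0:
            continue
        freq = counts[i] / depth
        if lo <= freq <= hi:
            in_band.append(i)
        else:
            max_other = max(max_other, freq)
    if len(in_band) == 2 and max_other <= 1.0 - hi:
        return in_band
    return None


def classify_site(rec: SyncRecord, params: PoolScanParams) -> str:
    """Classify one position as male_specific / female_specific / none / low_depth.

    Depth is the nucleotide depth A+T+C+G; N and deletion columns are ignored.
    A site is male-specific when the male pool is heterozygous inside the
    band, the female pool's major allele frequency reaches the homozygosity
    threshold, and the male pool carries an in-band allele that differs from
    the female major allele (female-specific is symmetric).
    """
    m = rec.male[:4]
    f = rec.female[:4]
    depth_m = sum(m)
    depth_f = sum(f)
    if depth_m < params.min_depth or depth_f < params.min_depth:
        return LOW_DEPTH

    band = params.het_band
    hom = params.hom_threshold

    major_f = int(np.argmax(f))
    if f[major_f] / depth_f >= hom:
        het_m = _in_band_alleles(m, depth_m, band)
        if het_m is not None and any(i != major_f for i in het_m):
            return MALE_SPECIFIC

    major_m = int(np.argmax(m))
    if m[major_m] / depth_m >= hom:
        het_f = _in_band_alleles(f, depth_f, band)
        if het_f is not None and any(i != major_m for i in het_f):
            return FEMALE_SPECIFIC

    return NONE


def classify_sites(
    records: Iterable[SyncRecord], params: PoolScanParams
) -> pd.DataFrame:
    """Classify a sorted record stream into a site table.

    Returns a DataFrame with columns chrom, pos, site_class, depth_m, depth_f
    (nucleotide depths), preserving input order.
    """
    rows = []
    for rec in records:
        cls = classify_site(rec, params)
        rows.append((rec.chrom, rec.pos, cls, sum(rec.male[:4]), sum(rec.female[:4])))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "site_class", "depth_m", "depth_f"]
    )


def depth_ratio(
    depth_male,
    depth_female,
    lib_male: float,
    lib_female: float,
    pseudocount: float = 1.0,
):
    """log2 ratio of library-size-normalised pool depths.

    Computed as log2(((dm + c) / Dm) / ((df + c) / Df)) with pseudocount
    c (default 1) so empty windows stay finite; equal normalised depths
    give 0. Accepts scalars or arrays.
    """
    if lib_male <= 0 or lib_female <= 0:
        raise ValueError("library sizes must be positive")
    dm = np.asarray(depth_male, dtype=float)
    df = np.asarray(depth_female, dtype=float)
    out = np.log2(((dm + pseudocount) / lib_male) / ((df + pseudocount) / lib_female))
    if np.isscalar(depth_male) and np.isscalar(depth_female):
        return float(out)
    return out


def window_scan(
    sites: pd.DataFrame,
    params: PoolScanParams,
    chrom_lengths: dict[str, int],
) -> pd.DataFrame:
    """Sliding-window counts of sex-specific SNPs along every chromosome.

    One output row is produced every ``output_resolution`` bp on each
    chromosome in ``chrom_lengths``; the window of ``window_size`` bp is
    centred on the output point and clipped at the chromosome ends, and a
    classified site is counted when its position lies inside the closed
    window. Mean per-pool depths are taken over all sync sites in the window
    and the log2 depth ratio is normalised by the genome-wide total depth of
    each pool.

    ``sites`` is the table from :func:`classify_sites`; it must be sorted by
    position within each chromosome, and no site may exceed its declared
    chromosome length.
    """
    if not isinstance(sites, pd.DataFrame):
        sites = pd.DataFrame(
            list(sites), columns=["chrom", "pos", "site_class", "depth_m", "depth_f"]
        )
    for chrom in sites["chrom"].unique():
        if chrom not in chrom_lengths:
            raise ValueError(f"chromosome {chrom!r} missing from chrom_lengths")

    lib_m = float(sites["depth_m"].sum()) if len(sites) else 0.0
    lib_f = float(sites["depth_f"].sum()) if len(sites) else 0.0
    lib_m = lib_m if lib_m > 0 else 1.0
    lib_f = lib_f if lib_f > 0 else 1.0

    half = params.window_size // 2
    res = params.output_resolution
    grouped = {chrom: g for chrom, g in sites.groupby("chrom", sort=False)}
    frames = []
    for chrom, length in chrom_lengths.items():
        g = grouped.get(chrom)
        if g is None:
            pos = np.empty(0, dtype=np.int64)
            cls = np.empty(0, dtype=object)
            dep_m = np.empty(0, dtype=np.int64)
            dep_f = np.empty(0, dtype=np.int64)
        else:
            pos = g["pos"].to_numpy(dtype=np.int64)
            if len(pos) > 1 and np.any(np.diff(pos) < 0):
                raise ValueError(f"sites on {chrom} are not sorted by position")
            if len(pos) and pos[-1] > length:
                raise ValueError(
                    f"site at {chrom}:{pos[-1]} beyond declared length {length}"
                )
            cls = g["site_class"].to_numpy()
            dep_m = g["depth_m"].to_numpy(dtype=np.int64)
            dep_f = g["depth_f"].to_numpy(dtype=np.int64)

        pts = np.arange(res, length + 1, res, dtype=np.int64)
        lo = np.maximum(pts - half, 1)
        hi = np.minimum(pts + half, length)

        pos_m = pos[cls == MALE_SPECIFIC]
        pos_f = pos[cls == FEMALE_SPECIFIC]
        male_snp = np.searchsorted(pos_m, hi, side="right") - np.searchsorted(
            pos_m, lo, side="left"
        )
        female_snp = np.searchsorted(pos_f, hi, side="right") - np.searchsorted(
            pos_f, lo, side="left"
        )

        i_lo = np.searchsorted(pos, lo, side="left")
        i_hi = np.searchsorted(pos, hi, side="right")
        n_sites = i_hi - i_lo
        cum_m = np.concatenate(([0], np.cumsum(dep_m)))
        cum_f = np.concatenate(([0], np.cumsum(dep_f)))
        denom = np.maximum(n_sites, 1)
        mean_m = (cum_m[i_hi] - cum_m[i_lo]) / denom
        mean_f = (cum_f[i_hi] - cum_f[i_lo]) / denom

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pts,
                    "male_snp": male_snp,
                    "female_snp": female_snp,
                    "n_sites": n_sites,
                    "depth_m": mean_m,
                    "depth_f": mean_f,
                    "log2_ratio": depth_ratio(mean_m, mean_f, lib_m, lib_f),
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "chrom", "pos", "male_snp", "female_snp",
                "n_sites", "depth_m", "depth_f", "log2_ratio",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def call_sdr(
    windows: pd.DataFrame,
    policy: SDRPolicy | None = None,
    params: PoolScanParams | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> list[SDRCall]:
    """Delimit candidate SDRs from the male-specific SNP window track.

    Windows with male_snp above mean + z_threshold * sd (moments over all
    windows genome-wide) are flagged; flagged windows whose spans (output
    point +/- half window) lie within merge_gap of each other on the same
    chromosome are merged, and merged spans of at least min_span bp are
    reported with their window count, mean and peak male-specific density.
    An all-zero genome yields an empty list. Deterministic.
    """
    if policy is None:
        policy = SDRPolicy()
    if params is None:
        params = PoolScanParams()
    if len(windows) == 0:
        raise ValueError("window table is empty")

    counts = windows["male_snp"].to_numpy(dtype=float)
    mu = counts.mean()
    sd = counts.std(ddof=0)
    if mu == 0.0 and sd == 0.0:
        return []
    threshold = mu + policy.z_threshold * sd

    half = params.window_size // 2
    calls: list[SDRCall] = []
    for chrom, g in windows.groupby("chrom", sort=False):
        flagged = g[g["male_snp"].to_numpy(dtype=float) > threshold]
        if len(flagged) == 0:
            continue
        length = None if chrom_lengths is None else chrom_lengths.get(chrom)
        pts = flagged["pos"].to_numpy(dtype=np.int64)
        lo = np.maximum(pts - half, 1)
        hi = pts + half
        if length is not None:
            hi = np.minimum(hi, length)
        # merge flagged window spans separated by <= merge_gap
        spans: list[list[int]] = [[int(lo[0]), int(hi[0]), 1]]
        for s, e in zip(lo[1:], hi[1:]):
            if s - spans[-1][1] <= policy.merge_gap:
                spans[-1][1] = max(spans[-1][1], int(e))
                spans[-1][2] += 1
            else:
                spans.append([int(s), int(e), 1])
        g_pos = g["pos"].to_numpy(dtype=np.int64)
        g_cnt = g["male_snp"].to_numpy(dtype=float)
        for start, end, n_flagged in spans:
            if end - start + 1 < policy.min_span:
                continue
            inside = (g_pos >= start) & (g_pos <= end)
            calls.append(
                SDRCall(
                    chrom=str(chrom),
                    start=start,
                    end=end,
                    n_windows=n_flagged,
                    mean_density=float(g_cnt[inside].mean()) if inside.any() else 0.0,
                    peak_density=float(g_cnt[inside].max()) if inside.any() else 0.0,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def reciprocal_overlap(
    a_start: int, a_end: int, b_start: int, b_end: int
) -> float:
    """Reciprocal overlap fraction of two 1-based closed intervals."""
    ov = min(a_end, b_end) - max(a_start, b_start) + 1
    if ov <= 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))


def write_window_table(windows: pd.DataFrame, path: str | Path) -> None:
    windows.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_sdr_bed(calls: Sequence[SDRCall], path: str | Path) -> None:
    """Write SDR calls as BED (0-based half-open)."""
    with open(path, "w") as out:
        for i, call in enumerate(calls, start=1):
            out.write(f"{call.chrom}\t{call.start - 1}\t{call.end}\tSDR{i}\n")


def write_sdr_json(calls: Sequence[SDRCall], path: str | Path) -> None:
    with open(path, "w") as out:
        json.dump([asdict(c) for c in calls], out, indent=2, sort_keys=True)
        out.write("\n")


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column (name, length) TSV of chromosome sizes."""
    lengths: dict[str, int] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2]
            lengths[name] = int(length)
    return lengths
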