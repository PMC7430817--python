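"""End-to-end workflow: simulate -> RAD markers -> purify pool -> scan -> crosses.

The ordering mirrors how the two sequencing strategies complement each other
in a system with environmental sex reversal: individual-tracked RAD markers
identify which phenotypic males actually carry the Y, the male pool passed to
the pooled scan is restricted to those verified Y-carriers (otherwise XX
neomales dilute the male-pool allele frequency of Y alleles below the
heterozygous detection band), and crosses from an XX versus an XY sire
provide the sex-ratio and sex-linkage statistics.

Every stage draws from its own child stream of the single run seed, and the
manifest records parameters and SHA-256 checksums of every output so a rerun
can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import crossstats, poolscan, radtags, simdata

logger = logging.getLogger("sexscan")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 42
    genome: simdata.GenomeModel = field(default_factory=simdata.default_genome)
    population: simdata.PopulationParams = field(
        default_factory=simdata.PopulationParams
    )
    radsex: radtags.RadSexParams = field(default_factory=radtags.RadSexParams)
    scan: poolscan.PoolScanParams = field(default_factory=poolscan.PoolScanParams)
    sdr_policy: poolscan.SDRPolicy = field(default_factory=poolscan.SDRPolicy)
    purify_male_pool: bool = True
    min_carry_fraction: float = 0.5
    n_autosomal_tags: int = 500
    n_y_tags: int = 32
    cross_offspring: int = 120
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)


def config_from_dict(data: dict, out_dir: str | Path | None = None) -> PipelineConfig:
    """Build a config from a (YAML-shaped) dictionary of overrides."""
    data = dict(data)
    genome_data = data.pop("genome", None)
    if genome_data is not None:
        genome = simdata.GenomeModel(
            linkage_groups=tuple(
                (str(n), int(l)) for n, l in genome_data["linkage_groups"]
            ),
            sdr=tuple(genome_data["sdr"]),
            background_snp_rate=float(
                genome_data.get("background_snp_rate", 1e-4)
            ),
            y_divergent_rate=float(genome_data.get("y_divergent_rate", 5e-4)),
        )
    else:
        genome = simdata.default_genome()
    population = simdata.PopulationParams(**data.pop("population", {}))
    radsex = radtags.RadSexParams(**data.pop("radsex", {}))
    scan = poolscan.PoolScanParams(**data.pop("scan", {}))
    sdr_policy = poolscan.SDRPolicy(**data.pop("sdr_policy", {}))
    if out_dir is not None:
        data["out_dir"] = out_dir
    return PipelineConfig(
        genome=genome,
        population=population,
        radsex=radsex,
        scan=scan,
        sdr_policy=sdr_policy,
        **data,
    )


def load_config(
    path: str | Path | None,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> PipelineConfig:
    data = {}
    if path is not None:
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
    if seed is not None:
        data["seed"] = int(seed)
    if out_dir is None and "out_dir" not in data:
        raise ValueError("an output directory is required (config or --out-dir)")
    return config_from_dict(data, out_dir=out_dir)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _params_payload(config: PipelineConfig) -> dict:
    payload = dataclasses.asdict(config)
    payload["out_dir"] = str(config.out_dir)
    return payload


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages and return (and write) the run manifest.

    Stages: simulate, radtags, pool_selection, poolscan, cross. Any failure
    aborts with a :class:`PipelineError` naming the stage; outputs written
    before the failure are flagged as partial in the exception message.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    population = dataclasses.replace(config.population, seed=config.seed)
    stages: list[dict] = []
    written: list[Path] = []
    state: dict = {}

    def stage(name):
        def decorator(fn):
            return (name, fn)
        return decorator

    def _run(name: str, fn) -> None:
        logger.info("stage %s: starting", name)
        before = list(written)
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            partial = [str(p) for p in written if p not in before]
            raise PipelineError(
                f"stage '{name}' failed: {exc}"
                + (f" (partial outputs: {partial})" if partial else "")
            ) from exc
        written.extend(outputs)
        stages.append({"name": name, "outputs": [str(p.name) for p in outputs]})

    @stage("simulate")
    def _simulate():
        registry, truth = simdata.simulate_individuals(population)
        tags = simdata.simulate_tag_matrix(
            truth,
            config.genome,
            population,
            n_autosomal_tags=config.n_autosomal_tags,
            n_y_tags=config.n_y_tags,
        )
        state.update(registry=registry, truth=truth, tags=tags)
        registry_path = out / "sex_registry.csv"
        simdata.write_sex_registry(registry, registry_path)
        matrix_path = out / "tag_matrix.tsv"
        tags.to_tsv(matrix_path)
        lengths_path = out / "chrom_lengths.tsv"
        simdata.write_chrom_lengths(config.genome, lengths_path)
        return [registry_path, matrix_path, lengths_path]

    @stage("radtags")
    def _radtags():
        tags = state["tags"]
        presence = radtags.build_presence(tags, config.radsex.min_depth)
        state["presence"] = presence
        distribution = radtags.tag_distribution(presence, tags.sexes)
        dist_path = out / "tag_distribution.tsv"
        distribution.write(dist_path)
        signif = radtags.significant_tags(presence, tags.sexes, config.radsex)
        signif_path = out / "significant_tags.tsv"
        signif.to_csv(signif_path, sep="\t")
        markers = radtags.male_specific_tags(presence, tags.sexes, config.radsex)
        state["markers"] = markers
        markers_path = out / "male_markers.txt"
        markers_path.write_text("".join(f"{t}\n" for t in markers))
        fasta_path = out / "male_markers.fasta"
        radtags.write_marker_fasta(tags, markers, fasta_path)
        calls, summary = radtags.classify_individuals(
            presence, tags.sexes, markers, config.min_carry_fraction
        )
        state["calls"] = calls
        state["neomale_summary"] = summary
        calls_path = out / "individual_calls.csv"
        calls.to_csv(calls_path)
        logger.info(
            "radtags: %d markers, %d/%d phenotypic males are Y-carriers",
            len(markers), summary.n_y_carriers, summary.n_pheno_males,
        )
        return [dist_path, signif_path, markers_path, fasta_path, calls_path]

    @stage("pool_selection")
    def _pools():
        tags = state["tags"]
        calls = state["calls"]
        males = [i for i in tags.individuals if tags.sexes[i] == "male"]
        females = [i for i in tags.individuals if tags.sexes[i] == "female"]
        if config.purify_male_pool:
            male_pool = [i for i in males if calls.loc[i, "call"] == "Y-carrier"]
        else:
            male_pool = males
        if not male_pool:
            raise ValueError("male pool is empty after purification")
        state["male_pool"] = male_pool
        state["female_pool"] = females
        pools_path = out / "pools.json"
        pools_path.write_text(
            json.dumps(
                {
                    "purified": config.purify_male_pool,
                    "male_pool": male_pool,
                    "female_pool": females,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        return [pools_path]

    @stage("poolscan")
    def _poolscan():
        truth = state["truth"]
        records = simdata.simulate_sync(
            truth,
            config.genome,
            population,
            male_pool=state["male_pool"],
            female_pool=state["female_pool"],
        )
        sync_path = out / "pools.sync"
        poolscan.write_sync(records, sync_path)
        sites = poolscan.classify_sites(records, config.scan)
        windows = poolscan.window_scan(
            sites, config.scan, config.genome.chrom_lengths
        )
        windows_path = out / "windows.tsv"
        poolscan.write_window_table(windows, windows_path)
        calls = poolscan.call_sdr(
            windows,
            policy=config.sdr_policy,
            params=config.scan,
            chrom_lengths=config.genome.chrom_lengths,
        )
        state["sdr_calls"] = calls
        bed_path = out / "sdr_calls.bed"
        poolscan.write_sdr_bed(calls, bed_path)
        json_path = out / "sdr_calls.json"
        poolscan.write_sdr_json(calls, json_path)
        truth_path = out / "truth.json"
        simdata.write_truth(truth, truth_path)
        logger.info("poolscan: %d SDR call(s)", len(calls))
        return [sync_path, windows_path, bed_path, json_path, truth_path]

    @stage("cross")
    def _cross():
        outputs = []
        report: dict = {}
        for sire in (simdata.XX, simdata.XY):
            records, _genotypes = simdata.simulate_cross(
                sire, population, n_offspring=config.cross_offspring
            )
            path = out / f"cross_p{sire.lower()}.csv"
            records.to_csv(path, index=False)
            outputs.append(path)
            summary = crossstats.summarize_cross(records)
            entry = {
                "n_males": summary.n_males,
                "n_females": summary.n_females,
                "n_undifferentiated": summary.n_undifferentiated,
                "ratio_female_male": summary.ratio_female_male,
                "percent_males": summary.percent_males,
                "linkage": {},
            }
            if summary.n_males + summary.n_females > 0:
                ratio = crossstats.sex_ratio_test(
                    summary.n_males, summary.n_females
                )
                entry["sex_ratio_chi2"] = ratio.chi2
                entry["sex_ratio_p"] = ratio.p
            for marker in crossstats.marker_columns(records):
                result = crossstats.sex_linkage_test(records, marker)
                entry["linkage"][marker] = {
                    "p": result.p,
                    "call": result.label,
                }
            if sire == simdata.XX:
                est = crossstats.estimate_sex_reversal(records)
                entry["sex_reversal"] = {
                    "rate": est.rate,
                    "percent": est.percent,
                    "ci": [est.ci_low, est.ci_high],
                }
            report[f"P({sire})"] = entry
        report_path = out / "cross_report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        outputs.append(report_path)
        return outputs

    for name, fn in (_simulate, _radtags, _pools, _poolscan, _cross):
        _run(name, fn)

    for entry in stages:
        entry["outputs"] = [
            {"path": name, "sha256": _sha256(out / name)}
            for name in entry["outputs"]
        ]
    manifest = {
        "package": "sexscan",
        "version": __version__,
        "seed": config.seed,
        "parameters": _params_payload(config),
        "stages": stages,
        "sdr_calls": [dataclasses.asdict(c) for c in state.get("sdr_calls", [])],
        "neomale_fraction": state["neomale_summary"].neomale_fraction,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def simulate_dataset(config: PipelineConfig) -> dict:
    """Generate the raw synthetic inputs only (no analysis stages).

    Writes the sex registry, tag matrix, chromosome lengths, a sync file for
    the unpurified pools (all phenotypic males vs all females), two cross
    tables, and the truth JSON. Returns the paths written.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    population = dataclasses.replace(config.population, seed=config.seed)
    registry, truth = simdata.simulate_individuals(population)
    tags = simdata.simulate_tag_matrix(
        truth,
        config.genome,
        population,
        n_autosomal_tags=config.n_autosomal_tags,
        n_y_tags=config.n_y_tags,
    )
    records = simdata.simulate_sync(truth, config.genome, population)
    paths = {
        "registry": out / "sex_registry.csv",
        "tag_matrix": out / "tag_matrix.tsv",
        "chrom_lengths": out / "chrom_lengths.tsv",
        "sync": out / "pools.sync",
        "cross_pxx": out / "cross_pxx.csv",
        "cross_pxy": out / "cross_pxy.csv",
        "truth": out / "truth.json",
    }
    simdata.write_sex_registry(registry, paths["registry"])
    tags.to_tsv(paths["tag_matrix"])
    simdata.write_chrom_lengths(config.genome, paths["chrom_lengths"])
    poolscan.write_sync(records, paths["sync"])
    for sire, key in ((simdata.XX, "cross_pxx"), (simdata.XY, "cross_pxy")):
        cross, _ = simdata.simulate_cross(
            sire, population, n_offspring=config.cross_offspring
        )
        cross.to_csv(paths[key], index=False)
    simdata.write_truth(truth, paths["truth"])
    return {k: str(v) for k, v in paths.items()}
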