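"""Configuration-driven orchestration of the full analysis.

``run_all`` executes simulate/load -> filter -> window scan -> joint SFS ->
demographic fits -> unit conversion -> (optional) bootstrap -> taxonomy
verdict, persisting every intermediate with a content-hash manifest and a
per-stage log, so a run is fully reproducible from its config and seeds.

The taxonomy rule engine encodes a decision tree over reproductive
isolation, genomic differentiation and diagnostic morphology: complete
reproductive isolation means species; otherwise diagnosable taxa are species
when their diagnostic features are backed by genomic differentiation (high
genome-wide differentiation, or features linked to differentiation islands),
and subspecies otherwise.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import landscape, variant_filtering
from .demography import bootstrap_ci, compare_models, convert_units, fit_model
from .models import ConversionConstants, DemographicModel, SampleConfig, Scenario
from .sfs import joint_sfs
from .simgen import simulate_dataset

__all__ = ["RunConfig", "TaxonomyEvidence", "taxonomy_decision", "run_all"]

log = logging.getLogger(__name__)

_KNOWN_SECTIONS = {
    "seed",
    "outdir",
    "input",
    "simulate",
    "filters",
    "window",
    "sfs",
    "fit",
    "convert",
    "bootstrap",
    "taxonomy",
}
_KNOWN_KEYS = {
    "input": {"vcf", "popmap", "placement"},
    "simulate": {
        "scenario", "nu1", "nu2", "t_iso", "t_sc", "m12", "m21",
        "nu1_0", "nu2_0", "n1", "n2", "n_loci", "theta_per_locus", "locus_length",
    },
    "filters": {"hwe_p", "maf", "ld_window", "ld_step", "ld_r2"},
    "window": {"size", "min_sites"},
    "sfs": {"project_to"},
    "fit": {"scenarios", "n_starts", "n_reps", "n_reps_polish", "maxfev",
            "n_grid", "n_pass"},
    "convert": {"mu", "gen_time", "L_eff"},
    "bootstrap": {"n_boot", "n_snps", "n_reps"},
    "taxonomy": {
        "reproductive_isolation",
        "genomic_differentiation",
        "diagnostic_features",
        "features_linked_to_islands",
    },
}


@dataclass
class RunConfig:
    """Validated run configuration (see the YAML schema in the docs)."""

    raw: dict

    def __post_init__(self) -> None:
        unknown = set(self.raw) - _KNOWN_SECTIONS
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        for section, keys in _KNOWN_KEYS.items():
            extra = set(self.raw.get(section, {}) or {}) - keys
            if extra:
                raise ValueError(f"unknown keys in [{section}]: {sorted(extra)}")
        if "input" not in self.raw and "simulate" not in self.raw:
            raise ValueError("config needs an 'input' or a 'simulate' section")
        if "input" in self.raw:
            for key in ("vcf", "popmap"):
                p = self.raw["input"].get(key)
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"input.{key} missing or not found: {p}")
        th = self.raw.get("filters", {}) or {}
        if not 0 <= th.get("maf", 0.05) <= 0.5:
            raise ValueError("filters.maf must lie in [0, 0.5]")
        if not 0 < th.get("hwe_p", 0.01) <= 1:
            raise ValueError("filters.hwe_p must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def get(self, section: str, key: str, default=None):
        return (self.raw.get(section, {}) or {}).get(key, default)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def outdir(self) -> Path:
        return Path(self.raw.get("outdir", "divflow_out"))


@dataclass(frozen=True)
class TaxonomyEvidence:
    """Evidence record feeding the species/subspecies decision tree."""

    reproductive_isolation: str  # "complete" | "incomplete"
    genomic_differentiation: str  # "high" | "low"
    diagnostic_features: str  # "several" | "none"
    features_linked_to_islands: bool = False

    def __post_init__(self) -> None:
        if self.reproductive_isolation not in ("complete", "incomplete"):
            raise ValueError("reproductive_isolation must be complete|incomplete")
        if self.genomic_differentiation not in ("high", "low"):
            raise ValueError("genomic_differentiation must be high|low")
        if self.diagnostic_features not in ("several", "none"):
            raise ValueError("diagnostic_features must be several|none")


def taxonomy_decision(evidence: TaxonomyEvidence) -> str:
    """Apply the classification decision tree; returns 'species' or 'subspecies'."""
    if evidence.reproductive_isolation == "complete":
        return "species"
    if evidence.diagnostic_features == "none":
        return "subspecies"
    # several diagnostic features, incomplete isolation
    if evidence.genomic_differentiation == "high":
        return "species"
    return "species" if evidence.features_linked_to_islands else "subspecies"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_logger(outdir: Path, stage: str):
    logdir = outdir / "logs"
    logdir.mkdir(parents=True, exist_ok=True)
    fh = open(logdir / f"{stage}.log", "a")

    def emit(msg: str) -> None:
        line = f"{time.strftime('%Y-%m-%dT%H:%M:%S')} [{stage}] {msg}"
        fh.write(line + "\n")
        fh.flush()
        log.info(line)

    return emit, fh


def run_all(config: RunConfig) -> dict:
    """Execute every stage in order and return the output manifest."""
    outdir = config.outdir
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "stages": []}
    artifacts: list[Path] = []

    def record(path: Path) -> None:
        artifacts.append(path)

    # -- stage: obtain genotypes ---------------------------------------
    emit, fh = _stage_logger(outdir, "data")
    if "simulate" in config.raw:
        sim = config.raw["simulate"]
        model = DemographicModel(
            scenario=sim.get("scenario", "SC_ASYM"),
            nu1=float(sim["nu1"]),
            nu2=float(sim["nu2"]),
            t_iso=float(sim["t_iso"]),
            t_sc=float(sim.get("t_sc", 0.0)),
            m12=float(sim.get("m12", 0.0)),
            m21=float(sim.get("m21", 0.0)),
            nu1_0=sim.get("nu1_0"),
            nu2_0=sim.get("nu2_0"),
        )
        samples = SampleConfig(int(sim.get("n1", 18)), int(sim.get("n2", 18)))
        vcf_path = outdir / "simulated.vcf"
        gm, truth = simulate_dataset(
            model,
            samples,
            n_loci=int(sim.get("n_loci", 1000)),
            theta_per_locus=float(sim.get("theta_per_locus", 2.0)),
            seed=config.seed,
            locus_length=int(sim.get("locus_length", 10_000)),
            out_vcf=vcf_path,
        )
        record(vcf_path)
        record(Path(str(vcf_path) + ".truth.txt"))
        emit(f"simulated {gm.n_sites} SNPs over {truth.n_loci} loci (seed {config.seed})")
    else:
        popmap = variant_filtering.read_population_map(config.raw["input"]["popmap"])
        gm = variant_filtering.read_vcf(config.raw["input"]["vcf"], popmap)
        emit(f"loaded {gm.n_sites} SNPs for {gm.n_samples} samples")
    fh.close()
    manifest["stages"].append("data")

    # -- stage: filtering ----------------------------------------------
    emit, fh = _stage_logger(outdir, "filter")
    th = config.raw.get("filters", {}) or {}
    filtered, report = variant_filtering.apply_filters(
        gm,
        hwe_p=float(th.get("hwe_p", 0.01)),
        maf=float(th.get("maf", 0.05)),
        ld_window=int(th.get("ld_window", 50)),
        ld_step=int(th.get("ld_step", 5)),
        ld_r2=float(th.get("ld_r2", 0.5)),
    )
    from .simgen import write_vcf

    fvcf = outdir / "filtered.vcf"
    write_vcf(filtered, fvcf)
    rpath = outdir / "filter_report.tsv"
    report.to_tsv(rpath)
    record(fvcf)
    record(rpath)
    emit(f"{report.n_input} -> {report.n_output} SNPs (HWE {report.removed_hwe}, "
         f"MAF {report.removed_maf}, LD {report.removed_ld})")
    fh.close()
    manifest["stages"].append("filter")

    # -- stage: window scan (on the unfiltered SNP set) ----------------
    emit, fh = _stage_logger(outdir, "scan")
    wsize = int(config.get("window", "size", 200_000))
    min_sites = int(config.get("window", "min_sites", 10))
    seq_lengths: dict[str, int] = {}
    for c, p in zip(gm.chrom.astype(str), gm.pos):
        seq_lengths[c] = max(seq_lengths.get(c, 0), int(p))
    windows = landscape.window_partition(seq_lengths, size=wsize)
    stats = landscape.window_scan(gm, windows, min_sites=min_sites)
    placement_path = config.get("input", "placement")
    if placement_path:
        stats = landscape.lift_windows(
            stats, landscape.PlacementTable.from_tsv(placement_path)
        )
    wpath = outdir / "windows.tsv"
    stats.to_csv(wpath, sep="\t", index=False)
    n_peaks, peaks = landscape.peak_census(stats)
    ppath = outdir / "peaks.bed"
    peaks[["chrom", "start", "end", "fst"]].to_csv(
        ppath, sep="\t", index=False, header=False
    )
    record(wpath)
    record(ppath)
    emit(f"{len(stats)} windows, {n_peaks} FST peaks > 0.25")
    fh.close()
    manifest["stages"].append("scan")

    # -- stage: joint SFS ----------------------------------------------
    emit, fh = _stage_logger(outdir, "sfs")
    project_to = config.get("sfs", "project_to")
    spec = joint_sfs(gm, project_to=tuple(project_to) if project_to else None)
    folded = spec.fold()
    fs_path = outdir / "spectrum.fs"
    folded.to_file(fs_path, comment="folded joint SFS")
    record(fs_path)
    emit(f"folded spectrum {folded.data.shape}, {folded.total():.0f} SNPs")
    fh.close()
    manifest["stages"].append("sfs")

    # -- stage: demographic fits ---------------------------------------
    emit, fh = _stage_logger(outdir, "fit")
    fit_cfg = config.raw.get("fit", {}) or {}
    scenarios = fit_cfg.get("scenarios", ["SI", "IM_SYM", "SC_ASYM"])
    fits = []
    rng = np.random.default_rng(config.seed + 1)
    for sc in scenarios:
        n_reps = int(fit_cfg.get("n_reps", 4000))
        fit = fit_model(
            folded,
            sc,
            n_starts=int(fit_cfg.get("n_starts", 10)),
            seed=int(rng.integers(2**31 - 1)),
            n_reps=n_reps,
            n_reps_polish=int(fit_cfg.get("n_reps_polish", 8 * n_reps)),
            maxfev=int(fit_cfg.get("maxfev", 250)),
            n_grid=int(fit_cfg.get("n_grid", 9)),
            n_pass=int(fit_cfg.get("n_pass", 6)),
        )
        fits.append(fit)
        emit(f"{sc}: loglik {fit.loglik:.1f} theta {fit.theta_hat:.3g}")
    ranked = compare_models(fits)
    fit_path = outdir / "fits.jsonl"
    with open(fit_path, "w") as out:
        for f in ranked:
            out.write(
                json.dumps(
                    {
                        "scenario": f.scenario.value,
                        "loglik": f.loglik,
                        "theta_hat": f.theta_hat,
                        "params": f.params_dict(),
                        "starts": f.starts,
                    }
                )
                + "\n"
            )
    record(fit_path)
    fh.close()
    manifest["stages"].append("fit")

    # -- stage: unit conversion ----------------------------------------
    emit, fh = _stage_logger(outdir, "convert")
    conv_cfg = config.raw.get("convert", {}) or {}
    best = ranked[0]
    consts = ConversionConstants(
        mu=float(conv_cfg.get("mu", 1e-9)),
        gen_time=float(conv_cfg.get("gen_time", 2.0)),
        L_eff=float(conv_cfg.get("L_eff", 1.0)),
    )
    converted = convert_units(best, consts)
    cpath = outdir / "converted_params.json"
    cpath.write_text(json.dumps(converted.as_dict(), indent=2) + "\n")
    record(cpath)
    emit(f"best model {best.scenario.value}: {converted.as_dict()}")
    fh.close()
    manifest["stages"].append("convert")

    # -- stage: bootstrap (optional) -----------------------------------
    boot_cfg = config.raw.get("bootstrap")
    if boot_cfg:
        emit, fh = _stage_logger(outdir, "bootstrap")
        result = bootstrap_ci(
            folded,
            best.scenario,
            best,
            n_boot=int(boot_cfg.get("n_boot", 10)),
            n_snps=boot_cfg.get("n_snps"),
            seed=config.seed + 2,
            n_reps=int(boot_cfg.get("n_reps", fit_cfg.get("n_reps", 20_000))),
        )
        bpath = outdir / "bootstrap.json"
        bpath.write_text(json.dumps(result["intervals"], indent=2) + "\n")
        record(bpath)
        emit(f"bootstrap CIs over {len(result['draws'])} refits")
        fh.close()
        manifest["stages"].append("bootstrap")

    # -- stage: taxonomy ------------------------------------------------
    tax_cfg = config.raw.get("taxonomy")
    if tax_cfg:
        emit, fh = _stage_logger(outdir, "taxonomy")
        evidence = TaxonomyEvidence(
            reproductive_isolation=tax_cfg["reproductive_isolation"],
            genomic_differentiation=tax_cfg["genomic_differentiation"],
            diagnostic_features=tax_cfg["diagnostic_features"],
            features_linked_to_islands=bool(
                tax_cfg.get("features_linked_to_islands", False)
            ),
        )
        verdict = taxonomy_decision(evidence)
        tpath = outdir / "taxonomy.txt"
        tpath.write_text(verdict + "\n")
        record(tpath)
        emit(f"verdict: {verdict}")
        fh.close()
        manifest["stages"].append("taxonomy")

    for p in artifacts:
        manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
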