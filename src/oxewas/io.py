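"""Readers/writers, run configuration and the end-to-end pipeline driver.

File conventions: matrices are TSV with probes (or SNPs) as rows and sample
ids as the header row; BED island intervals are 0-based half-open on disk
and converted to 1-based inclusive on ingestion; genotypes come from a VCF
v4.2 (DS FORMAT preferred, GP fallback) or a plain dosage TSV.

``run_pipeline`` executes the stages in dependency order — EWAS over the
marker panel, probe annotation and context enrichment, cis-meQTL scan with
permutation FDR, SNP-phenotype/triad/GWAS-overlap integration, and the
incident-disease screen — writing result TSVs and a JSON run manifest.
Identical config and seed give byte-identical result tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from oxewas._version import __version__ as _version
from oxewas.annotate import annotate_probes, context_enrichment
from oxewas.disease import attach_context, incident_screen
from oxewas.ewas import MARKER_PANEL, PhenotypeSpec, bmi_sensitivity, ewas_scan
from oxewas.integrate import gwas_overlap_enrichment, snp_phenotype_assoc, triad_screen
from oxewas.meqtl import cis_pairs, cis_scan, permutation_fdr, snp_filter
from oxewas.simulate import Cohort, SimConfig, SyntheticTruth, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_intensities_tsv",
    "read_intensities_tsv",
    "read_beta_tsv",
    "read_islands_bed",
    "read_transcripts_tsv",
    "read_vcf_dosages",
    "read_dosage_tsv",
    "read_inputs",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Pipeline configuration; defaults carry the analysis conventions.

    FDR 0.05 per trait, permutation gate 0.01 for disease, 100 kb cis
    window, 10 meQTL permutation replicates, 10,000 label permutations,
    10 bp probe-SNP exclusion window, 98.5% detection pass rate, 2 kb
    shore / 4 kb shelf, MAF >= 5% and INFO > 0.8 SNP filters.
    """

    input_dir: str | None = None  # fixture directory; None -> simulate
    out_dir: str = "results"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    stages: tuple[str, ...] = ("ewas", "annotate", "meqtl", "integrate", "disease")
    fdr_alpha: float = 0.05
    perm_gate: float = 0.01
    window_bp: int = 100_000
    meqtl_perms: int = 10
    perm_B: int = 10_000
    snp_window_bp: int = 10
    pass_rate_min: float = 0.985
    shore_bp: int = 2000
    shelf_bp: int = 4000
    maf_min: float = 0.05
    info_min: float = 0.8
    gwas_p_cut: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        stages = tuple(raw.pop("stages", cls.stages))
        return cls(sim=sim, stages=stages, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["marker_means_sds"] = {
            k: list(v) for k, v in d["sim"]["marker_means_sds"].items()
        }
        return d


def write_intensities_tsv(intensities, directory: str | Path) -> dict[str, Path]:
    """Write methylated/unmethylated/detection-p matrices and design types as TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("methylated", intensities.methylated),
        ("unmethylated", intensities.unmethylated),
        ("detection_p", intensities.detection_p),
    ):
        paths[name] = directory / f"{name}.tsv"
        frame.T.rename_axis("probe").to_csv(paths[name], sep="\t")
    paths["design_type"] = directory / "design_type.tsv"
    intensities.design_type.rename("design_type").rename_axis("probe").to_csv(
        paths["design_type"], sep="\t"
    )
    return paths


def read_intensities_tsv(directory: str | Path):
    """Read an intensity-matrix directory written by :func:`write_intensities_tsv`."""
    from oxewas.qc import IntensityData

    directory = Path(directory)
    frames = {
        name: pd.read_csv(directory / f"{name}.tsv", sep="\t", index_col=0).T.rename_axis(None, axis=1)
        for name in ("methylated", "unmethylated", "detection_p")
    }
    design = pd.read_csv(directory / "design_type.tsv", sep="\t", index_col=0)["design_type"]
    return IntensityData(
        frames["methylated"], frames["unmethylated"], frames["detection_p"], design
    )


def read_beta_tsv(path: str | Path) -> pd.DataFrame:
    """Beta matrix from TSV (probes as rows, sample header) as samples x probes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    out = df.T
    if out.index.duplicated().any() or out.columns.duplicated().any():
        raise ValueError("duplicate sample or probe ids in beta matrix")
    return out


def read_islands_bed(path: str | Path) -> pd.DataFrame:
    """CpG island intervals; BED 0-based half-open -> 1-based inclusive."""
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"])
    return pd.DataFrame(
        {"chrom": bed["chrom"], "start": bed["start"] + 1, "end": bed["end"]}
    )


def read_transcripts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_vcf_dosages(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dosages and SNP metadata from a VCF (DS preferred, GP fallback).

    Returns (samples x snps dosage frame, snp metadata frame with
    chromosome/position/maf/info).
    """
    from cyvcf2 import VCF

    from oxewas.meqtl import dosage_from_probabilities

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gp = np.asarray(variant.format("GP"), dtype=float)
            dosage = dosage_from_probabilities(gp)
        ids.append(vid)
        rows.append(dosage)
        meta.append(
            (
                variant.CHROM,
                variant.POS,
                float(variant.INFO.get("MAF", np.nan)),
                float(variant.INFO.get("INFO", np.nan)),
            )
        )
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate SNP ids in VCF")
    dosages = pd.DataFrame(np.column_stack(rows), index=samples, columns=ids)
    snp_meta = pd.DataFrame(
        meta, columns=["chromosome", "position", "maf", "info"], index=pd.Index(ids, name="snp")
    )
    return dosages, snp_meta


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    """Plain dosage TSV (SNPs as rows, sample header) as samples x snps."""
    return pd.read_csv(path, sep="\t", index_col=0).T


def read_inputs(config: RunConfig) -> tuple[Cohort, SyntheticTruth | None]:
    """Load a written fixture directory back into a cohort bundle.

    Sample ids are intersected across the beta matrix, covariates and
    genotypes (dropped ids are logged); duplicate ids raise.
    """
    d = Path(config.input_dir)
    betas = read_beta_tsv(d / "betas.tsv")
    covariates = pd.read_csv(d / "covariates.tsv", sep="\t", index_col=0)
    phenotypes = pd.read_csv(d / "phenotypes.tsv", sep="\t", index_col=0)
    outcomes = pd.read_csv(d / "outcomes.tsv", sep="\t", index_col=0)
    manifest = pd.read_csv(d / "manifest.tsv", sep="\t", index_col=0)
    transcripts = read_transcripts_tsv(d / "transcripts.tsv")
    islands = read_islands_bed(d / "islands.bed")
    gwas = pd.read_csv(d / "gwas.tsv", sep="\t")
    vcf_path = d / "genotypes.vcf"
    if vcf_path.exists():
        dosages, snp_meta = read_vcf_dosages(vcf_path)
    else:
        dosages = read_dosage_tsv(d / "dosages.tsv")
        snp_meta = pd.read_csv(d / "snp_meta.tsv", sep="\t", index_col=0)

    for name, frame in (("samples", betas), ("covariates", covariates)):
        if frame.index.duplicated().any():
            raise ValueError(f"duplicate ids in {name}")
    shared = betas.index.intersection(covariates.index).intersection(dosages.index)
    if len(shared) == 0:
        raise ValueError("empty sample intersection across inputs")
    dropped = len(betas.index) - len(shared)
    if dropped:
        logger.info("dropped %d samples outside the common intersection", dropped)
    cohort = Cohort(
        betas=betas.loc[shared],
        dosages=dosages.loc[shared],
        snp_meta=snp_meta,
        manifest=manifest,
        islands=islands,
        transcripts=transcripts,
        phenotypes=phenotypes.loc[shared],
        covariates=covariates.loc[shared],
        outcomes=outcomes.loc[shared],
        gwas=gwas,
        config=config.sim,
    )
    truth = None
    truth_path = d / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            raw = json.load(fh)
        truth = SyntheticTruth(
            true_cpg_phenotype_pairs=[tuple(t) for t in raw["true_cpg_phenotype_pairs"]],
            true_meqtl_pairs=[tuple(t) for t in raw["true_meqtl_pairs"]],
            true_disease_cpgs=[tuple(t) for t in raw["true_disease_cpgs"]],
            planted_triads=[tuple(t) for t in raw["planted_triads"]],
        )
    return cohort, truth


EWAS_COVARIATES = [
    "age",
    "sex",
    "visit_batch",
    "bisulphite_conversion_mean",
    "plate",
]


def _ewas_covariate_frame(covariates: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in EWAS_COVARIATES if c in covariates.columns]
    cols += [c for c in covariates.columns if c.startswith("cell_")]
    return covariates[cols]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns a dict of in-memory results keyed by stage, writes one TSV per
    result table under ``config.out_dir`` and a ``manifest.json`` with the
    config snapshot, seeds and per-stage row counts.  Stage dependencies
    are enforced: ``integrate`` requires ``ewas`` and ``meqtl``.
    """
    stages = tuple(config.stages)
    if "integrate" in stages and not {"ewas", "meqtl"} <= set(stages):
        raise ValueError("the integrate stage requires both the ewas and meqtl stages")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": _version,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    results: dict = {}

    if config.input_dir is None:
        sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
        cohort, truth = simulate_cohort(sim_cfg)
    else:
        cohort, truth = read_inputs(config)
    results["cohort"], results["truth"] = cohort, truth
    manifest["stages"]["input"] = {
        "samples": len(cohort.betas.index),
        "probes": len(cohort.betas.columns),
        "snps": len(cohort.dosages.columns),
    }

    cov = _ewas_covariate_frame(cohort.covariates)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    ewas_tables = []
    if "ewas" in stages:
        specs = [s for s in MARKER_PANEL if s.marker in cohort.phenotypes.columns]
        for spec in specs:
            tab = ewas_scan(
                cohort.betas, cohort.phenotypes[spec.marker], spec, cov, config.fdr_alpha
            )
            ewas_tables.append(tab)
        ewas_all = pd.concat(ewas_tables, ignore_index=True)
        results["ewas"] = ewas_all
        ewas_all.to_csv(out / "ewas.tsv", sep="\t", index=False)
        sig = ewas_all[ewas_all["q"] < config.fdr_alpha]
        manifest["stages"]["ewas"] = {
            "tests": len(ewas_all),
            "fdr_significant_records": int(len(sig)),
            "fdr_significant_probes": int(sig["probe"].nunique()),
        }

        # BMI sensitivity for gated-in markers, on their associated probes
        bmi_rows = []
        if "BMI" in cohort.covariates.columns:
            for spec in specs:
                assoc = sig[sig["marker"] == spec.marker]["probe"].tolist()
                res = bmi_sensitivity(
                    cohort.phenotypes[spec.marker], spec, cohort.betas, cov,
                    sex=cohort.covariates["sex"], bmi=cohort.covariates["BMI"],
                    probes=assoc,
                )
                bmi_rows.append((spec.marker, res.gate_p, res.gated_in, len(res.table)))
            results["bmi_gates"] = pd.DataFrame(
                bmi_rows, columns=["marker", "gate_p", "gated_in", "n_secondary_fits"]
            )
            results["bmi_gates"].to_csv(out / "bmi_gates.tsv", sep="\t", index=False)

    if "annotate" in stages:
        labels = annotate_probes(
            cohort.manifest, cohort.islands, cohort.transcripts,
            config.shore_bp, config.shelf_bp,
        )
        results["annotation"] = labels
        labels.to_csv(out / "annotation.tsv", sep="\t")
        manifest["stages"]["annotate"] = {"probes": len(labels)}
        if "ewas" in stages:
            assoc = set(results["ewas"].loc[results["ewas"]["q"] < config.fdr_alpha, "probe"])
            if assoc:
                enr = context_enrichment(assoc, set(labels.index), labels, "island_context")
                results["enrichment_island"] = enr
                enr.to_csv(out / "enrichment_island.tsv", sep="\t")
                enr2 = context_enrichment(assoc, set(labels.index), labels, "collapsed_feature")
                results["enrichment_feature"] = enr2
                enr2.to_csv(out / "enrichment_feature.tsv", sep="\t")

    if "meqtl" in stages:
        kept_snps = snp_filter(cohort.snp_meta, config.maf_min, config.info_min)
        dos = cohort.dosages[kept_snps]
        meta = cohort.snp_meta.loc[kept_snps]
        pairs = cis_pairs(cohort.manifest, meta, config.window_bp)
        scan = cis_scan(cohort.betas, cohort.manifest, dos, meta, config.window_bp, pairs=pairs)
        fdr = permutation_fdr(
            cohort.betas, cohort.manifest, dos, meta,
            window_bp=config.window_bp, n_perm=config.meqtl_perms,
            seed=int(rng.integers(2**31 - 1)), pairs=pairs, observed_scan=scan,
        )
        scan = fdr.significant_records(scan)
        results["meqtl"] = scan
        results["meqtl_fdr"] = fdr
        scan.to_csv(out / "meqtl.tsv", sep="\t", index=False)
        with open(out / "meqtl_fdr.json", "w") as fh:
            json.dump(
                {
                    "threshold_p": fdr.threshold_p,
                    "n_perm": fdr.n_perm,
                    "target": fdr.target,
                    "n_significant_probes": fdr.n_significant,
                },
                fh,
                indent=1,
            )
        manifest["stages"]["meqtl"] = {
            "snps_kept": len(kept_snps),
            "cis_pairs": len(scan),
            "threshold_p": fdr.threshold_p,
            "significant_probes": fdr.n_significant,
        }

    if "integrate" in stages:
        scan = results["meqtl"]
        sig_snps = sorted(scan.loc[scan["significant"], "snp"].unique())
        sp_rows = []
        for snp in sig_snps:
            for marker in cohort.phenotypes.columns:
                p, perm_p = snp_phenotype_assoc(
                    cohort.dosages[snp], cohort.phenotypes[marker],
                    B=config.perm_B, seed=int(rng.integers(2**31 - 1)),
                )
                sp_rows.append((snp, marker, p, perm_p))
        snp_phen = pd.DataFrame(sp_rows, columns=["snp", "marker", "p", "perm_p"])
        results["snp_phenotype"] = snp_phen
        snp_phen.to_csv(out / "snp_phenotype.tsv", sep="\t", index=False)
        triads = triad_screen(scan, snp_phen, results["ewas"])
        results["triads"] = triads
        triads.to_csv(out / "triads.tsv", sep="\t", index=False)
        overlap = gwas_overlap_enrichment(
            set(sig_snps), set(scan["snp"].unique()), cohort.gwas, config.gwas_p_cut
        ) if sig_snps else None
        results["gwas_overlap"] = overlap
        if overlap is not None:
            with open(out / "gwas_overlap.json", "w") as fh:
                json.dump(
                    {"counts": overlap.counts, "odds_ratio": overlap.odds_ratio, "p": overlap.p},
                    fh,
                    indent=1,
                )
        manifest["stages"]["integrate"] = {
            "snp_phenotype_tests": len(snp_phen),
            "triads_tested": len(triads),
            "triads_passing": int(triads["passes"].sum()) if len(triads) else 0,
        }

    if "disease" in stages:
        if "ewas" in stages:
            cand = sorted(results["ewas"].loc[results["ewas"]["q"] < config.fdr_alpha, "probe"].unique())
        else:
            cand = list(cohort.betas.columns)
        if cand:
            secondary = cohort.covariates[[c for c in ("BMI", "smoking") if c in cohort.covariates.columns]]
            screen = incident_screen(
                cand,
                cohort.outcomes[[c for c in ("T2D", "CVD") if c in cohort.outcomes.columns]],
                cohort.betas, cov, secondary,
                B=config.perm_B, seed=int(rng.integers(2**31 - 1)),
                perm_alpha=config.perm_gate,
            )
            if "ewas" in stages:
                screen = attach_context(
                    screen, results["ewas"], results.get("annotation"), config.fdr_alpha
                )
            results["disease"] = screen
            screen.to_csv(out / "disease.tsv", sep="\t", index=False)
            manifest["stages"]["disease"] = {
                "candidates": len(cand),
                "perm_significant": int(screen["perm_sig"].sum()),
            }

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    results["manifest"] = manifest
    return results
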