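"""Synthetic cohort generator with planted ground truth.

Every downstream stage of the pipeline is testable without any external
download: this module draws a full cohort — methylation betas (or raw
intensities), imputed genotype dosages, ten oxidative-stress markers,
covariates with blood cell-mixture confounding, incident-disease flags,
and genome annotations (CpG islands, transcripts) — and returns a truth
table of the planted effects.

Methylation is generated on the logit scale (probe baseline + cell-mixture
loadings + batch/plate/conversion effects + planted meQTL dosage effect +
planted marker coupling + Gaussian noise) and mapped through the inverse
logit, so betas stay in (0, 1) and planted effects translate to
approximately linear beta-scale slopes near beta = 0.5.

The ten markers reproduce the cohort's reported moments (e.g. homocysteine
10.6 +/- 3.98 umol/l in 966 samples) including per-marker missingness
(OLAB observed in 734 of 966); oxLDL and OLAB are drawn log-normal, the
rest normal.  Incident type 2 diabetes is drawn from a logistic model on
planted CpGs plus age/sex/BMI/smoking; cardiovascular sub-outcomes
(myocardial infarction, stroke, heart failure) are drawn null and combined
into the composite CVD flag.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from oxewas.qc import IntensityData

__all__ = [
    "MARKER_TABLE",
    "SimConfig",
    "SyntheticTruth",
    "Cohort",
    "simulate_cohort",
    "simulate_intensities",
    "write_fixture",
]

#: marker -> (location, scale, moments_scale, transform, n_observed of 966).
#: moments_scale 'raw' means the location/scale describe the raw variable;
#: 'log' means they describe its natural log.
MARKER_TABLE: dict[str, tuple[float, float, str, str, int]] = {
    "TGSH": (905.0, 199.3, "raw", "none", 958),
    "GSH": (829.9, 191.1, "raw", "none", 957),
    "GSSG": (75.8, 35.7, "raw", "none", 959),
    "GSSG/GSH": (0.1, 0.06, "raw", "none", 957),
    "HCY": (10.6, 3.98, "raw", "none", 966),
    "oxLDL": (132.8, 47.7, "raw", "ln", 966),
    "CD": (40.7, 11.1, "raw", "none", 966),
    "BCD-LDL": (21.7, 7.4, "raw", "none", 964),
    "OLAB": (5.9, 0.96, "log", "ln", 734),
    "TAOC": (37.6, 3.9, "raw", "none", 957),
}

CELL_TYPE_PROPS = {
    "neutrophils": 0.55,
    "cd4t": 0.15,
    "cd8t": 0.10,
    "bcell": 0.05,
    "nk": 0.05,
    "monocytes": 0.10,
}


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study's conditions.

    ``cpg_effect_size`` is the logit-scale slope per standard deviation of
    the (transformed) marker; ``meqtl_r2`` is the fraction of logit-scale
    variance explained by the planted dosage; ``disease_log_or_per_sd`` is
    the log-odds of incident disease per SD *increase* in methylation
    (negative values mean hypomethylation carries risk, mirroring the
    reported OR of 1.39 per SD decrement).
    """

    n_samples: int = 966
    n_probes: int = 5000
    n_snps: int = 5000
    n_phenotypes: int = 10
    marker_means_sds: dict[str, tuple[float, float, str, str, int]] = field(
        default_factory=lambda: dict(MARKER_TABLE)
    )
    frac_true_cpg_effects: float = 0.01
    cpg_effect_size: float = 0.15
    frac_cis_meqtl: float = 0.10
    meqtl_r2: float = 0.20
    n_cell_types: int = 6
    cell_confounding_strength: float = 1.0
    disease_prevalence: float = 71 / 966
    disease_log_or_per_sd: float = -0.33
    n_disease_cpgs: int = 2
    n_triads: int = 1
    triad_snp_marker_r2: float = 0.08
    genome_length: int = 50_000_000
    island_density: float = 10.0  # islands per Mb
    noise_sd: float = 0.4
    marker_missingness: bool = True
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_probes", "n_snps", "n_phenotypes", "genome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_true_cpg_effects", "frac_cis_meqtl", "disease_prevalence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.meqtl_r2 < 1.0:
            raise ValueError("meqtl_r2 must lie in [0, 1)")
        if self.cell_confounding_strength < 0:
            raise ValueError("cell_confounding_strength must be nonnegative")
        if self.n_phenotypes > len(self.marker_means_sds):
            raise ValueError("n_phenotypes exceeds the marker table")


@dataclass
class SyntheticTruth:
    """Planted effects: the oracle downstream stages are judged against.

    ``true_cpg_phenotype_pairs`` slopes are linearised beta-scale slopes per
    unit of the *transformed* marker (logit slope / 4 / marker SD, valid for
    probes planted at baseline beta = 0.5); ``true_meqtl_pairs`` slopes are
    logit-scale slopes per dosage unit; ``true_disease_cpgs`` store the
    log-odds per SD increase in methylation.
    """

    true_cpg_phenotype_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    true_meqtl_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    true_disease_cpgs: list[tuple[str, float]] = field(default_factory=list)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)

    def cpg_probes(self) -> set[str]:
        return {p for p, _, _ in self.true_cpg_phenotype_pairs}

    def meqtl_probes(self) -> set[str]:
        return {p for _, p, _ in self.true_meqtl_pairs}

    def validate(self, cohort: "Cohort") -> None:
        probes = set(cohort.betas.columns)
        snps = set(cohort.dosages.columns)
        markers = set(cohort.phenotypes.columns)
        for p, m, _ in self.true_cpg_phenotype_pairs:
            assert p in probes and m in markers
        for s, p, _ in self.true_meqtl_pairs:
            assert s in snps and p in probes
        meqtl_keys = {(s, p) for s, p, _ in self.true_meqtl_pairs}
        cpg_keys = {(p, m) for p, m, _ in self.true_cpg_phenotype_pairs}
        for s, p, m in self.planted_triads:
            assert (s, p) in meqtl_keys, "triad not among planted meQTLs"
            assert (p, m) in cpg_keys, "triad not among planted CpG-phenotype pairs"


@dataclass
class Cohort:
    """In-memory bundle of everything the pipeline consumes."""

    betas: pd.DataFrame  # samples x probes
    dosages: pd.DataFrame  # samples x snps
    snp_meta: pd.DataFrame  # snp -> chromosome, position, maf, info
    manifest: pd.DataFrame  # probe -> chromosome, position, design_type, ...
    islands: pd.DataFrame  # chrom, start, end (1-based inclusive)
    transcripts: pd.DataFrame
    phenotypes: pd.DataFrame  # samples x markers (raw scale, with NaN)
    covariates: pd.DataFrame  # samples x covariate columns
    outcomes: pd.DataFrame  # samples x {T2D, CVD, MI, stroke, HF}
    gwas: pd.DataFrame  # snp, p
    config: SimConfig


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _draw_annotations(cfg: SimConfig, rng: np.random.Generator):
    n_islands = max(1, round(cfg.island_density * cfg.genome_length / 1e6))
    starts = np.sort(rng.integers(1, cfg.genome_length - 3000, size=n_islands))
    lengths = rng.integers(200, 2000, size=n_islands)
    islands = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": np.minimum(starts + lengths, cfg.genome_length)}
    )
    n_tx = max(4, cfg.n_probes // 50)
    tx_rows = []
    for i in range(n_tx):
        span = int(rng.integers(5000, 50000))
        left = int(rng.integers(2000, cfg.genome_length - span - 2000))
        right = left + span
        strand = "+" if rng.random() < 0.5 else "-"
        e1 = int(rng.integers(200, 500))
        utr3 = int(rng.integers(100, 300))
        if strand == "+":
            tss, tes = left, right
            exon1 = (tss, tss + e1)
            utr5 = (tss, tss + 100)
            utr3_iv = (tes - utr3, tes)
        else:
            tss, tes = right, left
            exon1 = (tss - e1, tss)
            utr5 = (tss - 100, tss)
            utr3_iv = (tes, tes + utr3)
        tx_rows.append(
            (f"TX{i:04d}", "chr1", strand, tss, tes, exon1[0], exon1[1], utr5[0], utr5[1], utr3_iv[0], utr3_iv[1])
        )
    transcripts = pd.DataFrame(
        tx_rows,
        columns=[
            "transcript", "chrom", "strand", "tss", "tes",
            "exon1_start", "exon1_end", "utr5_start", "utr5_end", "utr3_start", "utr3_end",
        ],
    ).set_index("transcript")
    return islands, transcripts


def simulate_cohort(config: SimConfig | None = None) -> tuple[Cohort, SyntheticTruth]:
    """Draw a full synthetic cohort and its planted-effect truth table.

    Fixed seed implies a byte-identical cohort.  A configuration with
    ``frac_true_cpg_effects = frac_cis_meqtl = 0`` and
    ``disease_log_or_per_sd = 0`` yields a global-null cohort with empty
    truth lists.
    """
    cfg = config or SimConfig()
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    (r_cov, r_geno, r_marker, r_probe, r_noise, r_disease, r_misc) = [
        np.random.default_rng(s) for s in ss.spawn(7)
    ]
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(n)]

    # --- covariates and cell mixture -------------------------------------
    age = 70.2 + 0.2 * r_cov.standard_normal(n)
    sex = (r_cov.random(n) < 0.5).astype(float)
    bmi = np.clip(27.0 + 4.0 * r_cov.standard_normal(n), 16, 50)
    smoking = (r_cov.random(n) < 0.11).astype(float)
    visit_batch = np.array([f"B{b}" for b in r_cov.integers(0, 3, size=n)])
    n_plates = max(1, math.ceil(n / 96))
    plate = np.array([f"P{p:02d}" for p in r_cov.integers(0, n_plates, size=n)])
    conversion = 98.5 + 0.8 * r_cov.standard_normal(n)
    leukocytes = np.exp(r_cov.normal(math.log(6.0), 0.25, size=n))

    cell_names = list(CELL_TYPE_PROPS)[: cfg.n_cell_types]
    props = np.array([CELL_TYPE_PROPS[c] for c in cell_names])
    props = props / props.sum()
    alpha = 60.0 * props
    cells_true = r_cov.dirichlet(alpha, size=n)
    # Houseman-style predictions: truth plus estimation error, not renormalised
    cells_pred = np.clip(cells_true + 0.01 * r_cov.standard_normal((n, len(cell_names))), 0, None)

    covariates = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "BMI": bmi,
            "smoking": smoking,
            "visit_batch": visit_batch,
            "plate": plate,
            "bisulphite_conversion_mean": conversion,
            "leukocyte_count": leukocytes,
            **{f"cell_{c}": cells_pred[:, j] for j, c in enumerate(cell_names)},
        },
        index=samples,
    )

    # --- genotypes --------------------------------------------------------
    snp_ids = [f"rs{i:06d}" for i in range(cfg.n_snps)]
    snp_pos = np.sort(r_geno.integers(1, cfg.genome_length, size=cfg.n_snps))
    maf = r_geno.uniform(0.01, 0.5, size=cfg.n_snps)
    info = r_geno.uniform(0.6, 1.0, size=cfg.n_snps)

    # --- probes -----------------------------------------------------------
    probe_ids = [f"cg{i:07d}" for i in range(cfg.n_probes)]
    probe_pos = np.sort(r_probe.integers(1, cfg.genome_length, size=cfg.n_probes))
    design_type = np.where(r_probe.random(cfg.n_probes) < 0.3, "I", "II")

    # --- planted structure -------------------------------------------------
    markers = list(cfg.marker_means_sds)[: cfg.n_phenotypes]
    n_true_cpg = round(cfg.frac_true_cpg_effects * cfg.n_probes)
    # one SNP per planted meQTL probe, so the SNP panel caps the count
    n_meqtl = min(round(cfg.frac_cis_meqtl * cfg.n_probes), cfg.n_snps)
    n_triads = cfg.n_triads if (n_true_cpg > 0 and n_meqtl > 0) else 0
    n_triads = min(n_triads, n_true_cpg, n_meqtl)

    perm = r_probe.permutation(cfg.n_probes)
    triad_probe_idx = perm[:n_triads]
    cpg_only_idx = perm[n_triads:n_true_cpg]
    meqtl_only_idx = perm[n_true_cpg : n_true_cpg + (n_meqtl - n_triads)]
    cpg_idx = np.concatenate([triad_probe_idx, cpg_only_idx]).astype(int)
    meqtl_idx = np.concatenate([triad_probe_idx, meqtl_only_idx]).astype(int)

    # assign a marker to each CpG-effect probe (round robin over the panel)
    cpg_marker = {int(i): markers[k % len(markers)] for k, i in enumerate(cpg_idx)}

    # choose a cis SNP for each meQTL probe; relocate a SNP when none is in window
    window = 100_000
    snp_pos = snp_pos.copy()
    meqtl_snp: dict[int, int] = {}
    used_snps: set[int] = set()
    for i in meqtl_idx:
        pos = int(probe_pos[i])
        in_window = np.flatnonzero(np.abs(snp_pos - pos) <= window)
        in_window = [j for j in in_window if j not in used_snps]
        if in_window:
            j = int(r_geno.choice(in_window))
        else:
            free = np.setdiff1d(np.arange(cfg.n_snps), np.fromiter(used_snps, dtype=int, count=len(used_snps)))
            j = int(r_geno.choice(free))
            snp_pos[j] = min(max(1, pos + int(r_geno.integers(-window // 2, window // 2))), cfg.genome_length)
        used_snps.add(j)
        meqtl_snp[int(i)] = j
        maf[j] = r_geno.uniform(0.2, 0.5)
        info[j] = r_geno.uniform(0.92, 1.0)

    # Hardy-Weinberg genotypes plus small imputation noise, quantised like
    # posterior-mean dosages
    p_alt = maf
    g = (r_geno.random((n, cfg.n_snps)) < p_alt).astype(float) + (
        r_geno.random((n, cfg.n_snps)) < p_alt
    ).astype(float)
    dos = np.clip(g + 0.05 * r_geno.standard_normal((n, cfg.n_snps)), 0.0, 2.0)
    dos = np.round(dos, 3)

    snp_meta = pd.DataFrame(
        {"chromosome": "chr1", "position": snp_pos, "maf": maf, "info": info},
        index=pd.Index(snp_ids, name="snp"),
    )
    dosages = pd.DataFrame(dos, index=samples, columns=snp_ids)

    # --- oxidative markers -------------------------------------------------
    cell_centered = cells_true - cells_true.mean(axis=0)
    cell_dir = r_marker.standard_normal(len(cell_names))
    cell_score = cell_centered @ cell_dir
    sd_cs = cell_score.std()
    cell_score = cell_score / sd_cs if sd_cs > 0 else cell_score

    kappa = 0.2 * min(cfg.cell_confounding_strength, 1.0)  # marker-cell coupling
    z_latent = np.empty((n, len(markers)))
    triad_marker: dict[int, str] = {}
    triad_gamma = math.sqrt(cfg.triad_snp_marker_r2) if n_triads else 0.0
    for k, marker in enumerate(markers):
        eps = r_marker.standard_normal(n)
        load = math.sqrt(max(1.0 - kappa**2, 0.0))
        z = load * eps + kappa * cell_score
        z_latent[:, k] = z
    # triad SNP -> marker effects (direct genetic effect on the marker)
    for t, i in enumerate(triad_probe_idx):
        marker = cpg_marker[int(i)]
        k = markers.index(marker)
        d = dosages.iloc[:, meqtl_snp[int(i)]].to_numpy()
        d_std = (d - d.mean()) / d.std()
        z = z_latent[:, k]
        z_latent[:, k] = math.sqrt(max(1 - triad_gamma**2, 0.0)) * z + triad_gamma * d_std
        triad_marker[int(i)] = marker

    phen = {}
    for k, marker in enumerate(markers):
        loc, scale, mscale, _transform, n_obs = cfg.marker_means_sds[marker]
        z = z_latent[:, k]
        if mscale == "log":
            vals = np.exp(loc + scale * z)
        elif _transform == "ln":  # raw-scale moments, log-normal draw
            sigma2 = math.log(1.0 + (scale / loc) ** 2)
            mu = math.log(loc) - sigma2 / 2.0
            vals = np.exp(mu + math.sqrt(sigma2) * z)
        else:
            vals = loc + scale * z
        if cfg.marker_missingness and n_obs < 966:
            miss_rate = 1.0 - n_obs / 966.0
            miss = r_marker.random(n) < miss_rate
            vals = np.where(miss, np.nan, vals)
        phen[marker] = vals
    phenotypes = pd.DataFrame(phen, index=samples)

    # --- methylation -------------------------------------------------------
    b0 = np.empty(cfg.n_probes)
    comp = r_probe.random(cfg.n_probes)
    b0[comp < 0.4] = r_probe.normal(-2.5, 0.7, size=int((comp < 0.4).sum()))
    b0[(comp >= 0.4) & (comp < 0.8)] = r_probe.normal(2.5, 0.7, size=int(((comp >= 0.4) & (comp < 0.8)).sum()))
    b0[comp >= 0.8] = r_probe.normal(0.0, 1.0, size=int((comp >= 0.8).sum()))
    planted = np.concatenate([cpg_idx, meqtl_idx]).astype(int)
    b0[planted] = 0.0  # keep planted probes near beta = 0.5 for linearity

    cell_load = cfg.cell_confounding_strength * r_probe.standard_normal(
        (cfg.n_probes, len(cell_names))
    )
    batch_levels = sorted(set(visit_batch))
    batch_load = 0.1 * r_probe.standard_normal((cfg.n_probes, len(batch_levels)))
    batch_idx = np.searchsorted(batch_levels, visit_batch)
    plate_levels = sorted(set(plate))
    plate_load = 0.05 * r_probe.standard_normal((cfg.n_probes, len(plate_levels)))
    plate_idx = np.searchsorted(plate_levels, plate)
    conv_load = 0.02 * r_probe.standard_normal(cfg.n_probes)
    conv_c = conversion - conversion.mean()

    logit = (
        b0[None, :]
        + cell_centered @ cell_load.T
        + batch_load.T[batch_idx, :]
        + plate_load.T[plate_idx, :]
        + conv_c[:, None] * conv_load[None, :]
        + cfg.noise_sd * r_noise.standard_normal((n, cfg.n_probes))
    )

    # planted marker couplings (logit slope per SD of transformed marker)
    truth = SyntheticTruth()
    for i in cpg_idx:
        marker = cpg_marker[int(i)]
        k = markers.index(marker)
        logit[:, i] += cfg.cpg_effect_size * z_latent[:, k]
        _loc, scale, mscale, transform, _n_obs = cfg.marker_means_sds[marker]
        if mscale == "log":
            sd_t = scale
        elif transform == "ln":
            sd_t = math.sqrt(math.log(1.0 + (scale / _loc) ** 2))
        else:
            sd_t = scale
        truth.true_cpg_phenotype_pairs.append(
            (probe_ids[int(i)], marker, cfg.cpg_effect_size / (4.0 * sd_t))
        )

    # planted meQTLs: slope set so the dosage explains meqtl_r2 of the
    # probe's realised logit-scale variance
    for i in meqtl_idx:
        j = meqtl_snp[int(i)]
        d = dosages.iloc[:, j].to_numpy()
        var_d = d.var()
        var_rest = logit[:, i].var()
        slope = math.sqrt(cfg.meqtl_r2 / (1.0 - cfg.meqtl_r2) * var_rest / var_d)
        logit[:, i] += slope * (d - d.mean())
        truth.true_meqtl_pairs.append((snp_ids[j], probe_ids[int(i)], slope))

    for i in triad_probe_idx:
        truth.planted_triads.append(
            (snp_ids[meqtl_snp[int(i)]], probe_ids[int(i)], triad_marker[int(i)])
        )

    betas = pd.DataFrame(_sigmoid(logit), index=samples, columns=probe_ids)

    # --- incident disease ---------------------------------------------------
    outcomes = pd.DataFrame(index=pd.Index(samples), dtype=float)
    lin = 0.2 * sex + 0.4 * smoking + 0.03 * (bmi - 27.0) + 0.1 * (age - 70.2)
    disease_idx = cpg_idx[: cfg.n_disease_cpgs] if cfg.disease_log_or_per_sd != 0 else []
    for i in disease_idx:
        col = betas.iloc[:, int(i)].to_numpy()
        z = (col - col.mean()) / col.std(ddof=1)
        lin = lin + cfg.disease_log_or_per_sd * z
        truth.true_disease_cpgs.append((probe_ids[int(i)], cfg.disease_log_or_per_sd))

    def _solve_intercept(linpred: np.ndarray, prevalence: float) -> float:
        return brentq(lambda a: _sigmoid(a + linpred).mean() - prevalence, -20, 20)

    a0 = _solve_intercept(lin, cfg.disease_prevalence)
    outcomes["T2D"] = (r_disease.random(n) < _sigmoid(a0 + lin)).astype(int)
    for sub, prev in (("MI", 55 / 966), ("stroke", 47 / 966), ("HF", 76 / 966)):
        base = 0.2 * sex + 0.1 * (age - 70.2)
        a = _solve_intercept(base, prev)
        outcomes[sub] = (r_disease.random(n) < _sigmoid(a + base)).astype(int)
    outcomes["CVD"] = outcomes[["MI", "stroke", "HF"]].max(axis=1)

    # --- manifest and annotations -------------------------------------------
    manifest = pd.DataFrame(
        {
            "chromosome": "chr1",
            "position": probe_pos,
            "design_type": design_type,
            "multi_mapping": False,
            "nearest_common_snp_distance": np.nan,
            "overlaps_cnv": False,
            "autosomal": True,
        },
        index=pd.Index(probe_ids, name="probe"),
    )
    islands, transcripts = _draw_annotations(cfg, r_misc)
    gwas = pd.DataFrame({"snp": snp_ids, "p": r_misc.random(cfg.n_snps)})

    cohort = Cohort(
        betas=betas,
        dosages=dosages,
        snp_meta=snp_meta,
        manifest=manifest,
        islands=islands,
        transcripts=transcripts,
        phenotypes=phenotypes,
        covariates=covariates,
        outcomes=outcomes,
        gwas=gwas,
        config=cfg,
    )
    truth.validate(cohort)
    return cohort, truth


def simulate_intensities(
    betas: pd.DataFrame,
    intensity_scale: float = 10_000.0,
    seed: int | None = None,
    noise_sd: float = 0.0,
    fail_fraction: float = 0.0,
    fail_samples: list[str] | None = None,
    design_type: pd.Series | None = None,
) -> IntensityData:
    """Invert beta values into methylated/unmethylated intensity matrices.

    ``M = scale * beta * exp(noise)`` and ``U = scale * (1 - beta) * exp(noise)``
    with independent log-normal channel noise, so ``M / (M + U)`` recovers
    the input betas exactly when ``noise_sd = 0``.  ``fail_fraction`` of
    cells (in ``fail_samples``, or everywhere when None) receive detection
    p-values above 0.01 to exercise the sample pass-rate filter; all other
    cells get detection p <= 0.009.
    """
    if intensity_scale <= 0:
        raise ValueError("intensity_scale must be positive")
    vals = betas.to_numpy(dtype=float)
    if (vals <= 0).any() or (vals >= 1).any():
        raise ValueError("betas must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    shape = vals.shape
    noise_m = np.exp(noise_sd * rng.standard_normal(shape)) if noise_sd > 0 else 1.0
    noise_u = np.exp(noise_sd * rng.standard_normal(shape)) if noise_sd > 0 else 1.0
    meth = intensity_scale * vals * noise_m
    unmeth = intensity_scale * (1.0 - vals) * noise_u
    det = rng.uniform(0.0, 0.009, size=shape)
    if fail_fraction > 0:
        if fail_samples is None:
            rows = np.arange(shape[0])
        else:
            rows = np.array([betas.index.get_loc(s) for s in fail_samples])
        for r in rows:
            k = int(round(fail_fraction * shape[1]))
            cols = rng.choice(shape[1], size=k, replace=False)
            det[r, cols] = rng.uniform(0.011, 1.0, size=k)
    if design_type is None:
        design_type = pd.Series(
            np.where(rng.random(shape[1]) < 0.3, "I", "II"), index=betas.columns
        )
    return IntensityData(
        methylated=pd.DataFrame(meth, index=betas.index, columns=betas.columns),
        unmethylated=pd.DataFrame(unmeth, index=betas.index, columns=betas.columns),
        detection_p=pd.DataFrame(det, index=betas.index, columns=betas.columns),
        design_type=design_type,
    )


def write_fixture(cohort: Cohort, truth: SyntheticTruth, directory: str | Path) -> dict[str, Path]:
    """Write the cohort to plain-text files; re-reading yields equal values.

    Layout: beta TSV (probes as rows, samples as columns), dosage VCF v4.2
    (DS and GP FORMAT fields, MAF/INFO in INFO), plain dosage TSV, probe
    manifest TSV, islands BED (0-based half-open on disk), transcripts TSV,
    covariates/phenotypes/outcomes TSVs, GWAS summary TSV and a truth JSON.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["betas"] = directory / "betas.tsv"
    cohort.betas.T.rename_axis("probe").to_csv(paths["betas"], sep="\t")
    paths["covariates"] = directory / "covariates.tsv"
    cohort.covariates.rename_axis("sample").to_csv(paths["covariates"], sep="\t")
    paths["phenotypes"] = directory / "phenotypes.tsv"
    cohort.phenotypes.rename_axis("sample").to_csv(paths["phenotypes"], sep="\t")
    paths["outcomes"] = directory / "outcomes.tsv"
    cohort.outcomes.rename_axis("sample").to_csv(paths["outcomes"], sep="\t")
    paths["manifest"] = directory / "manifest.tsv"
    cohort.manifest.to_csv(paths["manifest"], sep="\t")
    paths["transcripts"] = directory / "transcripts.tsv"
    cohort.transcripts.to_csv(paths["transcripts"], sep="\t")
    paths["gwas"] = directory / "gwas.tsv"
    cohort.gwas.to_csv(paths["gwas"], sep="\t", index=False)
    paths["dosages"] = directory / "dosages.tsv"
    cohort.dosages.T.rename_axis("snp").to_csv(paths["dosages"], sep="\t")

    paths["islands"] = directory / "islands.bed"
    with open(paths["islands"], "w") as fh:
        for _, row in cohort.islands.iterrows():
            # 1-based inclusive -> 0-based half-open
            fh.write(f"{row['chrom']}\t{row['start'] - 1}\t{row['end']}\n")

    paths["vcf"] = directory / "genotypes.vcf"
    _write_vcf(paths["vcf"], cohort)

    paths["truth"] = directory / "truth.json"
    with open(paths["truth"], "w") as fh:
        json.dump(
            {
                "true_cpg_phenotype_pairs": truth.true_cpg_phenotype_pairs,
                "true_meqtl_pairs": truth.true_meqtl_pairs,
                "true_disease_cpgs": truth.true_disease_cpgs,
                "planted_triads": truth.planted_triads,
            },
            fh,
            indent=1,
        )
    return paths


def _write_vcf(path: Path, cohort: Cohort) -> None:
    samples = list(cohort.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID=chr1,length={cohort.config.genome_length}>\n")
        fh.write('##INFO=<ID=MAF,Number=1,Type=Float,Description="Minor allele frequency">\n')
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Posterior mean dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype probabilities">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        order = np.argsort(cohort.snp_meta["position"].to_numpy(), kind="mergesort")
        for j in order:
            snp = cohort.snp_meta.index[j]
            meta = cohort.snp_meta.iloc[j]
            ds = cohort.dosages[snp].to_numpy()
            fields = []
            for d in ds:
                p_het = d if d <= 1 else 2.0 - d
                p_hom = 0.0 if d <= 1 else d - 1.0
                p_ref = max(1.0 - p_het - p_hom, 0.0)
                fields.append(f"{d:.3f}:{p_ref:.3f},{p_het:.3f},{p_hom:.3f}")
            fh.write(
                f"chr1\t{int(meta['position'])}\t{snp}\tA\tG\t.\tPASS\t"
                f"MAF={meta['maf']:.4f};INFO={meta['info']:.4f}\tDS:GP\t" + "\t".join(fields) + "\n"
            )
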