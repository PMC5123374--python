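"""Generate a small synthetic cohort and inspect its planted truth.

The generator draws methylation betas, genotype dosages, ten oxidative
stress markers (with the cohort's reported means/SDs and per-marker
missingness), covariates with cell-mixture confounding, and incident
disease flags.  The returned truth table lists every planted effect.
"""

from oxewas import SimConfig, simulate_cohort

cfg = SimConfig(n_samples=400, n_probes=300, n_snps=1000, seed=1,
                genome_length=20_000_000)
cohort, truth = simulate_cohort(cfg)

print(f"betas: {cohort.betas.shape[0]} samples x {cohort.betas.shape[1]} probes, "
      f"range ({cohort.betas.values.min():.3f}, {cohort.betas.values.max():.3f})")
print("\nmarker panel (sample mean / SD, NaN = missing visits):")
print(cohort.phenotypes.describe().loc[["count", "mean", "std"]].T.round(2))
print(f"\nincident T2D cases: {cohort.outcomes['T2D'].sum()}, "
      f"CVD composite: {cohort.outcomes['CVD'].sum()}")
print(f"planted CpG-marker effects: {len(truth.true_cpg_phenotype_pairs)}")
print(f"planted cis-meQTLs:         {len(truth.true_meqtl_pairs)}")
print(f"planted triads:             {truth.planted_triads}")
# The means/SDs above should sit near the configured marker table (e.g.
# HCY 10.6 +/- 3.98); the truth lists are what downstream scans must recover.
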