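"""SNP-phenotype association and methylation-mediated triad integration.

A genetic effect on an oxidative marker may act through methylation.  The
screen looks for loci where three associations overlap:

* SNP -> phenotype at nominal p < 0.001 (suggestive evidence),
* SNP -> CpG: a significant cis-meQTL at the permutation FDR threshold,
* CpG -> phenotype at EWAS q < 0.05.

The module also tests whether significant meQTL SNPs are over-represented
among nominally significant hits (p < 0.05) of an external GWAS, with a
one-sided Fisher exact test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from oxewas._lrt import gaussian_lrt

logger = logging.getLogger(__name__)

__all__ = [
    "snp_phenotype_assoc",
    "triad_screen",
    "gwas_overlap_enrichment",
    "GwasOverlapResult",
    "TRIAD_SNP_P",
    "TRIAD_EWAS_Q",
]

# overlap gates: SNP-phenotype nominal p, EWAS q; the meQTL gate is the
# permutation-FDR significance flag.  These are the screen's definition,
# not tuning knobs.
TRIAD_SNP_P = 0.001
TRIAD_EWAS_Q = 0.05


def snp_phenotype_assoc(
    dosage: pd.Series | np.ndarray,
    marker: pd.Series | np.ndarray,
    B: int = 10000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> tuple[float, float]:
    """Additive-model association of a marker with a SNP dosage.

    Returns ``(p, perm_p)``: the Gaussian LRT p of ``marker ~ dosage`` and a
    genotype-permutation p with the +1 convention.  In ``exhaustive`` mode
    all distinct orderings of the dosage vector are enumerated instead
    (``p = #{stat >= observed}/N``); feasible only for small n.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(marker, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    res = gaussian_lrt(y, x)
    n = len(y)
    # the LRT is a monotone function of r^2, so permutation counting can use r^2
    yc = y - y.mean()
    xc = x - x.mean()
    yss = float(yc @ yc)
    obs_r2 = float((xc @ yc) ** 2 / ((xc @ xc) * yss))

    if exhaustive:
        perms = sorted(set(itertools.permutations(x)))
        count = 0
        for perm in perms:
            pv = np.asarray(perm) - x.mean()
            r2 = float((pv @ yc) ** 2 / ((pv @ pv) * yss))
            if r2 >= obs_r2 - 1e-12:
                count += 1
        return res.p, count / len(perms)

    rng = np.random.default_rng(seed)
    count = 0
    xss = float(xc @ xc)
    for _ in range(B):
        pv = xc[rng.permutation(n)]
        r2 = float((pv @ yc) ** 2 / (xss * yss))
        if r2 >= obs_r2 - 1e-12:
            count += 1
    return res.p, (1 + count) / (B + 1)


def triad_screen(
    meqtl: pd.DataFrame,
    snp_phenotype: pd.DataFrame,
    ewas: pd.DataFrame,
) -> pd.DataFrame:
    """Enumerate tested (SNP, probe, marker) triads and flag the passing ones.

    Inputs: the flagged cis-meQTL scan (columns probe, snp, significant),
    SNP-phenotype results (columns snp, marker, p) and the EWAS table
    (columns probe, marker, q).  A triad is listed when the (snp, probe)
    pair was cis-tested and both the (snp, marker) and (probe, marker)
    pairs were tested; it passes iff p_snp_phenotype < 0.001, the meQTL is
    significant, and q_cpg_phenotype < 0.05.  Ordering is deterministic
    (snp, probe, marker).
    """
    if "significant" not in meqtl.columns:
        raise ValueError("meqtl table must carry the permutation-FDR 'significant' flag")
    pairs = meqtl[["snp", "probe", "significant"]]
    sp = snp_phenotype[["snp", "marker", "p"]].rename(columns={"p": "p_snp_phenotype"})
    ew = ewas[["probe", "marker", "q"]].rename(columns={"q": "q_cpg_phenotype"})
    merged = pairs.merge(sp, on="snp").merge(ew, on=["probe", "marker"])
    merged = merged.rename(columns={"significant": "meqtl_significant"})
    merged["passes"] = (
        (merged["p_snp_phenotype"] < TRIAD_SNP_P)
        & merged["meqtl_significant"]
        & (merged["q_cpg_phenotype"] < TRIAD_EWAS_Q)
    )
    cols = ["snp", "probe", "marker", "p_snp_phenotype", "meqtl_significant", "q_cpg_phenotype", "passes"]
    return merged[cols].sort_values(["snp", "probe", "marker"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class GwasOverlapResult:
    """2x2 overlap of meQTL SNPs with nominal GWAS hits."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p: float
    n_dropped: int


def gwas_overlap_enrichment(
    meqtl_snps: set[str],
    all_tested_snps: set[str],
    gwas: pd.DataFrame,
    p_cut: float = 0.05,
) -> GwasOverlapResult:
    """One-sided Fisher test for over-representation of meQTL SNPs in GWAS hits.

    ``gwas`` has columns snp, p.  SNPs absent from the GWAS table are
    dropped with a logged count; the background is the set of tested SNPs
    present in the table.  The table is
    ``[[meQTL & hit, meQTL & ~hit], [~meQTL & hit, ~meQTL & ~hit]]`` with
    alternative='greater' (exact hypergeometric upper tail).
    """
    if not meqtl_snps <= all_tested_snps:
        raise ValueError("meqtl_snps must be a subset of all_tested_snps")
    gwas_p = gwas.set_index("snp")["p"]
    present = all_tested_snps & set(gwas_p.index)
    n_dropped = len(all_tested_snps) - len(present)
    if n_dropped:
        logger.info("dropped %d SNPs absent from the GWAS table", n_dropped)
    if not present:
        raise ValueError("no tested SNP appears in the GWAS table")
    hits = {s for s in present if gwas_p[s] < p_cut}
    mq = meqtl_snps & present
    a = len(mq & hits)
    b = len(mq - hits)
    c = len(hits - mq)
    d = len(present - hits - mq)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return GwasOverlapResult(counts=((a, b), (c, d)), odds_ratio=float(odds), p=float(p), n_dropped=n_dropped)
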