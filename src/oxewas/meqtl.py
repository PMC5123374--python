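"""cis-meQTL mapping with a permutation-based FDR threshold.

Each methylation probe is tested against every SNP within 100 kb of the CpG
(additive dosage model, Gaussian LRT of ``beta ~ dosage``).  Because only a
targeted set of probes is scanned (not the whole array), the FDR is
estimated by permutation rather than q-values: genotype sample labels are
permuted jointly across all SNPs (preserving LD), the scan is repeated
(default 10 replicates) keeping the most associated SNP per probe, and the
significance threshold is the largest nominal p at which the permuted data
yield fewer than 5% of the observed discoveries.

SNPs enter the scan only with MAF >= 5% and imputation INFO > 0.8; imputed
genotype probabilities are collapsed to posterior-mean dosages
``P(het) + 2 P(hom-alt)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "snp_filter",
    "dosage_from_probabilities",
    "cis_pairs",
    "cis_scan",
    "permutation_fdr",
    "PermFdrResult",
]


def snp_filter(
    snp_meta: pd.DataFrame,
    maf_min: float = 0.05,
    info_min: float = 0.8,
) -> list[str]:
    """SNP ids kept for analysis: MAF >= ``maf_min`` and INFO strictly > ``info_min``."""
    keep = (snp_meta["maf"] >= maf_min) & (snp_meta["info"] > info_min)
    return list(snp_meta.index[keep])


def dosage_from_probabilities(gp: np.ndarray) -> np.ndarray:
    """Posterior-mean dosage from genotype probability triples (ref, het, hom-alt).

    Probabilities must be nonnegative and sum to 1 within 1e-3 (they are
    renormalised); the dosage is ``P(het) + 2 P(hom-alt)`` in [0, 2].
    """
    gp = np.asarray(gp, dtype=float)
    if gp.shape[-1] != 3:
        raise ValueError("genotype probabilities must come in triples")
    if (gp < 0).any():
        raise ValueError("negative genotype probability")
    total = gp.sum(axis=-1)
    if (np.abs(total - 1.0) > 1e-3).any():
        raise ValueError("genotype probabilities do not sum to 1 within 1e-3")
    gp = gp / total[..., None]
    return gp[..., 1] + 2.0 * gp[..., 2]


def cis_pairs(
    manifest: pd.DataFrame,
    snp_meta: pd.DataFrame,
    window_bp: int = 100_000,
) -> pd.DataFrame:
    """All (probe, SNP) pairs on the same chromosome within the cis window.

    The window is inclusive on both sides: ``|snp_pos - probe_pos| <=
    window_bp``.  Distance is signed, ``snp_pos - probe_pos``.
    """
    rows = []
    snp_by_chrom = {c: g.sort_values("position") for c, g in snp_meta.groupby("chromosome")}
    for probe, rec in manifest.iterrows():
        group = snp_by_chrom.get(rec["chromosome"])
        if group is None:
            continue
        pos = int(rec["position"])
        positions = group["position"].to_numpy()
        lo = np.searchsorted(positions, pos - window_bp, side="left")
        hi = np.searchsorted(positions, pos + window_bp, side="right")
        for snp, spos in zip(group.index[lo:hi], positions[lo:hi]):
            rows.append((probe, snp, int(spos) - pos))
    return pd.DataFrame(rows, columns=["probe", "snp", "distance_bp"])


def cis_scan(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    dosages: pd.DataFrame,
    snp_meta: pd.DataFrame,
    window_bp: int = 100_000,
    pairs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive-model scan of all cis (probe, SNP) pairs.

    ``betas`` and ``dosages`` are samples x features with a shared sample
    index.  The per-pair model is ``beta ~ dosage`` with no covariates; the
    LRT statistic is ``-n log(1 - r^2)`` and p comes from chi-square(1).
    Records are sorted by probe then p.  An empty cis pairing yields an
    empty table.
    """
    if not betas.index.equals(dosages.index):
        raise ValueError("sample ids of betas and dosages are misaligned")
    if pairs is None:
        pairs = cis_pairs(manifest, snp_meta, window_bp)
    if pairs.empty:
        return pd.DataFrame(
            columns=["probe", "snp", "distance_bp", "slope", "lrt_stat", "p"]
        )
    n = len(betas)
    Yc = betas - betas.mean(axis=0)
    Xc = dosages - dosages.mean(axis=0)
    y_ss = (Yc**2).sum(axis=0)
    x_ss = (Xc**2).sum(axis=0)

    out_rows = []
    for probe, grp in pairs.groupby("probe", sort=True):
        yc = Yc[probe].to_numpy()
        snps = grp["snp"].tolist()
        Xg = Xc[snps].to_numpy()
        xy = yc @ Xg
        xss = x_ss[snps].to_numpy()
        yss = float(y_ss[probe])
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = xy / xss
            r2 = np.where((xss > 0) & (yss > 0), xy**2 / (xss * yss), 0.0)
        r2 = np.clip(r2, 0.0, 1.0)
        with np.errstate(divide="ignore"):
            lrt = np.where(r2 < 1.0, -n * np.log1p(-r2), np.inf)
        p = stats.chi2.sf(lrt, df=1)
        for snp, d, s, l, pv in zip(snps, grp["distance_bp"], slope, lrt, p):
            out_rows.append((probe, snp, int(d), float(s), float(l), float(pv)))
    out = pd.DataFrame(
        out_rows, columns=["probe", "snp", "distance_bp", "slope", "lrt_stat", "p"]
    )
    return out.sort_values(["probe", "p"], kind="mergesort").reset_index(drop=True)


@dataclass
class PermFdrResult:
    """Permutation-FDR threshold and its supporting per-replicate summaries."""

    threshold_p: float | None
    n_perm: int
    target: float
    observed_min_p: pd.Series
    perm_min_p: list[pd.Series] = field(default_factory=list)
    realized_false_rate: float | None = None
    estimator: str = "ratio"

    @property
    def n_significant(self) -> int:
        if self.threshold_p is None:
            return 0
        return int((self.observed_min_p <= self.threshold_p).sum())

    def significant_records(self, scan: pd.DataFrame) -> pd.DataFrame:
        """Flag scan records at the permutation threshold (p <= threshold)."""
        scan = scan.copy()
        if self.threshold_p is None:
            scan["significant"] = False
        else:
            scan["significant"] = scan["p"] <= self.threshold_p
        return scan


def permutation_fdr(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    dosages: pd.DataFrame,
    snp_meta: pd.DataFrame,
    window_bp: int = 100_000,
    n_perm: int = 10,
    target: float = 0.05,
    seed: int | None = None,
    estimator: str = "ratio",
    pairs: pd.DataFrame | None = None,
    observed_scan: pd.DataFrame | None = None,
) -> PermFdrResult:
    """Permutation-based FDR threshold for the cis scan.

    Each replicate applies one random permutation of sample labels to the
    whole genotype matrix (jointly across SNPs, preserving LD and the
    methylation correlation structure), re-runs the cis scan and records
    the minimum p per probe.  With ``estimator='ratio'`` the empirical
    false rate at a candidate threshold t is

        mean over replicates of #{probes with permuted min-p <= t}
        -----------------------------------------------------------
        #{probes with observed min-p <= t}

    (0/0 -> 0) and the threshold is the largest observed min-p with false
    rate < ``target``.  ``estimator='perm_fraction'`` instead requires the
    mean permuted-positive *proportion of probes* to stay below ``target``.
    When no candidate threshold qualifies the threshold is None.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if estimator not in ("ratio", "perm_fraction"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if pairs is None:
        pairs = cis_pairs(manifest, snp_meta, window_bp)
    if observed_scan is None:
        observed_scan = cis_scan(betas, manifest, dosages, snp_meta, window_bp, pairs=pairs)
    if observed_scan.empty:
        return PermFdrResult(None, n_perm, target, pd.Series(dtype=float), [], None, estimator)
    obs_min = observed_scan.groupby("probe")["p"].min()

    rng = np.random.default_rng(seed)
    perm_mins: list[pd.Series] = []
    n = len(betas)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dos_perm = pd.DataFrame(
            dosages.to_numpy()[perm], index=dosages.index, columns=dosages.columns
        )
        scan_p = cis_scan(betas, manifest, dos_perm, snp_meta, window_bp, pairs=pairs)
        perm_mins.append(scan_p.groupby("probe")["p"].min())

    candidates = np.sort(obs_min.unique())
    obs_sorted = np.sort(obs_min.to_numpy())
    perm_sorted = [np.sort(pm.to_numpy()) for pm in perm_mins]
    n_probes = len(obs_min)
    threshold = None
    realized = None
    for t in candidates[::-1]:  # largest qualifying t
        r = int(np.searchsorted(obs_sorted, t, side="right"))
        v = float(np.mean([np.searchsorted(ps, t, side="right") for ps in perm_sorted]))
        if estimator == "ratio":
            rate = 0.0 if r == 0 and v == 0 else (v / r if r > 0 else np.inf)
        else:
            rate = v / n_probes
        if rate < target:
            threshold = float(t)
            realized = rate
            break
    return PermFdrResult(
        threshold_p=threshold,
        n_perm=n_perm,
        target=target,
        observed_min_p=obs_min,
        perm_min_p=perm_mins,
        realized_false_rate=realized,
        estimator=estimator,
    )
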