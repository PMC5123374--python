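"""Continuous-trait EWAS: per-CpG linear models with LRT p-values and q-value FDR.

Each oxidative-stress marker is scanned separately against methylation beta
values.  The per-probe model is

    beta ~ marker + age + sex + batch + conversion + plate + cell fractions

fitted by Gaussian maximum likelihood; the marker effect is tested with
-2 log(likelihood ratio) against chi-square(1).  False discovery rates are
attached per trait with Storey q-values; Bonferroni flags use the number of
probes actually tested.  Markers flagged ``ln`` (oxLDL, OLAB) are
log-transformed before modelling; all others enter raw.

BMI sensitivity models are gated: only markers associated with BMI in a
sex-adjusted regression (nominal p < 0.01) are refit with BMI added, and
the relative change in the marker slope is reported per probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from oxewas._lrt import (
    CollinearDesignError,
    ConstantExposureError,
    LinearLrtResult,
    gaussian_lrt,
)

__all__ = [
    "PhenotypeSpec",
    "MARKER_PANEL",
    "build_design",
    "fit_linear_lrt",
    "ewas_scan",
    "storey_qvalues",
    "bmi_sensitivity",
    "BmiSensitivityResult",
]


@dataclass(frozen=True)
class PhenotypeSpec:
    """One oxidative marker: id, pre-model transform and units."""

    marker: str
    transform: str = "none"  # 'none' | 'ln'
    units: str = ""

    def __post_init__(self) -> None:
        if self.transform not in ("none", "ln"):
            raise ValueError(f"unknown transform {self.transform!r}")

    def apply_transform(self, values: pd.Series) -> pd.Series:
        if self.transform == "ln":
            if (values.dropna() <= 0).any():
                raise ValueError(f"ln transform of non-positive {self.marker} values")
            return np.log(values)
        return values


#: The ten-marker oxidative stress panel.  Only oxLDL and OLAB are modelled
#: on the log scale.
MARKER_PANEL: tuple[PhenotypeSpec, ...] = (
    PhenotypeSpec("TGSH", "none", "ug/ml"),
    PhenotypeSpec("GSH", "none", "ug/ml"),
    PhenotypeSpec("GSSG", "none", "ug/ml"),
    PhenotypeSpec("GSSG/GSH", "none", "ratio"),
    PhenotypeSpec("HCY", "none", "umol/l"),
    PhenotypeSpec("oxLDL", "ln", "U/l"),
    PhenotypeSpec("CD", "none", "umol/l"),
    PhenotypeSpec("BCD-LDL", "none", "umol/l"),
    PhenotypeSpec("OLAB", "ln", "U/l"),
    PhenotypeSpec("TAOC", "none", "%"),
)


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand a covariate frame into a numeric design (no intercept column).

    Object/categorical columns are one-hot encoded with lexicographically
    first level as reference; numeric columns pass through.  Column order is
    deterministic (input order, indicator levels sorted).
    """
    pieces = []
    for col in covariates.columns:
        s = covariates[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            levels = sorted(pd.unique(s.dropna().astype(str)))
            for level in levels[1:]:
                pieces.append((f"{col}[{level}]", (s.astype(str) == level).astype(float)))
        else:
            pieces.append((col, s.astype(float)))
    if not pieces:
        return pd.DataFrame(index=covariates.index)
    return pd.DataFrame({name: vals for name, vals in pieces}, index=covariates.index)


def fit_linear_lrt(
    response: pd.Series | np.ndarray,
    exposure: pd.Series | np.ndarray,
    covariates: pd.DataFrame | None = None,
) -> LinearLrtResult:
    """Gaussian LRT of an exposure effect on a response, complete cases only.

    Categorical covariates are expanded via :func:`build_design`.  Raises on
    rank-deficient designs (naming the collinear columns) and on exposures
    that are constant after the complete-case restriction.
    """
    y = pd.Series(np.asarray(response, dtype=float))
    x = pd.Series(np.asarray(exposure, dtype=float), index=y.index)
    if covariates is not None:
        design = build_design(covariates.reset_index(drop=True))
        mask = (~y.isna()) & (~x.isna()) & (~design.isna().any(axis=1))
        X = design.loc[mask].to_numpy()
        names = list(design.columns)
    else:
        mask = (~y.isna()) & (~x.isna())
        X = None
        names = None
    return gaussian_lrt(y[mask].to_numpy(), x[mask].to_numpy(), X, names)


def storey_qvalues(
    p: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with a cubic-smoother pi0 estimate.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed on the grid
    (default 0.05..0.95 step 0.05), smoothed with a cubic polynomial and
    extrapolated to the grid maximum; the estimate is clipped to (0, 1]
    (floored at 1/m).  ``q_i = min over p_j >= p_i of pi0 * m * p_j / rank_j``
    is monotone non-decreasing in p.  Forcing ``pi0=1`` reproduces
    Benjamini-Hochberg adjusted p-values exactly.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        if lambda_grid is None:
            lambda_grid = np.arange(0.05, 0.951, 0.05)
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        pi0_raw = np.array([(p > lam).mean() / (1.0 - lam) for lam in lambda_grid])
        if m < 100:
            # small scans carry too little tail information for the smoother
            pi0_hat = 1.0
        else:
            coef = np.polyfit(lambda_grid, pi0_raw, deg=3)
            pi0_hat = float(np.polyval(coef, lambda_grid.max()))
        pi0 = min(max(pi0_hat, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def ewas_scan(
    betas: pd.DataFrame,
    phenotype: pd.Series,
    spec: PhenotypeSpec,
    covariates: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
    bonferroni_alpha: float = 0.05,
) -> pd.DataFrame:
    """Scan every probe against one marker; returns one record per probe.

    ``betas`` is samples x probes; sample ids must align with the phenotype
    and covariate indexes.  Complete cases for the trait (non-missing marker
    and covariates) are used for every probe, matching a per-trait
    complete-case analysis.  Columns of the result: probe, marker, slope
    (beta change per unit transformed marker), lrt_stat, p, q, fdr_sig,
    bonferroni_sig, n_used.

    The scan uses the Frisch-Waugh decomposition (residualize the betas and
    the marker on the covariates once), which is algebraically identical to
    the per-probe :func:`fit_linear_lrt`.
    """
    if not betas.index.equals(phenotype.index):
        raise ValueError("sample ids of betas and phenotype are misaligned")
    pheno = spec.apply_transform(phenotype)
    if covariates is not None:
        if not betas.index.equals(covariates.index):
            raise ValueError("sample ids of betas and covariates are misaligned")
        design = build_design(covariates)
        mask = (~pheno.isna()) & (~design.isna().any(axis=1))
        X = design.loc[mask].to_numpy()
    else:
        mask = ~pheno.isna()
        X = np.empty((int(mask.sum()), 0))
    n = int(mask.sum())
    Y = betas.loc[mask].to_numpy(dtype=float)
    x = pheno[mask].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ConstantExposureError(f"{spec.marker} is constant among complete cases")

    X_full = np.column_stack([np.ones(n), X])
    Q, _ = np.linalg.qr(X_full)
    Yr = Y - Q @ (Q.T @ Y)
    xr = x - Q @ (Q.T @ x)
    xtx = float(xr @ xr)
    xty = xr @ Yr
    rss0 = np.einsum("ij,ij->j", Yr, Yr)
    rss1 = rss0 - xty**2 / xtx
    slope = xty / xtx
    with np.errstate(divide="ignore", invalid="ignore"):
        lrt = np.where(rss1 > 0, n * np.log(rss0 / rss1), np.inf)
    lrt = np.maximum(lrt, 0.0)
    p = stats.chi2.sf(lrt, df=1)
    q = storey_qvalues(p)
    m = betas.shape[1]
    out = pd.DataFrame(
        {
            "probe": betas.columns,
            "marker": spec.marker,
            "slope": slope,
            "lrt_stat": lrt,
            "p": p,
            "q": q,
            "fdr_sig": q < fdr_alpha,
            "bonferroni_sig": p < bonferroni_alpha / m,
            "n_used": n,
        }
    )
    return out


@dataclass
class BmiSensitivityResult:
    """Gate decision plus paired primary/secondary fits for one marker."""

    marker: str
    gate_p: float
    gated_in: bool
    table: pd.DataFrame = field(default_factory=pd.DataFrame)


def bmi_sensitivity(
    phenotype: pd.Series,
    spec: PhenotypeSpec,
    betas: pd.DataFrame,
    covariates: pd.DataFrame,
    sex: pd.Series,
    bmi: pd.Series,
    probes: list[str] | None = None,
    gate_p: float = 0.01,
) -> BmiSensitivityResult:
    """BMI-confounding check for one marker.

    The gate is the BMI term of a sex-adjusted ``marker ~ BMI + sex``
    regression; only when its nominal p < ``gate_p`` are the listed probes
    refit with BMI added to the covariates.  The table pairs the primary and
    secondary slopes and their relative change ``(slope2 - slope1)/slope1``.
    """
    pheno = spec.apply_transform(phenotype)
    gate = fit_linear_lrt(pheno, bmi, covariates=pd.DataFrame({"sex": sex}))
    gated_in = gate.p < gate_p
    if not gated_in or not probes:
        return BmiSensitivityResult(spec.marker, gate.p, gated_in)
    if bmi.isna().all():
        raise ValueError("BMI required for secondary models but entirely missing")
    cov2 = covariates.copy()
    cov2["BMI"] = bmi
    rows = []
    for probe in probes:
        fit1 = fit_linear_lrt(betas[probe], pheno, covariates=covariates)
        fit2 = fit_linear_lrt(betas[probe], pheno, covariates=cov2)
        rel = (fit2.slope - fit1.slope) / fit1.slope if fit1.slope != 0 else np.nan
        rows.append((probe, fit1.slope, fit2.slope, rel, fit1.p, fit2.p))
    table = pd.DataFrame(
        rows,
        columns=["probe", "slope_primary", "slope_secondary", "rel_change", "p_primary", "p_secondary"],
    )
    return BmiSensitivityResult(spec.marker, gate.p, gated_in, table)
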