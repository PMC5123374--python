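"""Incident-disease association of candidate CpGs with permutation significance.

Candidate probes (typically those associated with an oxidative marker) are
tested against incident type 2 diabetes and cardiovascular disease flags
with logistic regression:

    disease ~ standardised methylation + age + sex + cell fractions + technical covariates

The methylation term is tested by LRT; effect sizes are reported as the
odds ratio per standard-deviation *decrement* of methylation, ``exp(-b)``,
so an OR above 1 means hypomethylation carries risk.  Significance is
assessed by permuting case/control labels (default 10,000 permutations,
full model refit per permutation) and flagged at permutation p < 0.01.
Secondary models add BMI and smoking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from oxewas._lrt import (
    PerfectSeparationError,
    distinct_label_arrangements,
    logistic_deviance_batch,
    logistic_lrt,
)
from oxewas.ewas import build_design

__all__ = [
    "PerfectSeparationError",
    "DiseaseAssocRecord",
    "standardize_methylation",
    "fit_logistic_lrt",
    "permutation_test_binary",
    "incident_screen",
    "attach_context",
]


@dataclass
class DiseaseAssocRecord:
    probe: str
    outcome: str
    or_per_sd_decrement: float
    ci95: tuple[float, float]
    nominal_p: float
    perm_p: float | None
    model: str  # 'primary' | 'secondary'
    n_used: int
    lrt_stat: float
    separated: bool = False


def standardize_methylation(beta_column: pd.Series | np.ndarray) -> np.ndarray:
    """Z-score a methylation column over the analysis samples (ddof=1)."""
    x = np.asarray(beta_column, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("methylation column is constant; cannot standardise")
    return (x - x.mean()) / sd


def fit_logistic_lrt(
    outcome: pd.Series | np.ndarray,
    z_meth: np.ndarray,
    covariates: pd.DataFrame | None = None,
    probe: str = "",
    outcome_id: str = "",
    model: str = "primary",
) -> DiseaseAssocRecord:
    """Logistic LRT of standardised methylation on a binary outcome.

    The nominal p comes from chi-square(1) on the deviance drop; the OR per
    SD decrement is ``exp(-coef)`` with a Wald 95% CI on the same scale.
    Perfect separation raises :class:`PerfectSeparationError`.
    """
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = None
    names = None
    if covariates is not None:
        design = build_design(covariates)
        X = design.to_numpy(dtype=float)
        names = list(design.columns)
    res = logistic_lrt(y, z_meth, X, names)
    or_dec = math.exp(-res.coef)
    zcrit = stats.norm.ppf(0.975)
    lo = math.exp(-res.coef - zcrit * res.se)
    hi = math.exp(-res.coef + zcrit * res.se)
    return DiseaseAssocRecord(
        probe=probe,
        outcome=outcome_id,
        or_per_sd_decrement=or_dec,
        ci95=(min(lo, hi), max(lo, hi)),
        nominal_p=res.p,
        perm_p=None,
        model=model,
        n_used=res.n_used,
        lrt_stat=res.lrt_stat,
    )


def permutation_test_binary(
    outcome: pd.Series | np.ndarray,
    z_meth: np.ndarray,
    covariates: pd.DataFrame | None = None,
    B: int = 10000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> float:
    """Case/control permutation p for the methylation term.

    The statistic is the LRT of the methylation term, with covariates refit
    under each permuted label vector.  In the default sampled mode the
    +1-smoothed p ``(1 + #{perm stat >= observed}) / (B + 1)`` is returned,
    so p is bounded below by 1/(B+1).  In ``exhaustive`` mode all distinct
    label arrangements with the observed case count are enumerated and
    ``p = #{stat >= observed} / N`` (the observed arrangement is one of the
    N, so p >= 1/N).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(outcome, dtype=float)
    n = y.shape[0]
    k = int(y.sum())
    if k == 0 or k == n:
        raise ValueError("outcome is all-case or all-control")
    if covariates is not None:
        design = build_design(covariates).to_numpy(dtype=float)
        X0 = np.column_stack([np.ones(n), design])
    else:
        X0 = np.ones((n, 1))
    X1 = np.column_stack([X0, np.asarray(z_meth, dtype=float)])

    dev0_obs = logistic_deviance_batch(X0, y[:, None])[0]
    dev1_obs = logistic_deviance_batch(X1, y[:, None])[0]
    observed = max(dev0_obs - dev1_obs, 0.0)

    if exhaustive:
        Y = distinct_label_arrangements(n, k)
        stats_perm = _batched_lrt(X0, X1, Y)
        return float((stats_perm >= observed - 1e-12).sum() / Y.shape[1])

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 2000
    done = 0
    while done < B:
        b = min(chunk, B - done)
        Y = np.empty((n, b))
        for j in range(b):
            Y[:, j] = rng.permutation(y)
        stats_perm = _batched_lrt(X0, X1, Y)
        count += int((stats_perm >= observed - 1e-12).sum())
        done += b
    return (1 + count) / (B + 1)


def _batched_lrt(X0: np.ndarray, X1: np.ndarray, Y: np.ndarray) -> np.ndarray:
    dev0 = logistic_deviance_batch(X0, Y)
    dev1 = logistic_deviance_batch(X1, Y)
    return np.maximum(dev0 - dev1, 0.0)


def attach_context(
    screen: pd.DataFrame,
    ewas: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    fdr_alpha: float = 0.05,
) -> pd.DataFrame:
    """Join gene-feature context and linked oxidative markers onto a screen.

    Adds a ``marker_assoc`` column listing, per probe, the FDR-significant
    oxidative markers with the direction of the EWAS slope (``GSH(+)``
    means methylation rises with the marker), and — when an annotation
    table is given — the probe's collapsed gene feature and island context.
    """
    sig = ewas[ewas["q"] < fdr_alpha]
    links = sig.groupby("probe").apply(
        lambda g: ";".join(
            f"{m}({'+' if s > 0 else '-'})" for m, s in zip(g["marker"], g["slope"])
        ),
        include_groups=False,
    )
    out = screen.copy()
    out["marker_assoc"] = out["probe"].map(links).fillna("")
    if annotation is not None:
        out["feature"] = out["probe"].map(annotation["collapsed_feature"])
        out["island_context"] = out["probe"].map(annotation["island_context"])
    return out


def incident_screen(
    candidates: list[str],
    outcomes: pd.DataFrame,
    betas: pd.DataFrame,
    covariates: pd.DataFrame,
    secondary_covariates: pd.DataFrame | None = None,
    B: int = 10000,
    seed: int | None = None,
    perm_alpha: float = 0.01,
) -> pd.DataFrame:
    """Primary and secondary logistic screens of candidate CpGs vs outcomes.

    ``outcomes`` is samples x outcome-ids (0/1).  Secondary models add the
    ``secondary_covariates`` columns (BMI, smoking).  Probes whose logistic
    fit separates are reported with NaN estimates and ``separated=True``
    rather than silently dropped.  ``perm_sig`` flags permutation p <
    ``perm_alpha`` (primary model only).
    """
    missing = set(candidates) - set(betas.columns)
    if missing:
        raise KeyError(f"candidate probes not in beta matrix: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    rows = []
    for outcome_id in outcomes.columns:
        y = outcomes[outcome_id]
        for probe in candidates:
            z = standardize_methylation(betas[probe])
            for model, cov in (("primary", covariates), ("secondary", secondary_covariates)):
                if model == "secondary" and secondary_covariates is None:
                    continue
                if model == "secondary":
                    cov = pd.concat([covariates, secondary_covariates], axis=1)
                try:
                    rec = fit_logistic_lrt(y, z, cov, probe, outcome_id, model)
                except PerfectSeparationError:
                    rows.append(
                        dict(
                            probe=probe, outcome=outcome_id, model=model,
                            or_per_sd_decrement=np.nan, ci_low=np.nan, ci_high=np.nan,
                            nominal_p=np.nan, perm_p=np.nan, perm_sig=False,
                            n_used=len(y), separated=True,
                        )
                    )
                    continue
                perm_p = np.nan
                if model == "primary":
                    perm_p = permutation_test_binary(
                        y, z, cov, B=B, seed=int(rng.integers(2**31 - 1))
                    )
                rows.append(
                    dict(
                        probe=probe, outcome=outcome_id, model=model,
                        or_per_sd_decrement=rec.or_per_sd_decrement,
                        ci_low=rec.ci95[0], ci_high=rec.ci95[1],
                        nominal_p=rec.nominal_p, perm_p=perm_p,
                        perm_sig=bool(perm_p < perm_alpha) if not np.isnan(perm_p) else False,
                        n_used=rec.n_used, separated=False,
                    )
                )
    return pd.DataFrame(rows)
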