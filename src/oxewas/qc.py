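"""Sample/probe quality control and normalization for array methylation data.

The QC conventions implemented here follow common practice for the 450K
platform: samples are dropped when fewer than 98.5% of their probes reach a
detection p-value of 0.01, when leukocyte counts exceed 10x10^9 cells/L, or
when bisulphite conversion efficiency falls below a user threshold; probes
are dropped when multi-mapping, non-autosomal, within 10 bp of a common SNP
(MAF > 5%), or overlapping a copy-number variant.  Signal intensities are
quantile normalised separately for each Infinium design type (I vs II) and
channel (methylated vs unmethylated), and beta values are computed as
``M / (M + U + offset)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "IntensityData",
    "sample_qc",
    "probe_filter",
    "quantile_normalize_by_type",
    "compute_beta",
]


@dataclass
class IntensityData:
    """Methylated/unmethylated signals with detection p-values.

    All three frames are samples x probes with identical indexes;
    ``design_type`` labels each probe 'I' or 'II'.
    """

    methylated: pd.DataFrame
    unmethylated: pd.DataFrame
    detection_p: pd.DataFrame
    design_type: pd.Series

    def __post_init__(self) -> None:
        for name in ("unmethylated", "detection_p"):
            frame = getattr(self, name)
            if not frame.index.equals(self.methylated.index) or not frame.columns.equals(
                self.methylated.columns
            ):
                raise ValueError(f"{name} frame is not aligned with the methylated frame")
        if not self.design_type.index.equals(self.methylated.columns):
            raise ValueError("design_type index must equal the probe columns")
        if (self.methylated.values < 0).any() or (self.unmethylated.values < 0).any():
            raise ValueError("signal intensities must be nonnegative")
        dp = self.detection_p.values
        if (dp < 0).any() or (dp > 1).any():
            raise ValueError("detection p-values must lie in [0, 1]")

    @property
    def samples(self) -> pd.Index:
        return self.methylated.index

    @property
    def probes(self) -> pd.Index:
        return self.methylated.columns


def sample_qc(
    intensities: IntensityData,
    meta: pd.DataFrame,
    pass_rate_min: float = 0.985,
    detection_alpha: float = 0.01,
    leukocyte_max: float = 10.0,
    conversion_min: float | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Apply sample-level exclusions; return kept ids and an exclusion table.

    A sample is excluded iff it fails at least one rule; the exclusion table
    lists every failed rule (columns: sample, rule, value, threshold).
    ``conversion_min`` is an optional floor on the per-sample bisulphite
    conversion efficiency mean; when None the rule is skipped.
    """
    missing = intensities.samples.difference(meta.index)
    if len(missing):
        raise KeyError(f"metadata missing for samples: {list(missing)[:5]}")

    rows = []
    pass_rate = (intensities.detection_p <= detection_alpha).mean(axis=1)
    for sample in intensities.samples:
        pr = float(pass_rate.loc[sample])
        if pr < pass_rate_min:
            rows.append((sample, "pass_rate", pr, pass_rate_min))
        leuk = meta.loc[sample].get("leukocyte_count")
        if leuk is not None and not pd.isna(leuk) and leuk > leukocyte_max:
            rows.append((sample, "leukocytes", float(leuk), leukocyte_max))
        if conversion_min is not None:
            conv = meta.loc[sample].get("bisulphite_conversion_mean")
            if conv is not None and not pd.isna(conv) and conv < conversion_min:
                rows.append((sample, "conversion", float(conv), conversion_min))
    exclusions = pd.DataFrame(rows, columns=["sample", "rule", "value", "threshold"])
    excluded = set(exclusions["sample"])
    kept = [s for s in intensities.samples if s not in excluded]
    return kept, exclusions


def probe_filter(
    manifest: pd.DataFrame,
    snp_window_bp: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Apply probe-level exclusions on a manifest indexed by probe id.

    Expected columns: ``multi_mapping`` (bool), ``autosomal`` (bool),
    ``nearest_common_snp_distance`` (bp to the nearest MAF>5% SNP; NaN when
    none is nearby) and ``overlaps_cnv`` (bool).  A probe is excluded iff it
    is multi-mapping, non-autosomal, has a common SNP within
    ``snp_window_bp`` of the CpG (inclusive), or overlaps a CNV.  The order
    of kept probes is preserved.
    """
    rows = []
    for probe, rec in manifest.iterrows():
        if bool(rec.get("multi_mapping", False)):
            rows.append((probe, "multi_mapping", 1.0, 0.0))
        if not bool(rec.get("autosomal", True)):
            rows.append((probe, "non_autosomal", 1.0, 0.0))
        dist = rec.get("nearest_common_snp_distance")
        if dist is not None and not pd.isna(dist) and dist <= snp_window_bp:
            rows.append((probe, "snp_proximity", float(dist), float(snp_window_bp)))
        if bool(rec.get("overlaps_cnv", False)):
            rows.append((probe, "cnv_overlap", 1.0, 0.0))
    exclusions = pd.DataFrame(rows, columns=["probe", "rule", "value", "threshold"])
    excluded = set(exclusions["probe"])
    kept = [p for p in manifest.index if p not in excluded]
    return kept, exclusions


def _quantile_normalize_block(values: np.ndarray) -> np.ndarray:
    """Quantile normalise samples (rows) to the mean of order statistics.

    Ties receive the average of the tied order-statistic means (average
    ranks interpolated into the common target distribution).
    """
    n, m = values.shape
    if m == 0:
        return values.copy()
    order = np.sort(values, axis=1)
    target = order.mean(axis=0)
    out = np.empty_like(values, dtype=float)
    grid = np.arange(1, m + 1, dtype=float)
    for i in range(n):
        ranks = rankdata(values[i], method="average")
        out[i] = np.interp(ranks, grid, target)
    return out


def quantile_normalize_by_type(intensities: IntensityData) -> IntensityData:
    """Quantile normalise each channel within each probe design type.

    After normalization every sample shares the same empirical distribution
    (the cross-sample mean of order statistics) within each (type, channel)
    block, and within-sample ranks are preserved.  A design type with zero
    probes is skipped.
    """
    if len(intensities.samples) < 2:
        raise ValueError("quantile normalization requires at least two samples")
    meth = intensities.methylated.copy().astype(float)
    unmeth = intensities.unmethylated.copy().astype(float)
    for dtype in ("I", "II"):
        cols = intensities.design_type.index[intensities.design_type == dtype]
        if len(cols) == 0:
            continue
        meth.loc[:, cols] = _quantile_normalize_block(meth.loc[:, cols].values)
        unmeth.loc[:, cols] = _quantile_normalize_block(unmeth.loc[:, cols].values)
    return replace(intensities, methylated=meth, unmethylated=unmeth)


def compute_beta(intensities: IntensityData, offset: float = 100.0) -> pd.DataFrame:
    """Beta values ``M / (M + U + offset)``, elementwise, in [0, 1].

    The offset (default 100, the platform's conventional stabiliser) guards
    against low-intensity probes dominated by noise.
    """
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    m = intensities.methylated.values.astype(float)
    u = intensities.unmethylated.values.astype(float)
    denom = m + u + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, m / denom, 0.0)
    return pd.DataFrame(beta, index=intensities.samples, columns=intensities.probes)
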