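"""Genomic-context annotation of methylation probes and set enrichment.

Probes are assigned a CpG-island context (island / shore / shelf / open sea,
with shores the 2 kb flanks of island borders and shelves the next 2 kb)
and gene-feature labels relative to transcript models (TSS1500, TSS200,
5'UTR, first exon, body, 3'UTR), strand-aware.  Enrichment of an associated
probe set against the array background uses Fisher's exact test per
category, or a random-probe-set permutation for arbitrary binary
annotations.

Coordinates are 1-based inclusive throughout this module; BED input is
converted on ingestion (see :mod:`oxewas.io`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "GENE_FEATURES",
    "fisher_exact_2x2",
    "assign_island_context",
    "assign_gene_features",
    "annotate_probes",
    "context_enrichment",
    "overlap_permutation",
]

GENE_FEATURES = ("TSS1500", "TSS200", "5UTR", "first_exon", "body", "3UTR")
ISLAND_CONTEXTS = ("island", "shore", "shelf", "open_sea")
COLLAPSED_FEATURES = ("promoter", "body", "3UTR", "intergenic")

_PROMOTER_SET = {"TSS1500", "TSS200", "5UTR", "first_exon"}

_lgamma = math.lgamma


def _log_comb(n: int, k: int) -> float:
    return _lgamma(n + 1) - _lgamma(k + 1) - _lgamma(n - k + 1)


def fisher_exact_2x2(a: int, b: int, c: int, d: int, sidedness: str = "two_sided") -> tuple[float, float]:
    """Exact Fisher test of a 2x2 table by hypergeometric enumeration.

    Returns (sample odds ratio ``a*d / (b*c)``, p).  With the row and column
    margins fixed, the table count ``a`` follows a hypergeometric law; the
    one-sided p-values are its tails and the two-sided p sums the
    probabilities of all outcomes no more likely than the observed one
    (with the conventional 1e-7 relative slack against rounding).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table counts must be nonnegative")
    if sidedness not in ("two_sided", "greater", "less"):
        raise ValueError(f"unknown sidedness {sidedness!r}")
    N = a + b + c + d
    r1, c1 = a + b, a + c
    n2 = N - r1
    kmin, kmax = max(0, c1 - n2), min(r1, c1)
    support = np.arange(kmin, kmax + 1)
    logpmf = np.array(
        [_log_comb(c1, k) + _log_comb(N - c1, r1 - k) - _log_comb(N, r1) for k in support]
    )
    pmf = np.exp(logpmf)
    obs = pmf[a - kmin]
    if sidedness == "two_sided":
        p = float(pmf[pmf <= obs * (1.0 + 1e-7)].sum())
    elif sidedness == "greater":
        p = float(pmf[support >= a].sum())
    else:
        p = float(pmf[support <= a].sum())
    if b * c == 0:
        odds = math.nan if a * d == 0 else math.inf
    else:
        odds = (a * d) / (b * c)
    return odds, min(p, 1.0)


def _island_distance(position: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Distance in bp from a position to the nearest island border (0 if inside)."""
    if len(starts) == 0:
        return np.iinfo(np.int64).max
    inside = (starts <= position) & (position <= ends)
    if inside.any():
        return 0
    d_left = np.where(position < starts, starts - position, np.iinfo(np.int64).max)
    d_right = np.where(position > ends, position - ends, np.iinfo(np.int64).max)
    return int(min(d_left.min(), d_right.min()))


def assign_island_context(
    position: int,
    chromosome: str,
    islands: pd.DataFrame,
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> str:
    """Classify a position as island / shore / shelf / open_sea.

    ``islands`` has columns chrom, start, end in 1-based inclusive
    coordinates.  Shores are positions within ``shore_bp`` of an island
    border (inclusive), shelves within ``shelf_bp``; islands take precedence
    over shores over shelves.  Distances are measured to the nearest border
    on the same chromosome only; a chromosome absent from the island table
    yields open_sea with a logged warning.
    """
    chrom_islands = islands[islands["chrom"] == chromosome]
    if chrom_islands.empty:
        logger.warning("chromosome %s has no islands; classifying as open_sea", chromosome)
        return "open_sea"
    d = _island_distance(
        position, chrom_islands["start"].to_numpy(), chrom_islands["end"].to_numpy()
    )
    if d == 0:
        return "island"
    if d <= shore_bp:
        return "shore"
    if d <= shelf_bp:
        return "shelf"
    return "open_sea"


def _interval_contains(position: int, interval) -> bool:
    if interval is None:
        return False
    lo, hi = interval
    if pd.isna(lo) or pd.isna(hi):
        return False
    return lo <= position <= hi


def assign_gene_features(
    position: int,
    chromosome: str,
    transcripts: pd.DataFrame,
) -> tuple[set[str], str]:
    """Gene-feature labels of a position against a transcript table.

    ``transcripts`` columns: chrom, strand (+/-), tss, tes, exon1_start,
    exon1_end, utr5_start, utr5_end, utr3_start, utr3_end (NaN when absent).
    Upstream windows are strand-aware: TSS200 covers 1..200 bp upstream of
    the TSS and TSS1500 covers 201..1500 bp upstream.  The gene body is the
    transcript span between TSS and TES not claimed by the first exon or
    either UTR.  Labels accumulate over every overlapping transcript; an
    empty set collapses to ``intergenic``, otherwise precedence is
    promoter (TSS1500/TSS200/5UTR/first exon) > body > 3UTR.
    """
    features: set[str] = set()
    for _, tx in transcripts[transcripts["chrom"] == chromosome].iterrows():
        tss = int(tx["tss"])
        tes = int(tx["tes"])
        if tx["strand"] == "+":
            if tss > tes:
                raise ValueError(f"malformed + strand transcript: TSS {tss} > TES {tes}")
            upstream = tss - position  # >0 means upstream
        else:
            if tss < tes:
                raise ValueError(f"malformed - strand transcript: TSS {tss} < TES {tes}")
            upstream = position - tss
        if 1 <= upstream <= 200:
            features.add("TSS200")
        elif 201 <= upstream <= 1500:
            features.add("TSS1500")
        lo, hi = min(tss, tes), max(tss, tes)
        if lo <= position <= hi:
            in_sub = False
            for colpair, label in (
                (("utr5_start", "utr5_end"), "5UTR"),
                (("exon1_start", "exon1_end"), "first_exon"),
                (("utr3_start", "utr3_end"), "3UTR"),
            ):
                iv = (tx.get(colpair[0]), tx.get(colpair[1]))
                if _interval_contains(position, iv):
                    features.add(label)
                    in_sub = True
            if not in_sub:
                features.add("body")
    if not features:
        return features, "intergenic"
    if features & _PROMOTER_SET:
        collapsed = "promoter"
    elif "body" in features:
        collapsed = "body"
    else:
        collapsed = "3UTR"
    return features, collapsed


def annotate_probes(
    manifest: pd.DataFrame,
    islands: pd.DataFrame,
    transcripts: pd.DataFrame,
    shore_bp: int = 2000,
    shelf_bp: int = 4000,
) -> pd.DataFrame:
    """Annotate every manifest probe; returns a frame indexed by probe id.

    Columns: island_context, gene_features (semicolon-joined, sorted),
    collapsed_feature.
    """
    records = {}
    for probe, rec in manifest.iterrows():
        ctx = assign_island_context(
            int(rec["position"]), rec["chromosome"], islands, shore_bp, shelf_bp
        )
        feats, collapsed = assign_gene_features(
            int(rec["position"]), rec["chromosome"], transcripts
        )
        records[probe] = (ctx, ";".join(sorted(feats)), collapsed)
    out = pd.DataFrame.from_dict(
        records, orient="index", columns=["island_context", "gene_features", "collapsed_feature"]
    )
    out.index.name = "probe"
    return out


def context_enrichment(
    assoc_probes: set[str],
    background: set[str],
    labels: pd.DataFrame,
    category_axis: str = "island_context",
    sidedness: str = "two_sided",
) -> pd.DataFrame:
    """Per-category Fisher exact enrichment of an associated probe set.

    For each category level of ``category_axis`` the 2x2 table is
    ``[[assoc & cat, assoc & ~cat], [~assoc & cat, ~assoc & ~cat]]``; the
    odds ratio is the sample (conditional) odds ratio a*d / (b*c) and the
    p-value is the exact hypergeometric Fisher p with the requested
    sidedness ('two_sided', 'greater' for over-representation, 'less').
    """
    if not assoc_probes:
        raise ValueError("association set is empty")
    extra = assoc_probes - background
    if extra:
        raise ValueError(f"association probes missing from background: {sorted(extra)[:5]}")
    axis = labels.loc[sorted(background), category_axis]
    rows = []
    order = ISLAND_CONTEXTS if category_axis == "island_context" else COLLAPSED_FEATURES
    categories = [c for c in order if (axis == c).any()] + sorted(
        set(axis.unique()) - set(order)
    )
    assoc_mask = axis.index.isin(assoc_probes)
    for cat in categories:
        cat_mask = (axis == cat).to_numpy()
        a = int((assoc_mask & cat_mask).sum())
        b = int((assoc_mask & ~cat_mask).sum())
        c = int((~assoc_mask & cat_mask).sum())
        d = int((~assoc_mask & ~cat_mask).sum())
        odds, p = fisher_exact_2x2(a, b, c, d, sidedness)
        rows.append((cat, a, b, c, d, odds, p))
    return pd.DataFrame(
        rows, columns=["category", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("category")


def overlap_permutation(
    assoc_probes: set[str],
    annotation: pd.Series,
    n_random: int = 1000,
    seed: int | None = None,
) -> tuple[float, int, np.ndarray]:
    """Permutation p-value for overlap of a probe set with a binary annotation.

    ``annotation`` is a boolean series over the whole background.  Draws
    ``n_random`` random same-size probe sets from the background and reports
    the +1-smoothed permutation p ``(1 + #{random >= observed}) / (n_random + 1)``
    together with the observed overlap and the null draws.
    """
    background = annotation.index
    missing = assoc_probes - set(background)
    if missing:
        raise KeyError(f"annotation undefined for probes: {sorted(missing)[:5]}")
    k = len(assoc_probes)
    if k > len(background):
        raise ValueError("association set larger than background")
    flags = annotation.to_numpy(dtype=bool)
    observed = int(annotation.loc[sorted(assoc_probes)].sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_random, dtype=int)
    n_bg = len(background)
    for i in range(n_random):
        idx = rng.choice(n_bg, size=k, replace=False)
        null[i] = int(flags[idx].sum())
    p = (1 + int((null >= observed).sum())) / (n_random + 1)
    return p, observed, null
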