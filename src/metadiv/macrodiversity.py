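"""Abundance normalization and community (alpha/beta) diversity.

Raw truncated-mean abundances from pre-processing are proportionally
scaled to the largest library: every sample's column is multiplied by
max(library size) / library size, so the deepest library keeps factor 1
and a library with 1.5 M reads against a 2 M max is scaled by ~1.33.
Within-sample abundance ratios are preserved exactly.

Alpha diversity: richness, Chao1, ACE, Shannon's H (natural log),
Simpson (1 - sum p^2), inverse Simpson, Fisher's alpha and Pielou's J.
The count-based estimators (Chao1/ACE/Fisher) require integer data and
are fed normalized abundances rounded to the nearest integer with a
floor of 1 for detected populations — an explicit stand-in for feeding
vegan-style estimators scaled coverages.

Beta diversity: Jaccard on presence/absence, Bray-Curtis on normalized
abundances, and Euclidean distance of centered log-ratio (CLR)
transformed compositions. Zeros receive a pseudocount of 1e-6 times the
smallest nonzero abundance before the CLR.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio.diversity.alpha import ace as _skbio_ace

__all__ = [
    "normalize",
    "alpha_diversity",
    "alpha_diversity_table",
    "beta_diversity",
    "chao1",
    "fisher_alpha",
]


def normalize(
    raw: pd.DataFrame, library_sizes: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """Scale each sample column to the largest library.

    Parameters
    ----------
    raw
        genomes x samples matrix of raw abundances (zero when undetected).
    library_sizes
        reads or bp per sample; must cover every sample that has detections.

    Returns
    -------
    (normalized matrix, per-sample scale factors)
    """
    factors = {}
    sizes = library_sizes.reindex(raw.columns)
    has_detection = (raw > 0).any(axis=0)
    missing = [
        s for s in raw.columns
        if has_detection[s] and (s not in library_sizes.index or not np.isfinite(sizes[s]) or sizes[s] <= 0)
    ]
    if missing:
        raise ValueError(f"missing or invalid library size for sample(s) with detections: {missing}")
    max_size = float(sizes.max())
    for s in raw.columns:
        factors[s] = max_size / float(sizes[s]) if np.isfinite(sizes[s]) and sizes[s] > 0 else 1.0
    factors = pd.Series(factors, name="scale_factor")
    return raw.mul(factors, axis=1), factors


def chao1(counts: np.ndarray) -> float:
    """Classical Chao1: S + F1^2/(2 F2), or S + F1(F1-1)/2 when F2 = 0."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    s_obs = counts.size
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def fisher_alpha(counts: np.ndarray, rtol: float = 1e-9) -> float:
    """Fisher's alpha solved from S = alpha * ln(1 + N/alpha) by bisection."""
    counts = np.asarray(counts)
    counts = counts[counts > 0]
    s = counts.size
    n = float(counts.sum())
    if s == 0 or n <= 0:
        return math.nan
    if s >= n:  # all singletons: no finite root
        return math.nan

    def f(a: float) -> float:
        return a * math.log1p(n / a) - s

    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return math.nan
    while (hi - lo) > rtol * hi:
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _rounded_counts(values: np.ndarray) -> np.ndarray:
    """Integer counts for estimators: round, floor 1 for detected entries."""
    pos = values[values > 0]
    return np.maximum(np.rint(pos), 1).astype(np.int64)


def alpha_diversity(sample: pd.Series | np.ndarray) -> dict[str, float]:
    """Alpha-diversity record for one sample's normalized abundances.

    Pielou's J is undefined (NaN) for a single-population community.
    """
    values = np.asarray(sample, dtype=float)
    values = np.where(values > 0, values, 0.0)
    total = values.sum()
    richness = int((values > 0).sum())
    if richness == 0 or total <= 0:
        return {k: math.nan for k in (
            "richness", "chao1", "ace", "shannon_H", "simpson",
            "inv_simpson", "fisher_alpha", "pielou_J")} | {"richness": 0}
    p = values[values > 0] / total
    shannon = float(-(p * np.log(p)).sum())
    sum_p2 = float((p * p).sum())
    counts = _rounded_counts(values)
    try:
        ace_val = float(_skbio_ace(counts))
    except Exception:
        ace_val = math.nan
    return {
        "richness": richness,
        "chao1": chao1(counts),
        "ace": ace_val,
        "shannon_H": shannon,
        "simpson": 1.0 - sum_p2,
        "inv_simpson": 1.0 / sum_p2,
        "fisher_alpha": fisher_alpha(counts),
        "pielou_J": shannon / math.log(richness) if richness > 1 else math.nan,
    }


def alpha_diversity_table(normalized: pd.DataFrame) -> pd.DataFrame:
    """Alpha-diversity records for every sample column."""
    rows = {s: alpha_diversity(normalized[s]) for s in normalized.columns}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def beta_diversity(normalized: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Jaccard, Bray-Curtis and CLR-Euclidean sample x sample distances.

    Requires at least two samples. A sample with zero detections triggers
    a warning; its presence/absence distances follow the usual set
    conventions (empty vs non-empty Jaccard = 1).
    """
    if normalized.shape[1] < 2:
        raise ValueError("beta diversity requires at least two samples")
    X = normalized.to_numpy(dtype=float).T  # samples x genomes
    samples = list(normalized.columns)
    empty = [s for s, row in zip(samples, X) if not (row > 0).any()]
    if empty:
        warnings.warn(f"sample(s) with zero detections: {empty}")

    presence = X > 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        jac = squareform(pdist(presence, metric="jaccard"))
        bray = squareform(pdist(X, metric="braycurtis"))
    np.nan_to_num(jac, copy=False)  # empty-vs-empty: distance 0

    nonzero = X[X > 0]
    pseudo = 1e-6 * nonzero.min() if nonzero.size else 1e-6
    Xp = np.where(X > 0, X, pseudo)
    logX = np.log(Xp)
    clr = logX - logX.mean(axis=1, keepdims=True)
    eud = squareform(pdist(clr, metric="euclidean"))

    def frame(mat: np.ndarray) -> pd.DataFrame:
        return pd.DataFrame(mat, index=samples, columns=samples)

    return {"jaccard": frame(jac), "bray_curtis": frame(bray), "clr_euclidean": frame(eud)}
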