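"""The fourteen signature summary scores.

A signature score collapses the expression of a signature's genes in one
sample into a single number.  Ten scores are *per-sample* functions of the
gene-value vector alone (mean, median, mode, midrange, midhinge, trimean,
interquartile range, interquartile mean, median absolute deviation, average
absolute deviation).  Four are *cross-sample*: they first place each gene's
expression relative to the other samples (z-score, min-max normalized
cumulative score, ssGSEA's rank-weighted running sum, GSVA's kernel-CDF
random walk) and therefore need the whole matrix.

Conventions pinned here and shared by every quartile-based score: quartiles
use linear interpolation of order statistics (numpy's default, the common
"type 7").  Missing signature genes are intersected away, never imputed.
Scores are computed on the matrix as provided; no automatic log/linear
transformation is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .errors import DataError, InsufficientGenesError, UndefinedScoreError
from .sigio import ExpressionMatrix, GeneSignature, SignatureSet

__all__ = [
    "PER_SAMPLE_METHODS",
    "CROSS_SAMPLE_METHODS",
    "ALL_METHODS",
    "ScoreMatrix",
    "simple_score",
    "zscore_score",
    "ncs_score",
    "ssgsea_score",
    "gsva_score",
    "score_matrix",
]

PER_SAMPLE_METHODS = (
    "mean", "median", "mode", "midrange", "midhinge",
    "trimean", "iqr", "iqm", "mad", "aad",
)
CROSS_SAMPLE_METHODS = ("zscore", "gsva", "ssgsea", "ncs")
ALL_METHODS = PER_SAMPLE_METHODS + CROSS_SAMPLE_METHODS

#: minimum number of gene values each per-sample score needs
MIN_GENES = {m: 1 for m in PER_SAMPLE_METHODS}
MIN_GENES["iqm"] = 4


@dataclass
class ScoreMatrix:
    """Signatures x samples score table for one method.

    Cells that could not be computed (insufficient or unusable genes) are
    NaN, never zero.  ``n_genes_used`` records, per signature, how many
    matrix genes actually entered the score.
    """

    scores: pd.DataFrame
    method: str
    n_genes_used: dict[str, int] = field(default_factory=dict)

    def sample_scores(self, signature: str) -> pd.Series:
        return self.scores.loc[signature]


# ---------------------------------------------------------------------------
# Per-sample scores


def _quartiles(v: np.ndarray) -> tuple[float, float, float]:
    q1, q2, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(q1), float(q2), float(q3)


def half_sample_mode(v: np.ndarray) -> float:
    """Half-sample mode of a continuous sample.

    Repeatedly zoom into the shortest interval containing ceil(n/2) of the
    remaining values; the estimate is the midpoint of the final pair.  Ties
    between equally short candidate windows are broken toward the sample
    median, which makes the estimator deterministic.
    """
    x = np.sort(np.asarray(v, dtype=float))
    med = float(np.median(x))
    while x.size > 2:
        k = int(np.ceil(x.size / 2))
        widths = x[k - 1:] - x[: x.size - k + 1]
        best = np.flatnonzero(widths == widths.min())
        if best.size > 1:
            centers = (x[best + k - 1] + x[best]) / 2.0
            best = best[np.argmin(np.abs(centers - med))]
        else:
            best = best[0]
        x = x[best: best + k]
    return float(x.mean())


def simple_score(values: Sequence[float], method: str) -> float:
    """Apply one per-sample summary score to a vector of gene values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise UndefinedScoreError("empty value vector")
    if not np.all(np.isfinite(v)):
        raise DataError("non-finite values passed to simple_score")
    if method not in PER_SAMPLE_METHODS:
        raise DataError(f"unknown per-sample score {method!r}")
    if v.size < MIN_GENES[method]:
        raise InsufficientGenesError(
            f"{method} needs >= {MIN_GENES[method]} values, got {v.size}"
        )
    if method == "mean":
        return float(v.mean())
    if method == "median":
        return float(np.median(v))
    if method == "mode":
        return half_sample_mode(v)
    if method == "midrange":
        return float((v.min() + v.max()) / 2.0)
    q1, q2, q3 = _quartiles(v)
    if method == "midhinge":
        return (q1 + q3) / 2.0
    if method == "trimean":
        return (q1 + 2.0 * q2 + q3) / 4.0
    if method == "iqr":
        return q3 - q1
    if method == "iqm":
        inner = v[(v >= q1) & (v <= q3)]
        return float(inner.mean())
    if method == "mad":
        return float(np.median(np.abs(v - np.median(v))))
    if method == "aad":
        return float(np.mean(np.abs(v - v.mean())))
    raise AssertionError(method)


# ---------------------------------------------------------------------------
# Cross-sample scores


def _signature_rows(matrix: ExpressionMatrix, sig: GeneSignature) -> np.ndarray:
    idx = matrix.gene_index(sig.genes)
    if idx.size < len(sig.genes):
        warnings.warn(
            f"signature {sig.name!r}: {len(sig.genes) - idx.size} gene(s) "
            "absent from the matrix, dropped",
            stacklevel=3,
        )
    if idx.size == 0:
        raise UndefinedScoreError(
            f"signature {sig.name!r}: no genes present in the matrix"
        )
    return idx


def zscore_score(matrix: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Mean of per-gene z-scores (gene standardized across samples, ddof=1)."""
    if len(matrix.sample_ids) < 2:
        raise DataError("zscore needs at least two samples")
    idx = _signature_rows(matrix, sig)
    sub = matrix.values[idx]
    sd = sub.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.any():
        raise UndefinedScoreError(
            f"signature {sig.name!r}: all signature genes have zero variance"
        )
    if not usable.all():
        warnings.warn(
            f"signature {sig.name!r}: {int((~usable).sum())} zero-variance "
            "gene(s) excluded from z-score",
            stacklevel=2,
        )
    sub = sub[usable]
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[usable][:, None]
    return pd.Series(z.mean(axis=0), index=matrix.sample_ids)


def ncs_score(matrix: ExpressionMatrix, sig: GeneSignature) -> pd.Series:
    """Normalized cumulative score: mean of per-gene min-max scaled values.

    Each usable gene is rescaled to [0, 1] across samples; the score is the
    per-gene mean, so it always lies in [0, 1].
    """
    if len(matrix.sample_ids) < 2:
        raise DataError("ncs needs at least two samples")
    idx = _signature_rows(matrix, sig)
    sub = matrix.values[idx]
    lo = sub.min(axis=1, keepdims=True)
    hi = sub.max(axis=1, keepdims=True)
    rng = (hi - lo).ravel()
    usable = rng > 0
    if not usable.any():
        raise UndefinedScoreError(
            f"signature {sig.name!r}: all signature genes have zero range"
        )
    if not usable.all():
        warnings.warn(
            f"signature {sig.name!r}: {int((~usable).sum())} zero-range "
            "gene(s) excluded from NCS",
            stacklevel=2,
        )
    scaled = (sub[usable] - lo[usable]) / rng[usable][:, None]
    return pd.Series(scaled.mean(axis=0), index=matrix.sample_ids)


def ssgsea_score(
    matrix: ExpressionMatrix, sig: GeneSignature, alpha: float = 0.25
) -> pd.Series:
    """Single-sample GSEA enrichment score.

    Per sample, all N genes are ranked by expression (average ranks for
    ties, largest expression = rank N).  Walking down the ordered list, set
    members contribute their rank weight |r|^alpha normalized to the in-set
    total, non-members contribute 1/(N-k); the score is the *sum* of the
    running difference over all positions (the single-sample variant), so it
    depends only on within-sample ranks.
    """
    member = np.isin(matrix.gene_ids, sig.genes)
    k = int(member.sum())
    n = len(matrix.gene_ids)
    if k == 0:
        raise UndefinedScoreError(
            f"signature {sig.name!r}: no genes present in the matrix"
        )
    if k == n:
        raise DataError("signature covers the entire gene universe")
    if k < len(sig.genes):
        warnings.warn(
            f"signature {sig.name!r}: {len(sig.genes) - k} gene(s) absent "
            "from the matrix, dropped",
            stacklevel=2,
        )
    out = np.empty(len(matrix.sample_ids))
    for j in range(len(matrix.sample_ids)):
        ranks = rankdata(matrix.values[:, j], method="average")
        order = np.argsort(-ranks, kind="stable")  # descending expression
        in_set = member[order]
        w = np.abs(ranks[order]) ** alpha
        p_in = np.cumsum(np.where(in_set, w, 0.0))
        p_in /= p_in[-1]
        p_out = np.cumsum(~in_set) / (n - k)
        out[j] = float(np.sum(p_in - p_out))
    return pd.Series(out, index=matrix.sample_ids)


def _kcdf_gaussian(row: np.ndarray) -> np.ndarray:
    sd = row.std(ddof=1)
    h = sd / 4.0
    if h == 0:
        # constant gene: every sample sits at the same CDF value
        return np.full(row.size, 0.5)
    return norm.cdf((row[:, None] - row[None, :]) / h).mean(axis=1)


def _kcdf_empirical(row: np.ndarray) -> np.ndarray:
    return rankdata(row, method="average") / row.size


def gsva_score(
    matrix: ExpressionMatrix,
    sigs: SignatureSet | GeneSignature,
    kcdf: str = "gaussian",
    tau: float = 1.0,
) -> ScoreMatrix:
    """GSVA-style enrichment scores.

    Gene expression is first transformed to a cumulative-density estimate
    across samples (gaussian kernel with bandwidth sd/4, or the empirical
    CDF).  Per sample, genes are ranked by the transformed statistic, the
    ranks are symmetrized about the center, and a Kolmogorov-Smirnov-like
    random walk with weight exponent ``tau`` is run down the ordering; the
    enrichment score is max positive deviation minus the magnitude of the
    max negative deviation ("difference of extrema").
    """
    if isinstance(sigs, GeneSignature):
        sigs = SignatureSet([sigs])
    n_samples = len(matrix.sample_ids)
    if n_samples < 3:
        raise DataError("gsva needs at least three samples")
    if kcdf == "gaussian":
        z = np.apply_along_axis(_kcdf_gaussian, 1, matrix.values)
    elif kcdf == "empirical":
        z = np.apply_along_axis(_kcdf_empirical, 1, matrix.values)
    else:
        raise DataError(f"unknown kcdf {kcdf!r}")
    n = len(matrix.gene_ids)
    rows = {}
    n_used = {}
    # per-sample orderings shared by all signatures
    ranks = np.empty_like(z)
    orders = np.empty(z.shape[::-1], dtype=int)
    for j in range(n_samples):
        r = rankdata(z[:, j], method="average")
        ranks[:, j] = r
        orders[j] = np.argsort(-r, kind="stable")
    sym = np.abs(ranks - (n + 1) / 2.0) ** tau
    for sig in sigs:
        member = np.isin(matrix.gene_ids, sig.genes)
        k = int(member.sum())
        if k == 0:
            raise UndefinedScoreError(
                f"signature {sig.name!r}: no genes present in the matrix"
            )
        if k == n:
            raise DataError("signature covers the entire gene universe")
        es = np.empty(n_samples)
        for j in range(n_samples):
            order = orders[j]
            in_set = member[order]
            w = sym[order, j]
            denom_in = w[in_set].sum()
            if denom_in == 0:  # tau=0 edge handled by w == 1
                denom_in = float(k)
            walk = np.cumsum(np.where(in_set, w / denom_in, -1.0 / (n - k)))
            es[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
        rows[sig.name] = es
        n_used[sig.name] = k
    df = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.sample_ids)
    return ScoreMatrix(df, method="gsva", n_genes_used=n_used)


# ---------------------------------------------------------------------------
# Dispatcher


def score_matrix(
    matrix: ExpressionMatrix,
    sigs: SignatureSet | GeneSignature,
    method: str,
    **kwargs,
) -> ScoreMatrix:
    """Compute a signatures x samples :class:`ScoreMatrix` for one method.

    Per-sample methods operate on the intersection of each signature with
    the matrix genes; cells that cannot be computed (e.g. IQM with fewer
    than four matched genes) are NaN.
    """
    if isinstance(sigs, GeneSignature):
        sigs = SignatureSet([sigs])
    if len(matrix.gene_ids) == 0 or len(matrix.sample_ids) == 0:
        raise DataError("empty expression matrix")
    if method not in ALL_METHODS:
        raise DataError(f"unknown score method {method!r}")

    if method == "gsva":
        return gsva_score(matrix, sigs, **kwargs)

    rows: dict[str, np.ndarray] = {}
    n_used: dict[str, int] = {}
    for sig in sigs:
        if method in PER_SAMPLE_METHODS:
            idx = matrix.gene_index(sig.genes)
            n_used[sig.name] = int(idx.size)
            if idx.size < len(sig.genes):
                warnings.warn(
                    f"signature {sig.name!r}: "
                    f"{len(sig.genes) - idx.size} gene(s) absent, dropped",
                    stacklevel=2,
                )
            if idx.size < MIN_GENES[method] or idx.size == 0:
                rows[sig.name] = np.full(len(matrix.sample_ids), np.nan)
                continue
            sub = matrix.values[idx]
            rows[sig.name] = np.array(
                [simple_score(sub[:, j], method) for j in range(sub.shape[1])]
            )
        else:
            fn = {"zscore": zscore_score, "ncs": ncs_score, "ssgsea": ssgsea_score}[
                method
            ]
            try:
                series = fn(matrix, sig, **kwargs)
                rows[sig.name] = series.to_numpy()
                n_used[sig.name] = int(
                    np.isin(matrix.gene_ids, sig.genes).sum()
                )
            except UndefinedScoreError:
                rows[sig.name] = np.full(len(matrix.sample_ids), np.nan)
                n_used[sig.name] = 0
    df = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.sample_ids)
    df = df.loc[[s.name for s in sigs]]
    return ScoreMatrix(df, method=method, n_genes_used=n_used)
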