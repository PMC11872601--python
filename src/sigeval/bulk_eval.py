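"""Bulk hypoxia/normoxia pair evaluation against the RGS null.

Within each (series, platform, cell line) stratum, every hypoxic sample is
paired with every normoxic sample — pairs never cross strata, which keeps
batch effects out of the comparison.  For each pair the signature's score
distance d = |h_score - n_score| is ranked against the distances of 1000
length-matched random gene sets on the same two samples; the pair is
significant when the permutation p-value is at most 0.005 and the hypoxic
score is the larger one.  The accuracy index of a signature/score
combination is the percentage of significant pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .nullmodel import PermutationNull, RGSConfig, percentile_of, permutation_p, sample_rgs
from .scores import CROSS_SAMPLE_METHODS, PER_SAMPLE_METHODS, score_matrix
from .sigio import ExpressionMatrix, GeneSignature, SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "SamplePair",
    "PairResult",
    "AccuracyReport",
    "CoverageReport",
    "enumerate_pairs",
    "evaluate_pairs",
    "evaluate_pair",
    "accuracy_index",
    "platform_coverage_filter",
]


@dataclass(frozen=True)
class SamplePair:
    hyp_sample_id: str
    norm_sample_id: str
    series_id: str = ""
    platform_id: str = ""
    cell_line: str = ""


@dataclass
class PairResult:
    """One hypoxic/normoxic comparison of a signature under one score."""

    pair: SamplePair
    signature: str
    method: str
    h_score: float
    n_score: float
    d_sig: float
    percentile: float
    p: float
    evaluable: bool = True


@dataclass
class AccuracyReport:
    group_key: object
    n_pairs: int
    n_significant: int
    accuracy_pct: float | None
    alpha: float = 0.005
    n_unevaluable: int = 0


@dataclass
class CoverageReport:
    platform_id: str
    missing_fraction: dict[str, float]
    fraction_of_signatures_over_threshold: float
    excluded: bool


# ---------------------------------------------------------------------------
# Pair enumeration


def enumerate_pairs(meta: pd.DataFrame) -> list[SamplePair]:
    """Cross product hypoxic x normoxic within each stratum.

    A stratum is one (series_id, platform_id, cell_line) combination;
    missing grouping columns are treated as a single blank stratum value.
    Strata lacking one of the two conditions contribute no pairs.
    """
    meta = meta.copy()
    for col in ("series_id", "platform_id", "cell_line"):
        if col not in meta.columns:
            meta[col] = ""
        meta[col] = meta[col].fillna("")
    pairs: list[SamplePair] = []
    for (series, platform, cell), grp in meta.groupby(
        ["series_id", "platform_id", "cell_line"], sort=True
    ):
        hyp = grp.loc[grp["condition"] == "hypoxia", "sample_id"]
        norm = grp.loc[grp["condition"] == "normoxia", "sample_id"]
        if hyp.empty or norm.empty:
            logger.info(
                "stratum (%s, %s, %s): missing a condition, 0 pairs",
                series, platform, cell,
            )
            continue
        for h in hyp:
            for n in norm:
                pairs.append(SamplePair(h, n, series, platform, cell))
    return pairs


# ---------------------------------------------------------------------------
# Batched scoring of many gene sets on selected samples


def _batch_per_sample(arr: np.ndarray, method: str) -> np.ndarray:
    """Scores for a (n_sets, k, n_samples) value array, along axis 1."""
    if method == "mean":
        return arr.mean(axis=1)
    if method == "median":
        return np.median(arr, axis=1)
    if method == "midrange":
        return (arr.min(axis=1) + arr.max(axis=1)) / 2.0
    if method in ("midhinge", "trimean", "iqr"):
        q1, q2, q3 = np.quantile(arr, [0.25, 0.5, 0.75], axis=1)
        if method == "midhinge":
            return (q1 + q3) / 2.0
        if method == "trimean":
            return (q1 + 2 * q2 + q3) / 4.0
        return q3 - q1
    if method == "mad":
        med = np.median(arr, axis=1, keepdims=True)
        return np.median(np.abs(arr - med), axis=1)
    if method == "aad":
        mean = arr.mean(axis=1, keepdims=True)
        return np.mean(np.abs(arr - mean), axis=1)
    raise DataError(f"no batch path for method {method!r}")


def _batch_scores(
    matrix: ExpressionMatrix,
    sets_idx: np.ndarray,
    method: str,
) -> np.ndarray:
    """(n_sets, n_samples) scores for row-index gene sets under ``method``.

    Vectorized for the common methods; falls back to a per-set loop through
    the reference implementations for the rest (mode, ssgsea, gsva).
    """
    sets_idx = np.asarray(sets_idx)
    if method in ("mean", "median", "midrange", "midhinge", "trimean", "iqr",
                  "mad", "aad"):
        arr = matrix.values[sets_idx]
        return _batch_per_sample(arr, method)
    if method == "iqm":
        arr = matrix.values[sets_idx]
        q1, q3 = np.quantile(arr, [0.25, 0.75], axis=1)
        inner = (arr >= q1[:, None, :]) & (arr <= q3[:, None, :])
        masked = np.where(inner, arr, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(masked, axis=1)
    if method == "zscore":
        sd = matrix.values.std(axis=1, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (matrix.values - matrix.values.mean(axis=1, keepdims=True)) / sd[
                :, None
            ]
        z[sd == 0] = np.nan  # zero-variance genes excluded
        with np.errstate(invalid="ignore"):
            return np.nanmean(z[sets_idx], axis=1)
    if method == "ncs":
        lo = matrix.values.min(axis=1, keepdims=True)
        hi = matrix.values.max(axis=1, keepdims=True)
        rng = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            scaled = (matrix.values - lo) / rng
        scaled[rng.ravel() == 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(scaled[sets_idx], axis=1)
    # slow generic path: one GeneSignature per set
    out = np.empty((sets_idx.shape[0], len(matrix.sample_ids)))
    for i, idx in enumerate(sets_idx):
        sig = GeneSignature(
            name=f"_rgs{i}", genes=tuple(matrix.gene_ids[j] for j in idx)
        )
        out[i] = score_matrix(matrix, sig, method).scores.iloc[0].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Evaluation


def evaluate_pairs(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    pairs: Sequence[SamplePair],
    method: str,
    null_config: RGSConfig,
    per_pair_null: bool = False,
) -> list[PairResult]:
    """Evaluate a signature over many pairs, sharing one set of RGS draws.

    Random sets are drawn once (length-matched to the signature's matched
    genes) and their score distances recomputed on each pair, directly
    mirroring the signature's own distance.  With ``per_pair_null`` a fresh
    set of draws is used per pair (seed derived deterministically).
    """
    if method not in PER_SAMPLE_METHODS + CROSS_SAMPLE_METHODS:
        raise DataError(f"unknown score method {method!r}")
    sm = score_matrix(matrix, sig, method)
    sig_scores = sm.scores.iloc[0]
    k = int(np.isin(matrix.gene_ids, sig.genes).sum())
    if k == 0:
        raise DataError(f"signature {sig.name!r} shares no genes with the matrix")
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}

    def draws_to_idx(draws: list[np.ndarray]) -> np.ndarray:
        return np.array([[gene_pos[g] for g in d] for d in draws], dtype=int)

    results: list[PairResult] = []
    if not per_pair_null:
        sets_idx = draws_to_idx(sample_rgs(null_config, k, sig.genes))
        rgs_scores = _batch_scores(matrix, sets_idx, method)
    for i, pair in enumerate(pairs):
        hi = matrix.sample_index(pair.hyp_sample_id)
        ni = matrix.sample_index(pair.norm_sample_id)
        if per_pair_null:
            cfg = RGSConfig(
                universe=null_config.universe,
                n_rgs=null_config.n_rgs,
                seed=null_config.seed + i + 1,
                exclude_signature_genes=null_config.exclude_signature_genes,
            )
            sets_idx = draws_to_idx(sample_rgs(cfg, k, sig.genes))
            rgs_scores = _batch_scores(matrix, sets_idx, method)
        h_score = float(sig_scores.iloc[hi])
        n_score = float(sig_scores.iloc[ni])
        if np.isnan(h_score) or np.isnan(n_score):
            results.append(
                PairResult(pair, sig.name, method, h_score, n_score,
                           np.nan, np.nan, np.nan, evaluable=False)
            )
            continue
        d_sig = abs(h_score - n_score)
        d_null = np.abs(rgs_scores[:, hi] - rgs_scores[:, ni])
        ok = np.isfinite(d_null)
        if not ok.all():
            logger.info("pair %d: %d undefined RGS distances dropped",
                        i, int((~ok).sum()))
        null = PermutationNull(d_null[ok], epsilon=null_config.epsilon)
        direction_ok = h_score > n_score
        pct = percentile_of(d_sig, null)
        p = permutation_p(d_sig, null, direction_ok)
        results.append(
            PairResult(pair, sig.name, method, h_score, n_score, d_sig, pct, p)
        )
    n_bad = sum(not r.evaluable for r in results)
    if n_bad:
        logger.info("%d of %d pairs unevaluable under %s", n_bad, len(results), method)
    return results


def evaluate_pair(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    pair: SamplePair,
    method: str,
    null_config: RGSConfig,
) -> PairResult:
    """Single-pair convenience wrapper around :func:`evaluate_pairs`."""
    return evaluate_pairs(matrix, sig, [pair], method, null_config)[0]


def accuracy_index(
    results: Sequence[PairResult],
    alpha: float = 0.005,
    group_by: Callable[[PairResult], object] | None = None,
) -> dict[object, AccuracyReport]:
    """Share of significant pairs (p <= alpha) per group.

    Unevaluable pairs are excluded from denominators but counted; a group
    with no evaluable pairs is reported with an undefined (None) accuracy.
    """
    if not results:
        raise DataError("no pair results to aggregate")
    if group_by is None:
        group_by = lambda r: "all"  # noqa: E731
    groups: dict[object, list[PairResult]] = {}
    for r in results:
        groups.setdefault(group_by(r), []).append(r)
    reports: dict[object, AccuracyReport] = {}
    for key, rs in groups.items():
        ev = [r for r in rs if r.evaluable]
        n_sig = sum(r.p <= alpha for r in ev)
        reports[key] = AccuracyReport(
            group_key=key,
            n_pairs=len(ev),
            n_significant=n_sig,
            accuracy_pct=(100.0 * n_sig / len(ev)) if ev else None,
            alpha=alpha,
            n_unevaluable=len(rs) - len(ev),
        )
    return reports


def platform_coverage_filter(
    sigs: SignatureSet,
    platform_universes: Mapping[str, Sequence[str]],
    sig_missing_threshold: float = 0.20,
    platform_threshold: float = 0.20,
) -> list[CoverageReport]:
    """Flag platforms whose measured genes cover the signatures poorly.

    A platform is excluded when strictly more than ``platform_threshold`` of
    the signatures are each missing strictly more than
    ``sig_missing_threshold`` of their genes from the platform's universe.
    """
    if len(sigs) == 0 or not platform_universes:
        raise DataError("need signatures and platform universes")
    reports = []
    for platform, genes in platform_universes.items():
        universe = set(genes)
        missing = {
            s.name: 1.0 - len(set(s.genes) & universe) / len(s.genes)
            for s in sigs
        }
        frac_over = np.mean(
            [m > sig_missing_threshold for m in missing.values()]
        )
        reports.append(
            CoverageReport(
                platform_id=platform,
                missing_fraction=missing,
                fraction_of_signatures_over_threshold=float(frac_over),
                excluded=bool(frac_over > platform_threshold),
            )
        )
    return reports
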