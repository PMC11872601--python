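"""Synthetic data generators carrying the structure each evaluator assumes.

Three generators: (i) paired bulk hypoxia/normoxia experiments — log-normal
baseline expression with an additive log-scale shift planted on signature
genes in hypoxic samples, organized into series/platform strata with
optional per-platform gene dropout to exercise the coverage filter;
(ii) sparse single-cell counts — negative-binomial with independent dropout
and a multiplicative fold-change on signature genes in hypoxic cells;
(iii) tumor/NAT cohorts with exponential survival whose hazard is raised
for the top fraction of tumor samples by planted-signature score.

Defaults are the conditions the evaluators are validated under (effect 2.0
log-units with noise sd 0.3 in bulk; a 4-fold single-cell effect; a 3x
hazard multiplier on the top 20%).  All generators are deterministic given
their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .prognosis import SurvivalRecord
from .sigio import ExpressionMatrix, GeneSignature

__all__ = [
    "BulkSimConfig",
    "SCSimConfig",
    "CohortSimConfig",
    "BulkSim",
    "SCSim",
    "CohortSim",
    "simulate_bulk",
    "simulate_sc",
    "simulate_cohort",
]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Bulk


@dataclass
class BulkSimConfig:
    n_genes: int = 2000
    n_signature_genes: int = 20
    effect: float = 2.0        # additive shift on log expression, hypoxia only
    noise_sd: float = 0.3      # log-scale per-sample noise
    n_series: int = 25
    n_hyp: int = 2             # hypoxic samples per series
    n_norm: int = 2
    missing_fraction: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.n_signature_genes <= self.n_genes):
            raise DataError("need 0 < n_signature_genes <= n_genes")
        if self.effect < 0 or self.noise_sd <= 0:
            raise DataError("effect must be >= 0 and noise_sd > 0")
        if min(self.n_series, self.n_hyp, self.n_norm) < 1:
            raise DataError("need at least one series and one sample per condition")


@dataclass
class BulkSim:
    matrix: ExpressionMatrix
    metadata: pd.DataFrame
    signature: GeneSignature
    platform_universes: dict[str, list[str]]


def simulate_bulk(config: BulkSimConfig) -> BulkSim:
    """Paired bulk experiments with a planted hypoxia signature.

    Each gene g draws a baseline level mu_g ~ U(1, 8) on the natural-log
    scale; each sample value is exp(mu_g + noise), with +effect added to
    signature genes in hypoxic samples before exponentiation.  Each series
    is assigned one platform; ``missing_fraction`` removes a random share
    of genes from a platform's measured universe.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sig_idx = rng.choice(config.n_genes, config.n_signature_genes, replace=False)
    signature = GeneSignature(
        name="planted", genes=tuple(genes[i] for i in sorted(sig_idx))
    )
    mu = rng.uniform(1.0, 8.0, size=config.n_genes)

    sample_ids: list[str] = []
    meta_rows = []
    cols = []
    per_series = config.n_hyp + config.n_norm
    for s in range(config.n_series):
        series = f"SERIES{s:03d}"
        platform = f"PLATFORM{s % max(1, len(config.missing_fraction) or 3):02d}"
        for j in range(per_series):
            cond = "hypoxia" if j < config.n_hyp else "normoxia"
            sid = f"S{s:03d}_{cond[:3]}{j:02d}"
            logx = mu + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            if cond == "hypoxia":
                logx[sig_idx] += config.effect
            cols.append(np.exp(logx))
            sample_ids.append(sid)
            meta_rows.append(
                {"sample_id": sid, "series_id": series, "platform_id": platform,
                 "cell_line": "SIMCELL", "condition": cond}
            )
    values = np.column_stack(cols)
    matrix = ExpressionMatrix(genes, sample_ids, values, scale="linear")
    meta = pd.DataFrame(meta_rows)

    universes: dict[str, list[str]] = {}
    for platform in sorted(meta["platform_id"].unique()):
        frac = config.missing_fraction.get(platform, 0.0)
        if not (0 <= frac < 1):
            raise DataError(f"missing fraction for {platform!r} outside [0, 1)")
        n_keep = config.n_genes - int(round(frac * config.n_genes))
        keep = rng.choice(config.n_genes, n_keep, replace=False)
        universes[platform] = [genes[i] for i in sorted(keep)]
    return BulkSim(matrix, meta, signature, universes)


# ---------------------------------------------------------------------------
# Single-cell


@dataclass
class SCSimConfig:
    n_cells: int = 150         # per condition
    n_genes: int = 2000
    n_signature_genes: int = 20
    baseline_mean: float = 2.0  # mean of the per-gene NB mean distribution
    dispersion: float = 0.5     # NB size parameter; var = m + m^2/size
    dropout: float = 0.3
    effect: float = 4.0         # multiplicative fold-change, hypoxic cells
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout < 1):
            raise DataError("dropout must lie in [0, 1)")
        if self.effect < 0 or self.baseline_mean <= 0 or self.dispersion <= 0:
            raise DataError("effect >= 0, baseline_mean > 0, dispersion > 0 required")
        if not (0 < self.n_signature_genes <= self.n_genes):
            raise DataError("need 0 < n_signature_genes <= n_genes")


@dataclass
class SCSim:
    matrix: ExpressionMatrix
    labels: np.ndarray
    signature: GeneSignature


def simulate_sc(config: SCSimConfig) -> SCSim:
    """Sparse single-cell counts in two conditions.

    Per-gene means follow a gamma distribution with the requested overall
    mean; counts are negative binomial with the given dispersion, then
    zeroed independently with the dropout probability.  Signature genes in
    hypoxic cells have their mean multiplied by ``effect``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sig_idx = rng.choice(config.n_genes, config.n_signature_genes, replace=False)
    signature = GeneSignature(
        name="planted", genes=tuple(genes[i] for i in sorted(sig_idx))
    )
    gene_mean = rng.gamma(shape=1.0, scale=config.baseline_mean, size=config.n_genes)
    gene_mean = np.maximum(gene_mean, 1e-3)

    n_total = 2 * config.n_cells
    labels = np.array(["hypoxia"] * config.n_cells + ["normoxia"] * config.n_cells)
    means = np.tile(gene_mean[:, None], (1, n_total))
    means[np.ix_(sig_idx, np.arange(config.n_cells))] *= max(config.effect, 1e-12)

    size = config.dispersion
    p = size / (size + means)
    counts = rng.negative_binomial(size, p).astype(float)
    keep = rng.random(counts.shape) >= config.dropout
    counts *= keep
    cells = [f"C{('H' if l == 'hypoxia' else 'N')}{i:04d}"
             for i, l in enumerate(labels)]
    matrix = ExpressionMatrix(genes, cells, counts, scale="linear")
    return SCSim(matrix, labels, signature)


# ---------------------------------------------------------------------------
# Clinical cohorts with survival


@dataclass
class CohortSimConfig:
    n_cohorts: int = 10
    n_tumor: int = 50
    n_nat: int = 30
    n_genes: int = 2000
    n_signature_genes: int = 20
    tumor_shift: float = 1.5   # additive log-scale shift on signature genes
    noise_sd: float = 0.5
    baseline_hazard: float = 0.01   # events per month
    hazard_multiplier: float = 3.0  # applied to the top fraction by score
    top_fraction: float = 0.2
    censoring_rate: float = 0.3     # target share of censored tumor samples
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hazard_multiplier < 1:
            raise DataError("hazard multiplier must be >= 1")
        if not (0 <= self.censoring_rate < 1):
            raise DataError("censoring rate must lie in [0, 1)")
        if not (0 < self.top_fraction < 1):
            raise DataError("top fraction must lie in (0, 1)")
        if min(self.n_cohorts, self.n_tumor, self.n_nat) < 1:
            raise DataError("need at least one cohort and sample per tissue")


@dataclass
class CohortSim:
    matrix: ExpressionMatrix
    tissue_labels: np.ndarray
    cohort_labels: np.ndarray
    survival: list[SurvivalRecord]
    signature: GeneSignature


def simulate_cohort(config: CohortSimConfig) -> CohortSim:
    """Tumor/NAT cohorts with survival linked to the planted score.

    Tumor samples carry the planted shift on signature genes.  Within each
    cohort, tumor samples in the top ``top_fraction`` by planted-signature
    mean score have their exponential event hazard multiplied by
    ``hazard_multiplier``.  Censoring combines an independent exponential
    censoring time (rate chosen so roughly ``censoring_rate`` of baseline
    subjects are censored) with administrative censoring applied downstream.
    NAT samples carry no survival records.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    sig_idx = rng.choice(config.n_genes, config.n_signature_genes, replace=False)
    signature = GeneSignature(
        name="planted", genes=tuple(genes[i] for i in sorted(sig_idx))
    )
    mu = rng.uniform(1.0, 8.0, size=config.n_genes)

    cols, sample_ids, tissue, cohort = [], [], [], []
    survival: list[SurvivalRecord] = []
    c_rate = (
        config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        if config.censoring_rate > 0
        else None
    )
    for c in range(config.n_cohorts):
        cname = f"COHORT{c:02d}"
        tumor_scores = []
        tumor_ids = []
        for i in range(config.n_tumor + config.n_nat):
            is_tumor = i < config.n_tumor
            sid = f"{cname}_{'T' if is_tumor else 'N'}{i:03d}"
            logx = mu + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            if is_tumor:
                logx[sig_idx] += config.tumor_shift
            cols.append(np.exp(logx))
            sample_ids.append(sid)
            tissue.append("tumor" if is_tumor else "nat")
            cohort.append(cname)
            if is_tumor:
                tumor_scores.append(float(np.exp(logx[sig_idx]).mean()))
                tumor_ids.append(sid)
        # hazard groups within the cohort, by realized planted score
        scores = np.asarray(tumor_scores)
        thr = np.quantile(scores, 1.0 - config.top_fraction)
        for sid, sc in zip(tumor_ids, scores):
            lam = config.baseline_hazard * (
                config.hazard_multiplier if sc > thr else 1.0
            )
            t_event = rng.exponential(1.0 / lam)
            if c_rate is not None:
                t_cens = rng.exponential(1.0 / c_rate)
            else:
                t_cens = np.inf
            t = min(t_event, t_cens)
            survival.append(SurvivalRecord(sid, float(t), bool(t_event <= t_cens)))
    matrix = ExpressionMatrix(genes, sample_ids, np.column_stack(cols), "linear")
    return CohortSim(
        matrix, np.array(tissue), np.array(cohort), survival, signature
    )
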