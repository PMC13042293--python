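"""Simulation of MGE trials and ranking-based evaluation of training designs.

A replicate draws true genotypic values h ~ MVN(0, Omega_G kron K) and
residuals, forms true breeding values TBV_ij = mu_j + h_ij and phenotypes
TBV + e, extracts each design's training records, predicts candidate
genomic estimated breeding values (GEBVs) by MGE BLUP (with known or
REML-estimated variance components), and scores how well the predicted
ranking finds the top-k genotypes:

* NDCG@k   — discounted cumulative gain of the predicted top k relative to
  the ideal ranking, with linear gains f(v) = v and discount 1/log2(i+1);
* SRC@k    — Pearson correlation of (i, pi_i) over the top k predicted
  positions, where pi_i is the true TBV rank of the i-th predicted genotype;
* RSratio@k — (sum of ideal ranks 1..k) / (sum of true ranks of the
  predicted top k); equals 1 iff the predicted and true top-k sets agree.

k defaults to the top 5%: floor(0.05 * ncp), at least 1.  Each context is
scored separately: every environment, plus "overall" (environment-averaged
TBVs and GEBVs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenomicRelationship
from .mge_model import (
    CovarianceBundle,
    PhenotypeSet,
    RemlOptions,
    TrainingDesign,
    VarianceComponents,
    build_covariances,
    fit_reml,
    predictor_matrix,
)

__all__ = [
    "SimulationConfig",
    "SimulatedTrial",
    "MetricReport",
    "top_k",
    "rank_permutation",
    "ndcg_at_k",
    "src_at_k",
    "rs_ratio_at_k",
    "genetic_correlation",
    "simulate_truth",
    "run_experiment",
]

METRICS = ("ndcg", "src", "rs_ratio", "pearson")


def top_k(ncp: int, fraction: float = 0.05) -> int:
    """Number of top genotypes scored: floor(fraction * ncp), at least 1."""
    if ncp < 1:
        raise ValueError("ncp must be >= 1")
    return max(1, int(np.floor(fraction * ncp)))


def _rank_desc(values: np.ndarray) -> np.ndarray:
    """1-based ranks by descending value, ties broken by ascending index."""
    order = np.lexsort((np.arange(values.size), -values))
    ranks = np.empty(values.size, dtype=np.int64)
    ranks[order] = np.arange(1, values.size + 1)
    return ranks


def rank_permutation(tbv: np.ndarray, gebv: np.ndarray) -> np.ndarray:
    """True-rank permutation pi of the predicted ordering.

    Candidates are sorted by GEBV descending (ties by ascending index);
    pi[i] is the TBV rank (1 = best) of the candidate in predicted position
    i+1.
    """
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape or tbv.ndim != 1:
        raise ValueError("tbv and gebv must be 1-D vectors of equal length")
    pred_order = np.lexsort((np.arange(gebv.size), -gebv))
    return _rank_desc(tbv)[pred_order]


def ndcg_at_k(tbv: np.ndarray, pi: np.ndarray, k: int) -> float:
    """Normalized discounted cumulative gain at position k.

    Gains are the TBVs themselves (linear gain function) and the discount is
    1/log2(i+1).  Gains must be positive for the score to be meaningful; if
    any gain is <= 0 all TBVs are shifted so the smallest gain becomes 1
    (with a warning) — with realistic trait means this never triggers.
    """
    tbv = np.asarray(tbv, dtype=float)
    pi = np.asarray(pi, dtype=np.int64)
    if not 1 <= k <= tbv.size:
        raise ValueError("k must lie in [1, ncp]")
    v_sorted = np.sort(tbv)[::-1]
    if v_sorted[-1] <= 0:
        shift = 1.0 - v_sorted[-1]
        warnings.warn(
            f"non-positive TBV gains; shifting all gains by {shift:.6g} for NDCG",
            stacklevel=2,
        )
        v_sorted = v_sorted + shift
    discount = 1.0 / np.log2(np.arange(1, k + 1) + 1)
    dcg = float(np.sum(v_sorted[pi[:k] - 1] * discount))
    ideal = float(np.sum(v_sorted[:k] * discount))
    if ideal <= 0:
        raise ValueError("ideal DCG is non-positive")
    return dcg / ideal


def src_at_k(pi: np.ndarray, k: int) -> float:
    """Pearson correlation of the pairs (i, pi_i) over the first k positions."""
    pi = np.asarray(pi, dtype=float)
    if k < 2:
        raise ValueError("SRC@k needs k >= 2")
    if k > pi.size:
        raise ValueError("k exceeds the permutation length")
    top = pi[:k]
    if np.ptp(top) == 0:
        warnings.warn("constant ranks in the top k; SRC undefined", stacklevel=2)
        return float("nan")
    i = np.arange(1, k + 1, dtype=float)
    return float(np.corrcoef(i, top)[0, 1])


def rs_ratio_at_k(pi: np.ndarray, k: int) -> float:
    """Ratio of the ideal rank sum 1+..+k to the achieved true-rank sum."""
    pi = np.asarray(pi, dtype=float)
    if not 1 <= k <= pi.size:
        raise ValueError("k must lie in [1, ncp]")
    return float(k * (k + 1) / 2.0 / np.sum(pi[:k]))


def genetic_correlation(vc: VarianceComponents, env_a: int = 0, env_b: int = 1) -> float:
    """Between-environment genetic correlation tau0 / sqrt(s2_Ga * s2_Gb)."""
    s = vc.sigma_gxe
    return float(vc.tau0 / np.sqrt(s[env_a] * s[env_b]))


@dataclass
class SimulationConfig:
    """Ground truth and bookkeeping of a simulation experiment.

    ``heritability`` (if given) derives residual variances as
    sigma2_E = sigma2_G (1 - h2) / h2, overriding any set in ``vc``.
    """

    env_means: np.ndarray
    vc: VarianceComponents
    heritability: float | None = None
    n_replicates: int = 2_000
    master_seed: int = 0
    prediction_mode: str = "known_vc"
    top_fraction: float = 0.05
    reml_options: RemlOptions = field(default_factory=RemlOptions)

    def __post_init__(self) -> None:
        self.env_means = np.atleast_1d(np.asarray(self.env_means, dtype=float))
        if self.env_means.size != self.vc.n_envs:
            raise ValueError("env_means and variance components disagree on T")
        if self.heritability is not None:
            self.vc = VarianceComponents.from_heritability(
                self.vc.sigma_gxe, self.vc.tau0, self.heritability
            )
        if self.vc.sigma_e is None:
            raise ValueError("residual variances unset: give sigma_e or heritability")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.prediction_mode not in ("known_vc", "reml"):
            raise ValueError(f"unknown prediction_mode {self.prediction_mode!r}")

    @property
    def n_envs(self) -> int:
        return self.env_means.size


@dataclass
class SimulatedTrial:
    """One simulated MET replicate: TBVs and phenotypes, both ncp x T."""

    tbv: np.ndarray
    phenotypes: np.ndarray
    replicate_seed: int


def _genetic_factor(K: GenomicRelationship, vc: VarianceComponents) -> np.ndarray:
    """PSD square root L of Omega_G kron K (negative eigenvalues clipped at 0)."""
    ev_o, U_o = np.linalg.eigh(vc.omega_g)
    ev_k, U_k = np.linalg.eigh(K.K)
    L_o = U_o * np.sqrt(np.clip(ev_o, 0.0, None))
    L_k = U_k * np.sqrt(np.clip(ev_k, 0.0, None))
    return np.kron(L_o, L_k)


def simulate_truth(
    K: GenomicRelationship,
    cfg: SimulationConfig,
    replicate: int,
    _factor: np.ndarray | None = None,
) -> SimulatedTrial:
    """Draw one replicate of true breeding values and phenotypes.

    The replicate seed is master_seed + replicate, so trials are reproducible
    individually and as a batch.
    """
    ncp, t = K.n_genotypes, cfg.n_envs
    seed = cfg.master_seed + replicate
    rng = np.random.default_rng(seed)
    L = _factor if _factor is not None else _genetic_factor(K, cfg.vc)
    h_flat = L @ rng.standard_normal(t * ncp)
    h = h_flat.reshape(t, ncp).T  # (genotype, environment)
    e = rng.standard_normal((ncp, t)) * np.sqrt(cfg.vc.sigma_e)
    tbv = cfg.env_means + h
    return SimulatedTrial(tbv=tbv, phenotypes=tbv + e, replicate_seed=seed)


@dataclass
class MetricReport:
    """Replicate means and standard deviations of the ranking metrics.

    ``contexts`` maps a context label (each environment, plus "overall") to
    {metric: (mean, sd)}; ``samples`` keeps the raw per-replicate values for
    downstream significance checks.
    """

    contexts: dict[str, dict[str, tuple[float, float]]]
    k: int
    n_replicates: int
    n_reml_failures: int = 0
    samples: dict[str, dict[str, np.ndarray]] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "context": ctx,
                "metric": metric,
                "mean": mean,
                "sd": sd,
                "k": self.k,
                "replicates": self.n_replicates,
            }
            for ctx, metrics in self.contexts.items()
            for metric, (mean, sd) in metrics.items()
        ]
        return pd.DataFrame(rows)


def _training_phenotypes(trial: SimulatedTrial, design: TrainingDesign) -> PhenotypeSet:
    return PhenotypeSet([trial.phenotypes[s, j] for j, s in enumerate(design.subsets)])


def _score_contexts(
    trial: SimulatedTrial, h_hat_flat: np.ndarray, k: int, ncp: int, t: int
) -> dict[str, dict[str, float]]:
    H = h_hat_flat.reshape(t, ncp)
    out: dict[str, dict[str, float]] = {}
    views = [(f"env{j + 1}", trial.tbv[:, j], H[j]) for j in range(t)]
    views.append(("overall", trial.tbv.mean(axis=1), H.mean(axis=0)))
    for label, v, vhat in views:
        pi = rank_permutation(v, vhat)
        out[label] = {
            "ndcg": ndcg_at_k(v, pi, k),
            "src": src_at_k(pi, k) if k >= 2 else float("nan"),
            "rs_ratio": rs_ratio_at_k(pi, k),
            "pearson": float(np.corrcoef(v, vhat)[0, 1]),
        }
    return out


def run_experiment(
    K: GenomicRelationship,
    designs: dict[str, TrainingDesign],
    cfg: SimulationConfig,
) -> dict[str, MetricReport]:
    """Run the full simulation loop for one or more training designs.

    Per replicate: simulate truth, pull each design's training phenotypes,
    predict all candidates' GEBVs by MGE BLUP (known truth components or a
    fresh REML fit per replicate), and score every context.  Returns one
    MetricReport per design, with replicate-level samples retained.
    """
    ncp, t = K.n_genotypes, cfg.n_envs
    k = top_k(ncp, cfg.top_fraction)
    factor = _genetic_factor(K, cfg.vc)

    predictors: dict[str, np.ndarray] = {}
    fallback_bundles: dict[str, CovarianceBundle] = {}
    for name, design in designs.items():
        design.validate_against(ncp)
        bundle = build_covariances(K, design, cfg.vc)
        fallback_bundles[name] = bundle
        predictors[name] = predictor_matrix(bundle)

    samples: dict[str, dict[str, dict[str, list[float]]]] = {
        name: {} for name in designs
    }
    reml_failures = {name: 0 for name in designs}

    for r in range(cfg.n_replicates):
        trial = simulate_truth(K, cfg, r, _factor=factor)
        for name, design in designs.items():
            y = _training_phenotypes(trial, design)
            if cfg.prediction_mode == "reml":
                try:
                    fit = fit_reml(K, design, y, cfg.reml_options)
                except Exception:
                    fit = None
                if fit is not None and fit.converged:
                    bundle = build_covariances(K, design, fit.vc)
                    h_hat = predictor_matrix(bundle) @ y.stacked
                else:
                    reml_failures[name] += 1
                    h_hat = predictors[name] @ y.stacked
            else:
                h_hat = predictors[name] @ y.stacked
            scored = _score_contexts(trial, h_hat, k, ncp, t)
            store = samples[name]
            for ctx, metrics in scored.items():
                ctx_store = store.setdefault(ctx, {m: [] for m in METRICS})
                for m, val in metrics.items():
                    ctx_store[m].append(val)

    reports: dict[str, MetricReport] = {}
    for name in designs:
        contexts: dict[str, dict[str, tuple[float, float]]] = {}
        raw: dict[str, dict[str, np.ndarray]] = {}
        for ctx, metrics in samples[name].items():
            raw[ctx] = {m: np.asarray(vals) for m, vals in metrics.items()}
            contexts[ctx] = {}
            for m in METRICS:
                vals = raw[ctx][m]
                if np.isnan(vals).all():  # e.g. SRC when k = 1
                    contexts[ctx][m] = (float("nan"), float("nan"))
                else:
                    contexts[ctx][m] = (
                        float(np.nanmean(vals)),
                        float(np.nanstd(vals, ddof=1)) if cfg.n_replicates > 1 else 0.0,
                    )
        reports[name] = MetricReport(
            contexts=contexts,
            k=k,
            n_replicates=cfg.n_replicates,
            n_reml_failures=reml_failures[name],
            samples=raw,
        )
    return reports
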