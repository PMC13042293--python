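"""The marker-by-environment (MGE) mixed model for multi-environment trials.

The model for training phenotypes stacked over T environments is

    y = mu + g + e,    g ~ MVN(0, G_tr),    e ~ MVN(0, diag(sigma2_Ej I)),

where the pooled genotypic covariance G_tr has diagonal blocks
sigma2_GxJ * K[Sj, Sj] and off-diagonal blocks tau0 * K[Sj, Sj'], i.e. a
compound-symmetric environment covariance Omega_G crossed with the genomic
relationship matrix.  Fixed environment means are never estimated
explicitly: the matrix M_tr = blockdiag((1/sigma2_Ej)(I - Jbar)) centers
each environment and annihilates them, so the BLUP of the training
genotypic values is

    g_hat = (M + G_tr^{-1})^{-1} M y = G_tr (M G_tr + I)^{-1} M y,

and candidate genotypic values over all T environments follow as

    h_hat = G_cp.tr G_tr^{-1} g_hat = G_cp.tr (M G_tr + I)^{-1} M y,

with prediction covariance (equal to Cov(h, h_hat) by BLUP orthogonality)

    A = Var(h_hat) = G_cp.tr (M G_tr + I)^{-1} M G_cp.tr^T.

Candidate effects use environment-major flat ordering: genotype i in
environment j sits at index j*ncp + i.

Variance components are either supplied (the design criteria fix them) or
estimated by REML on the compound-symmetric structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize as sp_optimize
from scipy.linalg import cho_factor, cho_solve

from .genotypes import GenomicRelationship

__all__ = [
    "TrainingDesign",
    "VarianceComponents",
    "PhenotypeSet",
    "CovarianceBundle",
    "PredictionResult",
    "RemlFit",
    "RemlOptions",
    "build_covariances",
    "blup_training",
    "predict_candidates",
    "prediction_covariance",
    "fit_reml",
]


@dataclass
class TrainingDesign:
    """Per-environment training subsets S1..ST of the candidate population.

    ``subsets[j]`` holds candidate indices phenotyped in environment j.
    Indices are duplicate-free within an environment; the same genotype may
    appear in several environments.
    """

    subsets: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.subsets:
            raise ValueError("design needs at least one environment")
        clean = []
        for j, s in enumerate(self.subsets):
            s = np.asarray(s, dtype=np.int64)
            if s.ndim != 1 or s.size == 0:
                raise ValueError(f"environment {j}: subset must be a non-empty 1-D index list")
            if (s < 0).any():
                raise ValueError(f"environment {j}: negative candidate index")
            if len(np.unique(s)) != s.size:
                raise ValueError(f"environment {j}: duplicate candidate indices")
            clean.append(s)
        self.subsets = clean

    @property
    def n_envs(self) -> int:
        return len(self.subsets)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(s.size for s in self.subsets)

    @property
    def n_train(self) -> int:
        return sum(self.sizes)

    def validate_against(self, ncp: int) -> None:
        for j, s in enumerate(self.subsets):
            if (s >= ncp).any():
                raise ValueError(f"environment {j}: candidate index out of range for ncp={ncp}")

    def flat_columns(self, ncp: int) -> np.ndarray:
        """Indices of the training effects in the environment-major flat layout."""
        return np.concatenate([j * ncp + s for j, s in enumerate(self.subsets)])

    def key(self) -> tuple[tuple[int, ...], ...]:
        """Hashable canonical form (order within an environment is immaterial)."""
        return tuple(tuple(sorted(s.tolist())) for s in self.subsets)

    def to_frame(self, genotype_ids: list[str], env_labels: list[str] | None = None) -> pd.DataFrame:
        env_labels = env_labels or [f"env{j + 1}" for j in range(self.n_envs)]
        rows = [
            {"genotype_id": genotype_ids[i], "environment": env_labels[j]}
            for j, s in enumerate(self.subsets)
            for i in s
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, genotype_ids: list[str], env_order: list[str] | None = None
    ) -> "TrainingDesign":
        """Build a design from a (genotype_id, environment) table."""
        idx = {g: i for i, g in enumerate(genotype_ids)}
        missing = set(df["genotype_id"].astype(str)) - idx.keys()
        if missing:
            raise ValueError(f"unknown genotype ids in design: {sorted(missing)[:5]}")
        envs = env_order or list(dict.fromkeys(df["environment"].astype(str)))
        subsets = []
        for e in envs:
            sub = df[df["environment"].astype(str) == e]["genotype_id"].astype(str)
            subsets.append(np.array([idx[g] for g in sub], dtype=np.int64))
        return cls(subsets)

    @classmethod
    def from_csv(cls, path: str | Path, genotype_ids: list[str]) -> "TrainingDesign":
        return cls.from_frame(pd.read_csv(path), genotype_ids)


@dataclass
class VarianceComponents:
    """Variance components of the MGE model.

    ``sigma_gxe[j]`` is the total genetic variance in environment j (main +
    interaction), ``tau0`` the common between-environment genetic covariance,
    and ``sigma_e[j]`` the residual variance in environment j (may be left
    unset when only the genetic part is needed).
    """

    sigma_gxe: np.ndarray
    tau0: float
    sigma_e: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sigma_gxe = np.atleast_1d(np.asarray(self.sigma_gxe, dtype=float))
        if (self.sigma_gxe <= 0).any():
            raise ValueError("genetic variances must be positive")
        self.tau0 = float(self.tau0)
        if self.sigma_e is not None:
            self.sigma_e = np.atleast_1d(np.asarray(self.sigma_e, dtype=float))
            if self.sigma_e.shape != self.sigma_gxe.shape:
                raise ValueError("sigma_e and sigma_gxe must have equal length")
            if (self.sigma_e <= 0).any():
                raise ValueError("residual variances must be positive")
        ev = np.linalg.eigvalsh(self.omega_g)
        if ev[0] < -1e-10 * max(ev[-1], 1.0):
            raise ValueError("Omega_G (sigma_gxe / tau0) is not positive semidefinite")

    @property
    def n_envs(self) -> int:
        return self.sigma_gxe.size

    @property
    def omega_g(self) -> np.ndarray:
        """T x T genetic covariance across environments (compound symmetric)."""
        t = self.n_envs
        om = np.full((t, t), self.tau0)
        np.fill_diagonal(om, self.sigma_gxe)
        return om

    @property
    def omega_e(self) -> np.ndarray:
        if self.sigma_e is None:
            raise ValueError("residual variances are unset")
        return np.diag(self.sigma_e)

    @classmethod
    def from_heritability(
        cls, sigma_gxe: np.ndarray, tau0: float, heritability: float
    ) -> "VarianceComponents":
        """Derive residual variances as sigma2_E = sigma2_G (1 - h2) / h2."""
        if not 0 < heritability < 1:
            raise ValueError("heritability must lie in (0, 1)")
        sigma_gxe = np.atleast_1d(np.asarray(sigma_gxe, dtype=float))
        sigma_e = sigma_gxe * (1 - heritability) / heritability
        return cls(sigma_gxe, tau0, sigma_e)


@dataclass
class PhenotypeSet:
    """Per-environment phenotype vectors aligned with a training design."""

    values: list[np.ndarray]
    environment_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = [np.asarray(v, dtype=float).ravel() for v in self.values]
        if self.environment_labels is None:
            self.environment_labels = [f"env{j + 1}" for j in range(len(self.values))]
        if len(self.environment_labels) != len(self.values):
            raise ValueError("environment_labels length mismatch")

    @property
    def stacked(self) -> np.ndarray:
        return np.concatenate(self.values)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, design: TrainingDesign, genotype_ids: list[str],
        env_order: list[str] | None = None,
    ) -> "PhenotypeSet":
        """Align a (genotype_id, environment, value) table with a design."""
        envs = env_order or list(dict.fromkeys(df["environment"].astype(str)))
        if len(envs) != design.n_envs:
            raise ValueError("environment count mismatch between phenotypes and design")
        lut = {
            (str(r.genotype_id), str(r.environment)): float(r.value)
            for r in df.itertuples()
        }
        values = []
        for j, s in enumerate(design.subsets):
            try:
                values.append(np.array([lut[(genotype_ids[i], envs[j])] for i in s]))
            except KeyError as exc:
                raise ValueError(f"phenotype missing for {exc.args[0]}") from exc
        return cls(values, envs)


@dataclass
class CovarianceBundle:
    """All covariance pieces of the MGE BLUP for one design.

    ``G_tr`` (ntr x ntr) covariance of training genotypic values, ``G_cp``
    (N x N, N = T*ncp) candidate covariance Omega_G kron K, ``G_cp_tr``
    (N x ntr) cross-covariance, ``M_tr`` (ntr x ntr) the residual-weighted
    per-environment centering matrix.
    """

    G_tr: np.ndarray
    G_cp: np.ndarray
    G_cp_tr: np.ndarray
    M_tr: np.ndarray
    design: TrainingDesign
    vc: VarianceComponents
    ncp: int

    @property
    def n_train(self) -> int:
        return self.G_tr.shape[0]


@dataclass
class PredictionResult:
    """BLUPs and their covariance for one design and phenotype set."""

    g_hat_tr: np.ndarray
    h_hat_cp: np.ndarray
    A: np.ndarray


@dataclass
class RemlOptions:
    tol: float = 1e-6
    max_iter: int = 200
    floor_factor: float = 1e-6  # variance floor = floor_factor * var(y)


@dataclass
class RemlFit:
    vc: VarianceComponents
    env_means: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


def _centering_blocks(sizes: tuple[int, ...], sigma_e: np.ndarray) -> np.ndarray:
    """Block-diagonal M_tr = blockdiag((1/sigma2_Ej)(I_nj - Jbar_nj))."""
    ntr = sum(sizes)
    M = np.zeros((ntr, ntr))
    off = 0
    for nj, se in zip(sizes, sigma_e):
        block = (np.eye(nj) - np.full((nj, nj), 1.0 / nj)) / se
        M[off : off + nj, off : off + nj] = block
        off += nj
    return M


def build_covariances(
    K: GenomicRelationship, design: TrainingDesign, vc: VarianceComponents
) -> CovarianceBundle:
    """Assemble G_tr, G_cp, G_cp.tr and M_tr for a training design.

    All genetic pieces are submatrices of G_cp = Omega_G kron K in the
    environment-major flat layout, which keeps the block bookkeeping in one
    place.
    """
    if vc.n_envs != design.n_envs:
        raise ValueError("variance components and design disagree on T")
    if vc.sigma_e is None:
        raise ValueError("residual variances required to build M_tr")
    design.validate_against(K.n_genotypes)
    ncp = K.n_genotypes
    G_cp = np.kron(vc.omega_g, K.K)
    cols = design.flat_columns(ncp)
    G_tr = G_cp[np.ix_(cols, cols)]
    G_cp_tr = G_cp[:, cols]
    M_tr = _centering_blocks(design.sizes, vc.sigma_e)
    return CovarianceBundle(G_tr, G_cp, G_cp_tr, M_tr, design, vc, ncp)


def _solve_mg_plus_i(bundle: CovarianceBundle, rhs: np.ndarray) -> np.ndarray:
    """Solve (M_tr G_tr + I) x = rhs, with a ridge fallback on G_tr."""
    lhs = bundle.M_tr @ bundle.G_tr + np.eye(bundle.n_train)
    try:
        return np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * float(np.mean(np.diag(bundle.G_tr)))
        lhs = bundle.M_tr @ (bundle.G_tr + jitter * np.eye(bundle.n_train)) + np.eye(
            bundle.n_train
        )
        return np.linalg.solve(lhs, rhs)


def blup_training(bundle: CovarianceBundle, y: PhenotypeSet) -> np.ndarray:
    """BLUP of the training genotypic values, g_hat = G (M G + I)^{-1} M y.

    Algebraically identical to the Henderson form (M + G^{-1})^{-1} M y but
    avoids inverting G_tr.  Environment-wise constants in y are annihilated
    by M, so fixed environment means never enter.
    """
    yv = y.stacked
    if yv.size != bundle.n_train:
        raise ValueError("phenotype vector length does not match the design")
    return bundle.G_tr @ _solve_mg_plus_i(bundle, bundle.M_tr @ yv)


def predict_candidates(bundle: CovarianceBundle, y: PhenotypeSet) -> PredictionResult:
    """BLUP of all candidate genotypic values plus the prediction covariance."""
    yv = y.stacked
    if yv.size != bundle.n_train:
        raise ValueError("phenotype vector length does not match the design")
    w = _solve_mg_plus_i(bundle, bundle.M_tr @ yv)
    g_hat = bundle.G_tr @ w
    h_hat = bundle.G_cp_tr @ w
    return PredictionResult(g_hat, h_hat, prediction_covariance(bundle))


def prediction_covariance(bundle: CovarianceBundle) -> np.ndarray:
    """A = Var(h_hat) = G_cp.tr (M G_tr + I)^{-1} M G_cp.tr^T (symmetrized).

    Data-free: depends only on the design, the GRM and the variance
    components, which is what makes it usable as a design criterion.
    """
    QM = _solve_mg_plus_i(bundle, bundle.M_tr)  # (M G + I)^{-1} M
    A = bundle.G_cp_tr @ QM @ bundle.G_cp_tr.T
    return (A + A.T) / 2.0


def predictor_matrix(bundle: CovarianceBundle) -> np.ndarray:
    """The linear map C with h_hat = C y (N x ntr); handy for simulations."""
    QM = _solve_mg_plus_i(bundle, bundle.M_tr)
    return bundle.G_cp_tr @ QM


# ---------------------------------------------------------------------------
# REML for the compound-symmetric MGE structure
# ---------------------------------------------------------------------------


def _tau0_from_r(r: float, sigma_gxe: np.ndarray) -> float:
    """Map a correlation-like parameter r in (-1, 1) to a PSD-safe tau0.

    For T = 2 the bound |tau0| <= sqrt(sigma2_G1 sigma2_G2) is exact.  For
    T >= 3 a sufficient bound is used: tau0 <= min_j sigma2_Gj for positive
    tau0 and |tau0| <= min_j sigma2_Gj / (T - 1) for negative.
    """
    t = sigma_gxe.size
    if t == 1:
        return 0.0
    if t == 2:
        return r * float(np.sqrt(sigma_gxe[0] * sigma_gxe[1]))
    m = float(sigma_gxe.min())
    return r * m if r >= 0 else r * m / (t - 1)


def _unpack_theta(theta: np.ndarray, t: int) -> VarianceComponents:
    sigma_gxe = np.exp(theta[:t])
    sigma_e = np.exp(theta[t + 1 :]) if t > 1 else np.exp(theta[t:])
    if t > 1:
        tau0 = _tau0_from_r(np.tanh(theta[t]), sigma_gxe)
    else:
        tau0 = 0.0
    # keep strictly inside the PSD region for the eigenvalue check
    return VarianceComponents(sigma_gxe, tau0 * (1 - 1e-12), sigma_e)


def restricted_loglik(
    K: GenomicRelationship,
    design: TrainingDesign,
    y: PhenotypeSet,
    vc: VarianceComponents,
) -> float:
    """Restricted log-likelihood of the MGE model with fixed environment means."""
    design.validate_against(K.n_genotypes)
    yv = y.stacked
    sizes = design.sizes
    ntr, t = sum(sizes), len(sizes)
    env_of = np.repeat(np.arange(t), sizes)
    idx = np.concatenate(design.subsets)
    # G_tr = Omega_G expanded over observations, elementwise with K submatrix
    omega_exp = vc.omega_g[np.ix_(env_of, env_of)]
    G_tr = omega_exp * K.K[np.ix_(idx, idx)]
    V = G_tr + np.diag(np.asarray(vc.sigma_e)[env_of])
    X = np.zeros((ntr, t))
    X[np.arange(ntr), env_of] = 1.0
    try:
        c, low = cho_factor(V, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), yv)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    resid_quad = float(yv @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * ((ntr - t) * np.log(2 * np.pi) + logdet_v + logdet_x + resid_quad)


def fit_reml(
    K: GenomicRelationship,
    design: TrainingDesign,
    y: PhenotypeSet,
    opts: RemlOptions | None = None,
) -> RemlFit:
    """REML estimation of (sigma2_GxJ, tau0, sigma2_Ej) for the MGE model.

    Variances are optimized on the log scale; tau0 through a tanh-bounded
    correlation-like parameter that keeps Omega_G positive semidefinite.
    Initialized from per-environment phenotypic moments (an even split of
    variance between genetic and residual parts) and refined by L-BFGS-B
    with numerical gradients.
    """
    opts = opts or RemlOptions()
    t = design.n_envs
    sizes = design.sizes
    if any(n < 2 for n in sizes):
        raise ValueError("REML needs at least 2 observations per environment")
    if design.n_train <= t + 2:
        raise ValueError("too few observations for REML (need ntr > T + 2)")
    var_y = float(np.var(y.stacked))
    floor = max(opts.floor_factor * var_y, 1e-12)

    env_vars = np.array([max(np.var(v, ddof=1), 2 * floor) for v in y.values])
    theta0 = np.concatenate(
        [
            np.log(env_vars / 2),
            [np.arctanh(0.25)] if t > 1 else [],
            np.log(env_vars / 2),
        ]
    )

    def objective(theta: np.ndarray) -> float:
        try:
            vc = _unpack_theta(theta, t)
        except ValueError:
            return np.inf
        ll = restricted_loglik(K, design, y, vc)
        return np.inf if not np.isfinite(ll) else -ll

    log_floor = np.log(floor)
    bounds = (
        [(log_floor, None)] * t
        + ([(-5.0, 5.0)] if t > 1 else [])
        + [(log_floor, None)] * t
    )
    res = sp_optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": opts.max_iter, "ftol": opts.tol},
    )
    # derivative-free polish: finite-difference gradients stall on the flat
    # ridge between genetic and residual variances
    polish = sp_optimize.minimize(
        objective,
        res.x,
        method="Nelder-Mead",
        options={"maxiter": 50 * (2 * t + 1), "fatol": opts.tol, "xatol": 1e-8},
    )
    converged = bool(res.success or polish.success)
    if polish.fun <= res.fun:
        res = polish
    vc = _unpack_theta(res.x, t)
    loglik = -res.fun if np.isfinite(res.fun) else -np.inf
    converged = converged and np.isfinite(loglik)
    if not converged:
        warnings.warn("REML did not converge; estimates are best-effort", stacklevel=2)

    bundle = build_covariances(K, design, vc)
    g_hat = blup_training(bundle, y)
    off = np.cumsum((0,) + sizes)
    env_means = np.array(
        [float(np.mean(v) - np.mean(g_hat[off[j] : off[j + 1]])) for j, v in enumerate(y.values)]
    )
    return RemlFit(vc, env_means, loglik, converged, int(res.nit))
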