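"""Generalized coefficient-of-determination (CD) design criteria.

Both criteria score a training design by how precisely the MGE-model BLUP
would recover candidate genotypic values, using fixed "criterion" variance
components (defaults: unit genetic and residual variances, tau0 = 0.5 —
training-set rankings under CD criteria are known to be insensitive to this
choice).  With A the prediction covariance and B = G_cp the prior candidate
covariance:

* ``cdmean_v2``  sums A_ll / B_ll over all N = T * ncp (genotype,
  environment) cells — the mean squared correlation between true and
  estimated genotypic values when divided by N.
* ``cdmean_met`` sums Ai* / Bi* over genotypes, where Ai* and Bi* pool the
  T x T block entries of candidate i — the squared correlation between
  environment-averaged true and estimated values (the 1/T^2 averaging
  factors cancel in the ratio).

The sum is used as the optimization objective; divide by N (respectively
ncp) for the reported "mean CD".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genotypes import GenomicRelationship
from .mge_model import TrainingDesign, VarianceComponents, _centering_blocks

__all__ = ["CriterionSpec", "CDScorer", "cdmean_v2", "cdmean_met", "default_criterion_vc"]


def default_criterion_vc(n_envs: int) -> VarianceComponents:
    """The fixed criterion components: sigma2_GxJ = sigma2_Ej = 1, tau0 = 0.5."""
    ones = np.ones(n_envs)
    return VarianceComponents(ones, 0.5 if n_envs > 1 else 0.0, ones.copy())


@dataclass
class CriterionSpec:
    """Which CD criterion to use and under which fixed variance components."""

    name: str = "cdmean_v2"
    criterion_vc: VarianceComponents | None = None
    report_mean: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("cdmean_v2", "cdmean_met"):
            raise ValueError(f"unknown criterion {self.name!r}")

    def resolve_vc(self, n_envs: int) -> VarianceComponents:
        if self.criterion_vc is None:
            return default_criterion_vc(n_envs)
        if self.criterion_vc.n_envs != n_envs:
            raise ValueError("criterion_vc has the wrong number of environments")
        if self.criterion_vc.sigma_e is None:
            raise ValueError("criterion_vc needs residual variances")
        return self.criterion_vc


class CDScorer:
    """Scores many designs against one (K, vc) pair.

    Precomputes G_cp = Omega_G kron K once; each design evaluation then only
    slices it and solves an ntr x ntr system, which is what makes
    criterion-guided search affordable.
    """

    def __init__(
        self,
        K: GenomicRelationship,
        n_envs: int,
        spec: CriterionSpec | None = None,
    ) -> None:
        self.spec = spec or CriterionSpec()
        self.vc = self.spec.resolve_vc(n_envs)
        self.K = K
        self.ncp = K.n_genotypes
        self.n_envs = n_envs
        self._G_cp = np.kron(self.vc.omega_g, K.K)
        self._B_diag = np.diag(self._G_cp).copy()
        # Bi* = K_ii * sum(Omega_G): the T x T block of candidate i in G_cp
        self._B_star = np.diag(K.K) * float(self.vc.omega_g.sum())

    def _solve_design(self, design: TrainingDesign) -> tuple[np.ndarray, np.ndarray]:
        """Return (G_cp_tr, (M G_tr + I)^{-1} M) for one design."""
        design.validate_against(self.ncp)
        if design.n_envs != self.n_envs:
            raise ValueError("design has the wrong number of environments")
        cols = design.flat_columns(self.ncp)
        G_tr = self._G_cp[np.ix_(cols, cols)]
        M = _centering_blocks(design.sizes, self.vc.sigma_e)
        lhs = M @ G_tr + np.eye(cols.size)
        QM = np.linalg.solve(lhs, M)
        return self._G_cp[:, cols], QM

    def _a_diag(self, design: TrainingDesign) -> np.ndarray:
        G_cp_tr, QM = self._solve_design(design)
        return np.einsum("ij,jk,ik->i", G_cp_tr, QM, G_cp_tr, optimize=True)

    def cdmean_v2(self, design: TrainingDesign) -> float:
        if all(n == 1 for n in design.sizes):
            warnings.warn("all-singleton design: prediction covariance is zero", stacklevel=2)
            return 0.0
        a = self._a_diag(design)
        ok = self._B_diag > 0
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} zero-variance candidates from CDmean(v2)",
                stacklevel=2,
            )
        score = float(np.sum(a[ok] / self._B_diag[ok]))
        return score / ok.sum() if self.spec.report_mean else score

    def cdmean_met(self, design: TrainingDesign) -> float:
        if all(n == 1 for n in design.sizes):
            warnings.warn("all-singleton design: prediction covariance is zero", stacklevel=2)
            return 0.0
        G_cp_tr, QM = self._solve_design(design)
        A = G_cp_tr @ QM @ G_cp_tr.T
        t, n = self.n_envs, self.ncp
        a_star = np.einsum("aibi->i", A.reshape(t, n, t, n))
        ok = self._B_star > 0
        if not ok.all():
            warnings.warn(
                f"excluding {int((~ok).sum())} zero-variance candidates from CDmean.MET",
                stacklevel=2,
            )
        score = float(np.sum(a_star[ok] / self._B_star[ok]))
        return score / ok.sum() if self.spec.report_mean else score

    def __call__(self, design: TrainingDesign) -> float:
        if self.spec.name == "cdmean_met":
            return self.cdmean_met(design)
        return self.cdmean_v2(design)


def cdmean_v2(
    K: GenomicRelationship, design: TrainingDesign, spec: CriterionSpec | None = None
) -> float:
    """CDmean(v2) score of a design (sum of per-cell CD values A_ll / B_ll)."""
    spec = spec or CriterionSpec(name="cdmean_v2")
    return CDScorer(K, design.n_envs, CriterionSpec("cdmean_v2", spec.criterion_vc, spec.report_mean)).cdmean_v2(design)


def cdmean_met(
    K: GenomicRelationship, design: TrainingDesign, spec: CriterionSpec | None = None
) -> float:
    """CDmean.MET score of a design (sum over genotypes of Ai* / Bi*)."""
    spec = spec or CriterionSpec(name="cdmean_met")
    return CDScorer(K, design.n_envs, CriterionSpec("cdmean_met", spec.criterion_vc, spec.report_mean)).cdmean_met(design)
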