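"""Marker data handling and the genomic relationship matrix.

Markers are biallelic SNP scores on inbred-line-like panels, coded -1/0/+1
(-1 = minor-allele homozygote, 0 = heterozygote, +1 = major-allele
homozygote).  Standardizing each marker column to mean 0 / sample sd 1 and
cross-multiplying yields the genomic relationship matrix (GRM)

    K = (1/p) W W^T,

whose rows sum to zero and whose trace equals n - 1 — the two identities the
test suite leans on.  A seeded Balding-Nichols-style generator provides
synthetic panels with tunable subpopulation structure so everything runs
without real genotype files.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "StandardizedMarkers",
    "GenomicRelationship",
    "load_markers",
    "filter_maf",
    "standardize",
    "compute_grm",
    "simulate_marker_matrix",
    "read_grm",
    "write_grm",
]

logger = logging.getLogger(__name__)

_VALID_SCORES = (-1, 0, 1)


@dataclass
class MarkerMatrix:
    """Integer marker scores for a candidate population.

    Attributes
    ----------
    scores : ndarray of shape (n_genotypes, n_markers)
        Values in {-1, 0, 1}; +1 is the major-allele homozygote.
    genotype_ids, marker_ids : list of str
        Unique row / column labels.
    """

    scores: np.ndarray
    genotype_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.int64)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-D matrix")
        ncp, p = self.scores.shape
        if ncp < 2:
            raise ValueError("need at least 2 genotypes")
        if p < 1:
            raise ValueError("need at least 1 marker")
        if not np.isin(self.scores, _VALID_SCORES).all():
            bad = np.setdiff1d(np.unique(self.scores), _VALID_SCORES)
            raise ValueError(f"marker scores outside {{-1,0,1}}: {bad.tolist()}")
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        self.marker_ids = [str(m) for m in self.marker_ids]
        if len(self.genotype_ids) != ncp:
            raise ValueError("genotype_ids length mismatch")
        if len(self.marker_ids) != p:
            raise ValueError("marker_ids length mismatch")
        if len(set(self.genotype_ids)) != ncp:
            raise ValueError("duplicate genotype ids")
        if len(set(self.marker_ids)) != p:
            raise ValueError("duplicate marker ids")

    @property
    def n_genotypes(self) -> int:
        return self.scores.shape[0]

    @property
    def n_markers(self) -> int:
        return self.scores.shape[1]


@dataclass
class StandardizedMarkers:
    """Column-standardized marker matrix W (mean 0, sample sd 1 per column)."""

    w: np.ndarray
    genotype_ids: list[str]
    kept_marker_ids: list[str]

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] < 1:
            raise ValueError("w must be a 2-D matrix with >= 1 column")


@dataclass
class GenomicRelationship:
    """Genomic relationship matrix K = (1/p) W W^T with its genotype labels."""

    K: np.ndarray
    genotype_ids: list[str]

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = self.K.shape[0]
        if self.K.ndim != 2 or self.K.shape[1] != n:
            raise ValueError("K must be square")
        if len(self.genotype_ids) != n:
            raise ValueError("genotype_ids length mismatch")
        if not np.allclose(self.K, self.K.T, atol=1e-10):
            raise ValueError("K must be symmetric")
        ev = np.linalg.eigvalsh(self.K)
        if ev[0] < -1e-8 * max(ev[-1], 1.0):
            raise ValueError("K is not positive semidefinite")

    @property
    def n_genotypes(self) -> int:
        return self.K.shape[0]


def _orient_minus1_0_1(scores: np.ndarray) -> np.ndarray:
    """Flip marker columns so +1 is the major-allele homozygote.

    Frequency ties keep the input orientation.
    """
    ncp = scores.shape[0]
    # frequency of the allele currently coded +1
    freq_plus = (2 * (scores == 1).sum(axis=0) + (scores == 0).sum(axis=0)) / (2 * ncp)
    flip = freq_plus < 0.5
    out = scores.copy()
    out[:, flip] *= -1
    return out


def _recode_012(scores: np.ndarray) -> np.ndarray:
    """Map 0/1/2 allele-dosage codes to oriented -1/0/+1 scores."""
    return _orient_minus1_0_1(scores - 1)


def _impute_column_mean(values: np.ndarray, valid: Sequence[int]) -> np.ndarray:
    """Replace NaNs by the column mean rounded to the nearest valid score."""
    out = values.copy()
    valid_arr = np.asarray(valid, dtype=float)
    for j in range(out.shape[1]):
        col = out[:, j]
        mask = np.isnan(col)
        if not mask.any():
            continue
        if mask.all():
            raise ValueError(f"marker column {j} is entirely missing")
        mean = col[~mask].mean()
        out[mask, j] = valid_arr[np.argmin(np.abs(valid_arr - mean))]
    return out


def _load_delimited(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[1] < 1:
        raise ValueError(f"no marker columns found in {path}")
    genotype_ids = [str(g) for g in df.index]
    marker_ids = [str(m) for m in df.columns]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    non_numeric = np.isnan(values) & df.notna().to_numpy()
    if non_numeric.any():
        raise ValueError(f"non-numeric marker entries in {path}")
    return values, genotype_ids, marker_ids


def _load_vcf(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - present in supported envs
        raise ImportError("VCF loading requires the cyvcf2 package") from exc

    vcf = VCF(str(path))
    genotype_ids = list(vcf.samples)
    columns: list[np.ndarray] = []
    marker_ids: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping multi-allelic site {variant.CHROM}:{variant.POS}",
                stacklevel=3,
            )
            continue
        # ALT-allele dosage per sample; missing genotypes -> NaN
        col = np.full(len(genotype_ids), np.nan)
        for i, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if len(alleles) == 2:
                col[i] = sum(alleles)
        columns.append(col)
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        marker_ids.append(vid)
    vcf.close()
    if not columns:
        raise ValueError(f"no usable biallelic sites in {path}")
    return np.column_stack(columns), genotype_ids, marker_ids


def load_markers(
    path: str | Path,
    format: str = "delimited",
    coding: str = "auto",
    missing_policy: str = "error",
) -> MarkerMatrix:
    """Load a marker matrix from a delimited text file or a VCF.

    Parameters
    ----------
    path : path to the genotype file.
    format : {"delimited", "vcf"}
        Delimited files carry a header row of marker ids and genotype ids in
        the first column (tab or comma, autodetected).  VCF files are read
        through cyvcf2 (diploid GT field; multi-allelic sites skipped).
    coding : {"auto", "minus1_0_1", "0_1_2"}
        Score coding of a delimited file.  ``auto`` infers ``minus1_0_1``
        when negative entries are present and ``0_1_2`` otherwise.  VCF input
        is always ALT-allele dosage (0/1/2).
    missing_policy : {"error", "mean_impute"}
        ``mean_impute`` replaces missing cells by the column mean rounded to
        the nearest valid score of the declared coding.

    Returns
    -------
    MarkerMatrix in -1/0/+1 coding with +1 the major-allele homozygote
    (columns of 0/1/2 input are oriented by allele frequency; ties keep the
    file orientation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        values, genotype_ids, marker_ids = _load_delimited(path)
    elif format == "vcf":
        values, genotype_ids, marker_ids = _load_vcf(path)
        coding = "0_1_2"
    else:
        raise ValueError(f"unknown format {format!r}")

    if coding == "auto":
        finite = values[np.isfinite(values)]
        coding = "minus1_0_1" if (finite < 0).any() else "0_1_2"
    if coding not in ("minus1_0_1", "0_1_2"):
        raise ValueError(f"unknown coding {coding!r}")
    valid = (-1, 0, 1) if coding == "minus1_0_1" else (0, 1, 2)

    finite = values[np.isfinite(values)]
    if not np.isin(finite, valid).all():
        bad = np.setdiff1d(np.unique(finite), valid)
        raise ValueError(f"unknown {coding} symbols: {bad.tolist()}")

    if np.isnan(values).any():
        if missing_policy == "error":
            raise ValueError(f"missing marker values in {path} (policy=error)")
        if missing_policy != "mean_impute":
            raise ValueError(f"unknown missing_policy {missing_policy!r}")
        values = _impute_column_mean(values, valid)

    scores = values.astype(np.int64)
    if coding == "0_1_2":
        scores = _recode_012(scores)
    else:
        scores = _orient_minus1_0_1(scores)
    return MarkerMatrix(scores, genotype_ids, marker_ids)


def minor_allele_frequency(m: MarkerMatrix) -> np.ndarray:
    """Per-marker minor allele frequency (2#(-1) + #(0)) / (2 ncp)."""
    s = m.scores
    return (2 * (s == -1).sum(axis=0) + (s == 0).sum(axis=0)) / (2 * m.n_genotypes)


def filter_maf(m: MarkerMatrix, threshold: float) -> MarkerMatrix:
    """Drop markers with minor allele frequency below ``threshold``.

    Marker order is preserved; ``threshold=0`` is a no-op.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    keep = minor_allele_frequency(m) >= threshold
    if not keep.any():
        raise ValueError("no markers survive the MAF filter")
    return MarkerMatrix(
        m.scores[:, keep],
        m.genotype_ids,
        [mid for mid, k in zip(m.marker_ids, keep) if k],
    )


def standardize(m: MarkerMatrix) -> StandardizedMarkers:
    """Center and scale each marker column to mean 0 and sample sd 1.

    The scale is the sample standard deviation (denominator ncp - 1), which
    makes trace(K) = ncp - 1 exact for the downstream GRM.  Monomorphic
    (zero-variance) columns carry no information and are dropped with a
    warning.
    """
    x = m.scores.astype(float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all marker columns are monomorphic")
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = [mid for mid, k in zip(m.marker_ids, keep) if not k]
        logger.warning("dropping %d zero-variance markers: %s", n_dropped, dropped[:10])
        warnings.warn(f"dropped {n_dropped} zero-variance markers", stacklevel=2)
    w = (x[:, keep] - mean[keep]) / sd[keep]
    return StandardizedMarkers(
        w, list(m.genotype_ids), [mid for mid, k in zip(m.marker_ids, keep) if k]
    )


def compute_grm(w: StandardizedMarkers) -> GenomicRelationship:
    """Genomic relationship matrix K = (1/p) W W^T over retained markers."""
    p = w.w.shape[1]
    if p == 0:
        raise ValueError("no retained markers")
    K = (w.w @ w.w.T) / p
    K = (K + K.T) / 2.0
    return GenomicRelationship(K, list(w.genotype_ids))


def grm_from_markers(m: MarkerMatrix, maf_threshold: float = 0.0) -> GenomicRelationship:
    """Convenience pipeline: MAF filter -> standardize -> GRM."""
    if maf_threshold > 0:
        m = filter_maf(m, maf_threshold)
    return compute_grm(standardize(m))


def simulate_marker_matrix(
    ncp: int,
    p: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    n_subpops: int = 1,
    fst: float = 0.0,
    seed: int | None = None,
    inbreeding: float = 0.9,
) -> MarkerMatrix:
    """Simulate an inbred-line-like SNP panel.

    Each marker draws an ancestral allele frequency uniformly on
    ``maf_range``.  With ``n_subpops > 1`` the per-subpopulation frequencies
    follow a Balding-Nichols Beta around the ancestral frequency with
    differentiation ``fst``; genotypes are then drawn with a high inbreeding
    coefficient (default F = 0.9) so heterozygotes are rare, mimicking elite
    inbred panels.  Genotypes are split into contiguous, near-equal
    subpopulation blocks.  Fully deterministic given ``seed``.
    """
    if ncp < 2 or p < 1:
        raise ValueError("need ncp >= 2 and p >= 1")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
    if n_subpops < 1:
        raise ValueError("n_subpops must be >= 1")
    if not 0 <= fst < 1:
        raise ValueError("fst must lie in [0, 1)")
    if not 0 <= inbreeding <= 1:
        raise ValueError("inbreeding must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(lo, hi, size=p)

    membership = np.repeat(np.arange(n_subpops), -(-ncp // n_subpops))[:ncp]
    if n_subpops > 1 and fst > 0:
        a = ancestral * (1 - fst) / fst
        b = (1 - ancestral) * (1 - fst) / fst
        subpop_freq = rng.beta(a, b, size=(n_subpops, p))
    else:
        subpop_freq = np.tile(ancestral, (n_subpops, 1))

    q = subpop_freq[membership]  # minor-allele frequency per (genotype, marker)
    p_het = 2 * q * (1 - q) * (1 - inbreeding)
    p_minor_hom = q**2 + inbreeding * q * (1 - q)
    u = rng.random((ncp, p))
    scores = np.where(u < p_minor_hom, -1, np.where(u < p_minor_hom + p_het, 0, 1))
    # realized frequencies can drift past 0.5 at small ncp; re-orient so +1
    # stays the major-allele homozygote, as the coding promises
    scores = _orient_minus1_0_1(scores)

    genotype_ids = [f"g{i + 1:04d}" for i in range(ncp)]
    marker_ids = [f"m{j + 1:05d}" for j in range(p)]
    return MarkerMatrix(scores, genotype_ids, marker_ids)


def write_grm(K: GenomicRelationship, path: str | Path) -> None:
    """Write a GRM as TSV with genotype ids as header and first column."""
    df = pd.DataFrame(K.K, index=K.genotype_ids, columns=K.genotype_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_grm(path: str | Path) -> GenomicRelationship:
    """Read a GRM written by :func:`write_grm`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != [str(c) for c in df.columns]:
        raise ValueError("GRM row and column labels disagree")
    return GenomicRelationship(df.to_numpy(dtype=float), [str(g) for g in df.index])
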