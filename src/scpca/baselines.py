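"""First-PC score extractors used as comparison arms: standard PCA on the
numeric 0/1/2 coding, and logistic (Bernoulli) PCA on a binarized coding."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cpca import FitConfig, fit_cpca, first_pc_scores
from .setio import GenotypeMatrix

__all__ = ["PcScores", "fit_pca_scores", "fit_lpca_scores", "binarize_genotypes"]


@dataclass
class PcScores:
    """First principal-component scores with the extractor's method tag."""

    scores: np.ndarray
    method: Literal["pca", "lpca", "cpca"]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("PC scores must be finite")


def fit_pca_scores(G: GenotypeMatrix | np.ndarray) -> PcScores:
    """First PC of the column-centered numeric genotype matrix.

    This is the classical PCA arm: genotypes are treated as numbers 0/1/2,
    implicitly assuming risk proportional to minor-allele count.  The sign is
    stabilized to correlate non-negatively with per-sample allele counts.
    """
    X = (G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)).astype(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least two samples")
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        warnings.warn("zero-variance genotype matrix; returning zero scores")
        return PcScores(scores=np.zeros(X.shape[0]), method="pca")
    # first left-singular direction scaled by its singular value = projection
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, 0] * s[0]
    counts = X.sum(axis=1)
    if np.std(counts) > 0 and np.std(scores) > 0:
        if np.corrcoef(scores, counts)[0, 1] < 0:
            scores = -scores
    return PcScores(scores=scores, method="pca")


def binarize_genotypes(
    values: np.ndarray, coding: Literal["dominant", "recessive"] = "dominant"
) -> np.ndarray:
    """Collapse 0/1/2 genotypes to 0/1.

    dominant: any minor allele counts (1, 2 -> 1); recessive: only the
    homozygous minor genotype counts (2 -> 1).
    """
    if coding == "dominant":
        return (values >= 1).astype(np.int8)
    if coding == "recessive":
        return (values == 2).astype(np.int8)
    raise ValueError(f"unknown coding {coding!r}")


def fit_lpca_scores(
    G: GenotypeMatrix | np.ndarray,
    config: FitConfig | None = None,
    coding: Literal["dominant", "recessive"] = "dominant",
) -> PcScores:
    """Logistic (Bernoulli) PCA first-PC scores on binarized genotypes.

    Uses the c = 2 reduction of the categorical PCA solver, so the likelihood
    trace and damping guarantees carry over.
    """
    values = G.values if isinstance(G, GenotypeMatrix) else np.asarray(G)
    B = binarize_genotypes(values, coding=coding)
    model = fit_cpca(B, config=config, n_categories=2)
    return PcScores(scores=first_pc_scores(model), method="lpca")
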