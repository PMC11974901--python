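"""Reference-panel PCA and query projection.

Genotypes are standardized SNP-wise to (g - 2p̂) / sqrt(2p̂(1-p̂)) using
reference allele frequencies p̂ (unit variance under Hardy-Weinberg),
the classical scaling for population-structure PCA. Missing genotypes
are mean-imputed, i.e. contribute 0 after standardization, both when
fitting and when projecting. Queries are projected onto the first
``n_components`` (default 5) principal axes by plain least squares;
no shrinkage correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import MISSING, GenotypeMatrix, ReferencePanel
from .qc import allele_frequencies


@dataclass
class PCAModel:
    """Frozen standardization constants plus principal-axis loadings.

    ``loadings`` columns are orthonormal; ``explained_variance`` is
    non-increasing. ``reference_scores`` are the fitted scores of the
    panel the model was trained on.
    """

    snp_ids: list[str]
    means: np.ndarray
    scales: np.ndarray
    loadings: np.ndarray
    n_components: int
    explained_variance: np.ndarray
    reference_scores: np.ndarray = field(repr=False)
    reference_sample_ids: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.scales <= 0):
            raise ValueError("all scales must be strictly positive")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(self.n_components), atol=1e-8):
            raise ValueError("loading columns are not orthonormal to 1e-8")
        if np.any(np.diff(self.explained_variance) > 1e-12):
            raise ValueError("explained_variance must be non-increasing")


def standardize(
    m: GenotypeMatrix, means: np.ndarray, scales: np.ndarray
) -> np.ndarray:
    """(g - mean) / scale with missing cells set to 0 (mean imputation)."""
    means = np.asarray(means, dtype=float)
    scales = np.asarray(scales, dtype=float)
    if len(means) != m.n_snps or len(scales) != m.n_snps:
        raise ValueError("means/scales must match the matrix's SNPs")
    if np.any(scales <= 0):
        raise ValueError("zero or negative scale: monomorphic SNPs must be "
                         "removed before standardization")
    x = (m.dosages.astype(float) - means) / scales
    x[m.missing_mask] = 0.0
    return x


def _apply_sign_convention(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Make the largest-|entry| loading of each component positive, in place.

    Ties on |entry| resolve to the first index (np.argmax), so the
    convention is exact and the fit is reproducible regardless of
    sample order or SVD sign indeterminacy.
    """
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
            scores[:, c] *= -1.0


def fit_reference_pca(
    ref: ReferencePanel | GenotypeMatrix, n_components: int = 5
) -> PCAModel:
    """Fit standardization constants and top principal axes on a reference.

    Monomorphic and all-missing SNPs are excluded (their scale is 0 or
    undefined). Raises if the standardized matrix has rank below
    ``n_components``, naming the achievable rank.
    """
    m = ref.genotypes if isinstance(ref, ReferencePanel) else ref
    p = allele_frequencies(m)
    informative = np.nonzero(np.nan_to_num(p, nan=0.0) * (1 - np.nan_to_num(p, nan=1.0)) > 0)[0]
    m_fit = m.take_snps(informative)
    if m_fit.n_snps < n_components or m_fit.n_samples < n_components:
        raise ValueError(
            f"need at least {n_components} polymorphic SNPs and samples; "
            f"have {m_fit.n_snps} SNPs x {m_fit.n_samples} samples"
        )
    p_fit = p[informative]
    means = 2.0 * p_fit
    scales = np.sqrt(2.0 * p_fit * (1.0 - p_fit))
    x = standardize(m_fit, means, scales)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(x.shape) * np.finfo(float).eps))
    if rank < n_components:
        raise ValueError(
            f"standardized reference has rank {rank} < n_components={n_components}"
        )
    loadings = vt[:n_components].T.copy()
    scores = u[:, :n_components] * s[:n_components]
    _apply_sign_convention(loadings, scores)
    explained = s[:n_components] ** 2 / max(m_fit.n_samples - 1, 1)
    return PCAModel(
        snp_ids=m_fit.snp_ids,
        means=means,
        scales=scales,
        loadings=loadings,
        n_components=n_components,
        explained_variance=explained,
        reference_scores=scores,
        reference_sample_ids=list(m_fit.sample_ids),
    )


def project(model: PCAModel, m: GenotypeMatrix) -> np.ndarray:
    """Project samples onto the model's axes; returns samples x components.

    ``m`` is matched to ``model.snp_ids`` by SNP id; model SNPs absent
    from ``m`` are treated as missing (standardized 0). Raises if no
    SNP overlaps.
    """
    col_of = {sid: j for j, sid in enumerate(m.snp_ids)}
    n = m.n_samples
    dos = np.full((n, len(model.snp_ids)), MISSING, dtype=np.int8)
    n_overlap = 0
    for k, sid in enumerate(model.snp_ids):
        j = col_of.get(sid)
        if j is not None:
            dos[:, k] = m.dosages[:, j]
            n_overlap += 1
    if n_overlap == 0:
        raise ValueError("no SNP overlap between query matrix and PCA model")
    x = (dos.astype(float) - model.means) / model.scales
    x[dos == MISSING] = 0.0
    return x @ model.loadings
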