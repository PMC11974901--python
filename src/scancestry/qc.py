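"""SNP/sample quality control and windowed r² LD pruning.

QC mirrors standard practice for sparse call sets: keep SNPs common
(reference MAF strictly > 5%) in the reference panel, drop SNPs and
then samples with missingness strictly > 10%, and LD-prune with a
sliding window of 50 SNPs, step 10, r² threshold 0.1 (the PLINK
``--indep-pairwise 50 10 0.1`` semantics: windows counted in SNPs,
not base pairs).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PruneParams:
    """Windowed-pruning parameters (defaults: PLINK 50 / 10 / 0.1)."""

    window_snps: int = 50
    step_snps: int = 10
    r2_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.window_snps < 2:
            raise ValueError("window_snps must be >= 2")
        if not 1 <= self.step_snps <= self.window_snps:
            raise ValueError("step_snps must be in [1, window_snps]")
        if not 0 < self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in (0, 1]")


def compute_maf(m: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency min(p, 1-p) over non-missing calls.

    All-missing SNPs get NaN (MAF undefined) with a warning.
    """
    dosages = m.dosages.astype(float)
    observed = m.dosages != MISSING
    n_obs = observed.sum(axis=0)
    alt_sum = np.where(observed, dosages, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt_sum / (2.0 * n_obs)
    maf = np.minimum(p, 1.0 - p)
    if (n_obs == 0).any():
        bad = [m.snps[j].id for j in np.nonzero(n_obs == 0)[0][:5]]
        warnings.warn(f"MAF undefined for all-missing SNPs (e.g. {bad})")
        maf[n_obs == 0] = np.nan
    return maf


def allele_frequencies(m: GenotypeMatrix) -> np.ndarray:
    """Per-SNP ALT allele frequency over non-missing calls (NaN if all missing)."""
    observed = m.dosages != MISSING
    n_obs = observed.sum(axis=0)
    alt_sum = np.where(observed, m.dosages, 0).astype(float).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return alt_sum / (2.0 * n_obs)


def filter_common(
    m: GenotypeMatrix, reference_maf: np.ndarray, threshold: float = 0.05
) -> GenotypeMatrix:
    """Keep SNPs whose *reference-panel* MAF is strictly above ``threshold``.

    The MAF must come from the reference panel, never the query set;
    NaN (undefined) MAFs are dropped.
    """
    reference_maf = np.asarray(reference_maf, dtype=float)
    if len(reference_maf) != m.n_snps:
        raise ValueError("reference_maf must have one value per SNP")
    keep = np.nonzero(np.nan_to_num(reference_maf, nan=-1.0) > threshold)[0]
    logger.info("filter_common: kept %d / %d SNPs (MAF > %g)", len(keep), m.n_snps, threshold)
    return m.take_snps(keep)


def filter_missingness(
    m: GenotypeMatrix, snp_max: float = 0.10, sample_max: float = 0.10
) -> GenotypeMatrix:
    """Drop SNPs then samples with missing fraction strictly above the cutoffs.

    SNP filtering runs first; sample missingness is then recomputed over
    the surviving SNPs. Boundary values (fraction exactly equal to the
    cutoff) are kept: the exclusion rule is "higher than", strictly.
    """
    miss = m.missing_mask
    snp_frac = miss.mean(axis=0)
    keep_snps = np.nonzero(snp_frac <= snp_max)[0]
    m2 = m.take_snps(keep_snps)
    if m2.n_snps == 0:
        raise ValueError("all SNPs removed by the missingness filter")
    sample_frac = m2.missing_mask.mean(axis=1)
    keep_samples = np.nonzero(sample_frac <= sample_max)[0]
    m3 = m2.take_samples(keep_samples)
    if m3.n_samples == 0:
        raise ValueError("all samples removed by the missingness filter")
    logger.info(
        "filter_missingness: removed %d SNPs (> %g missing) and %d samples (> %g missing)",
        m.n_snps - m2.n_snps, snp_max, m2.n_samples - m3.n_samples, sample_max,
    )
    return m3


def pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete (both non-missing) entries on the
    raw dosages. Defined as 0 when either vector is constant on the
    complete subset; fewer than 2 complete pairs also yields 0, with a
    warning.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        warnings.warn("pairwise_r2: fewer than 2 complete pairs; returning 0")
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    dx = xv - xv.mean()
    dy = yv - yv.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return 0.0
    sxy = float(dx @ dy)
    return sxy * sxy / (sxx * syy)


def _window_r2_matrix(dos: np.ndarray) -> np.ndarray:
    """All-pairs r² for the columns of a dosage block, pairwise-complete.

    Missing-aware closed form via masked sums; pairs with < 2 complete
    observations or a constant member get r² = 0.
    """
    observed = (dos != MISSING).astype(float)
    y = np.where(dos == MISSING, 0, dos).astype(float)
    n = observed.T @ observed                     # complete pairs per (a, b)
    sx = y.T @ observed                           # sum of x over complete pairs
    sxx = (y * y).T @ observed
    sxy = y.T @ y
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n
        varx = sxx - sx * sx / n
        r2 = cov * cov / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    # guard float round-off on exact duplicates
    return np.clip(r2, 0.0, 1.0)


def _prune_window(
    win: list[int], kept: np.ndarray, dosages: np.ndarray,
    maf: np.ndarray, positions: np.ndarray, threshold: float,
) -> bool:
    """Greedy removal inside one window; returns True if anything was removed.

    While some retained pair exceeds the r² threshold, take the pair
    with the largest r² (ties: smallest window-index pair) and remove
    its member with the smaller reference MAF; MAF tie -> the larger
    position (ties beyond that cannot occur within a chromosome).
    """
    idx = list(win)
    r2 = _window_r2_matrix(dosages[:, idx])
    np.fill_diagonal(r2, 0.0)
    removed = False
    while len(idx) >= 2:
        flat = np.argmax(r2)
        a, b = divmod(flat, r2.shape[1])
        if r2[a, b] <= threshold:
            break
        if a > b:
            a, b = b, a
        ja, jb = idx[a], idx[b]
        if maf[ja] < maf[jb]:
            victim = a
        elif maf[jb] < maf[ja]:
            victim = b
        else:
            victim = a if positions[ja] > positions[jb] else b
        kept[idx[victim]] = False
        removed = True
        del idx[victim]
        r2 = np.delete(np.delete(r2, victim, axis=0), victim, axis=1)
    return removed


def ld_prune(m: GenotypeMatrix, params: PruneParams = PruneParams()) -> list[str]:
    """Windowed greedy LD pruning; returns the kept SNP ids in input order.

    SNPs must be ordered by (chrom, pos); windows never span
    chromosomes. Sliding passes at the configured step repeat until no
    SNP is removed, then step-1 enforcement passes guarantee that *no*
    window of ``window_snps`` consecutive kept SNPs contains a pair
    with r² above the threshold. The removal rule (see
    :func:`_prune_window`) is deterministic, so the result is too, and
    pruning an already-pruned set is a no-op.
    """
    snps = m.snps
    order = [(s.chrom, s.pos) for s in snps]
    if order != sorted(order):
        raise ValueError("ld_prune requires SNPs ordered by (chrom, pos)")
    maf = np.nan_to_num(compute_maf(m), nan=0.0)
    positions = np.array([s.pos for s in snps])
    kept = np.ones(m.n_snps, dtype=bool)
    W, threshold = params.window_snps, params.r2_threshold

    # contiguous per-chromosome index runs
    segments: list[list[int]] = []
    for j, s in enumerate(snps):
        if segments and snps[j - 1].chrom == s.chrom:
            segments[-1].append(j)
        else:
            segments.append([j])

    def sweep(segment: list[int], step: int) -> bool:
        removed = False
        retained = [j for j in segment if kept[j]]
        start = 0
        while True:
            win = [j for j in retained[start: start + W] if kept[j]]
            if len(win) >= 2:
                removed |= _prune_window(win, kept, m.dosages, maf, positions, threshold)
            if start + W >= len(retained):
                break
            start += step
        return removed

    for segment in segments:
        while sweep(segment, params.step_snps):
            pass
        while sweep(segment, 1):
            pass

    kept_ids = [s.id for j, s in enumerate(snps) if kept[j]]
    logger.info("ld_prune: kept %d / %d SNPs (window=%d step=%d r2<=%g)",
                len(kept_ids), m.n_snps, W, params.step_snps, threshold)
    return kept_ids
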