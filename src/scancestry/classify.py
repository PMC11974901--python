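"""The three ancestry-inference approaches.

* PCA-Distance: nearest ancestry-group centroid in the space of the
  first five reference PCs (Euclidean distance).
* PCA-RandomForest: a random-forest classifier trained on the
  reference PC scores, reporting class probabilities.
* Supervised admixture: maximum-likelihood estimation of ancestry
  proportions q_ik under the binomial-mixture model in which genotype
  g_ij ~ Binomial(2, sum_k q_ik f_kj), with reference individuals'
  proportions fixed to one-hot group indicators (supervised mode) and
  f_kj the ancestral (group) ALT-allele frequencies. Fitting is by EM;
  the log-likelihood is guaranteed non-decreasing across iterations.

Every argmax assignment breaks ties lexicographically by group label,
so all three methods are deterministic given their inputs (and seed,
for the forest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype import MISSING, GenotypeMatrix, ReferencePanel

logger = logging.getLogger(__name__)

#: Allele-frequency clamp keeping the likelihood finite for discordant calls.
F_EPS = 1e-6


@dataclass
class AncestryCall:
    """One sample's per-group scores and its argmax assignment.

    ``score_type`` is "probability" for the forest and admixture
    methods; PCA-Distance reports normalized inverse distances, which
    share the same shape but are not probabilities.
    """

    sample_id: str
    proportions: dict[str, float]
    assigned_group: str
    score_type: str = "probability"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.proportions.values()):
            raise ValueError("proportions must be nonnegative")
        if self.assigned_group != _argmax_group(self.proportions):
            raise ValueError("assigned_group must be the (lexicographic-tie) argmax")


def _argmax_group(proportions: dict[str, float]) -> str:
    best = max(proportions.values())
    return min(g for g, v in proportions.items() if v == best)


@dataclass
class AdmixtureFit:
    """Supervised-admixture solution over concatenated reference + query rows."""

    sample_ids: list[str]
    groups: list[str]
    Q: np.ndarray
    F: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    n_reference: int = 0

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each Q row must sum to 1")
        if np.any(self.Q < -1e-12):
            raise ValueError("Q entries must be nonnegative")
        if np.any(self.F < F_EPS - 1e-15) or np.any(self.F > 1 - F_EPS + 1e-15):
            raise ValueError("F entries must lie in [eps, 1-eps]")

    @property
    def query_Q(self) -> np.ndarray:
        return self.Q[self.n_reference:]

    @property
    def query_sample_ids(self) -> list[str]:
        return self.sample_ids[self.n_reference:]


# ---------------------------------------------------------------------------
# PCA-based classifiers
# ---------------------------------------------------------------------------

def centroid_classify(
    ref_scores: np.ndarray,
    ref_groups: Sequence[str],
    query_scores: np.ndarray,
    query_ids: Sequence[str],
) -> list[AncestryCall]:
    """Assign each query to the ancestry group with the nearest centroid.

    Centroids are per-group means of the reference PC scores over all
    components. Reported scores are inverse distances normalized to sum
    to 1 (``score_type="inverse_distance"``); a query exactly on a
    centroid gets that group with score 1.
    """
    ref_scores = np.asarray(ref_scores, dtype=float)
    query_scores = np.asarray(query_scores, dtype=float)
    if ref_scores.shape[1] != query_scores.shape[1]:
        raise ValueError("reference and query scores must share dimensionality")
    if len(ref_scores) == 0:
        raise ValueError("empty reference scores: every group needs members")
    groups = sorted(set(ref_groups))
    labels = np.asarray(ref_groups, dtype=object)
    centroids = []
    for g in groups:
        members = ref_scores[labels == g]
        if len(members) == 0:
            raise ValueError(f"empty ancestry group {g!r}")
        centroids.append(members.mean(axis=0))
    cent = np.vstack(centroids)
    dists = np.linalg.norm(query_scores[:, None, :] - cent[None, :, :], axis=2)
    calls = []
    for i, sid in enumerate(query_ids):
        d = dists[i]
        if np.any(d == 0.0):
            inv = (d == 0.0).astype(float)
        else:
            inv = 1.0 / d
        props = dict(zip(groups, inv / inv.sum()))
        calls.append(
            AncestryCall(sid, props, _argmax_group(props), score_type="inverse_distance")
        )
    return calls


def rf_classify(
    ref_scores: np.ndarray,
    ref_groups: Sequence[str],
    query_scores: np.ndarray,
    query_ids: Sequence[str],
    n_trees: int = 100,
    seed: int = 0,
) -> list[AncestryCall]:
    """Random forest on reference PC scores; proportions = class probabilities.

    100 unlimited-depth trees with a fixed seed by default, class
    probabilities by tree-vote averaging. Identical inputs and seed
    give identical probabilities.
    """
    from sklearn.ensemble import RandomForestClassifier

    groups = sorted(set(ref_groups))
    if len(groups) < 2:
        raise ValueError("random forest needs at least 2 ancestry groups")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    clf.fit(np.asarray(ref_scores, dtype=float), np.asarray(ref_groups))
    proba = clf.predict_proba(np.asarray(query_scores, dtype=float))
    class_order = list(clf.classes_)
    calls = []
    for i, sid in enumerate(query_ids):
        props = {g: float(proba[i, class_order.index(g)]) for g in groups}
        calls.append(AncestryCall(sid, props, _argmax_group(props)))
    return calls


# ---------------------------------------------------------------------------
# Supervised admixture (binomial-mixture EM)
# ---------------------------------------------------------------------------

def group_frequencies(ref: ReferencePanel) -> tuple[list[str], np.ndarray]:
    """Observed per-group ALT frequencies, clamped to [eps, 1-eps].

    Returns (groups sorted lexicographically, K x M frequency matrix).
    A group with zero non-missing calls at a SNP falls back to the
    panel-wide frequency there, with a warning.
    """
    m = ref.genotypes
    groups = ref.groups
    observed = m.dosages != MISSING
    dos = np.where(observed, m.dosages, 0).astype(float)
    panel_n = observed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        panel_freq = dos.sum(axis=0) / (2.0 * panel_n)
    panel_freq = np.nan_to_num(panel_freq, nan=0.5)
    F = np.empty((len(groups), m.n_snps))
    for k, g in enumerate(groups):
        rows = ref.ancestry_group == g
        n_k = observed[rows].sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_k = dos[rows].sum(axis=0) / (2.0 * n_k)
        empty = n_k == 0
        if empty.any():
            logger.warning(
                "group %s has no calls at %d SNPs; using panel-wide frequency",
                g, int(empty.sum()),
            )
            f_k[empty] = panel_freq[empty]
        F[k] = f_k
    return groups, np.clip(F, F_EPS, 1.0 - F_EPS)


def _dosage_array(G: GenotypeMatrix | np.ndarray) -> np.ndarray:
    return G.dosages if isinstance(G, GenotypeMatrix) else np.asarray(G)


def admixture_loglik(
    G: GenotypeMatrix | np.ndarray, Q: np.ndarray, F: np.ndarray
) -> float:
    """Binomial-mixture log-likelihood; missing genotypes contribute 0.

    l = sum_ij [ g_ij ln(sum_k q_ik f_kj) + (2 - g_ij) ln(sum_k q_ik (1 - f_kj)) ]
    over non-missing cells (the binomial coefficient, a constant, is
    omitted, matching the usual admixture-likelihood convention).
    """
    dos = _dosage_array(G)
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if np.isnan(Q).any() or np.isnan(F).any():
        raise ValueError("NaN in Q or F")
    observed = dos != MISSING
    g = np.where(observed, dos, 0).astype(float)
    pa = np.clip(Q @ F, 1e-300, None)
    pb = np.clip(Q @ (1.0 - F), 1e-300, None)
    terms = g * np.log(pa) + (2.0 - g) * np.log(pb)
    return float(np.where(observed, terms, 0.0).sum())


def em_step(
    G: GenotypeMatrix | np.ndarray,
    Q: np.ndarray,
    F: np.ndarray,
    frozen_q_rows: Sequence[int] | None = None,
    frozen_F: bool = False,
    f_update_rows: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One EM update of (Q, F); never decreases the log-likelihood.

    E step: the 2 allele copies of cell (i, j) are attributed to
    ancestral group k with responsibility proportional to q_ik f_kj for
    ALT copies and q_ik (1 - f_kj) for REF copies. M step:

        q'_ik = sum_j (a_ijk + b_ijk) / (2 M_i)
        f'_kj = sum_i a_ijk / sum_i (a_ijk + b_ijk)

    with M_i the count of i's non-missing SNPs. Rows in
    ``frozen_q_rows`` keep their Q (supervised reference rows); F is
    untouched when ``frozen_F``; otherwise the F sums run over
    ``f_update_rows`` (default: all rows). A (k, j) with zero
    denominator keeps its F entry.
    """
    dos = _dosage_array(G)
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    observed = dos != MISSING
    g = np.where(observed, dos, 0).astype(float)
    g_ref = np.where(observed, 2.0 - dos, 0.0)

    pa = np.clip(Q @ F, 1e-300, None)          # N x M: P(ALT copy)
    pb = np.clip(Q @ (1.0 - F), 1e-300, None)
    ga = g / pa                                 # expected-count helpers
    gb = g_ref / pb

    # per-row responsibilities summed over SNPs: sum_j (a + b)
    alt_load = Q * (ga @ F.T)                   # N x K: sum_j a_ijk
    ref_load = Q * (gb @ (1.0 - F).T)           # N x K: sum_j b_ijk
    m_i = observed.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        Q_new = (alt_load + ref_load) / (2.0 * m_i)[:, None]
    Q_new = np.nan_to_num(Q_new, nan=1.0 / Q.shape[1])
    # simplex hygiene against float drift
    Q_new /= Q_new.sum(axis=1, keepdims=True)
    if frozen_q_rows is not None and len(frozen_q_rows) > 0:
        fr = np.asarray(frozen_q_rows)
        Q_new[fr] = Q[fr]

    if frozen_F:
        return Q_new, F.copy()

    rows = slice(None) if f_update_rows is None else np.asarray(f_update_rows)
    num = F * (Q[rows].T @ ga[rows])            # K x M: sum_i a_ijk
    den = num + (1.0 - F) * (Q[rows].T @ gb[rows])
    F_new = np.where(den > 0, num / np.where(den > 0, den, 1.0), F)
    return Q_new, np.clip(F_new, F_EPS, 1.0 - F_EPS)


def fit_supervised_admixture(
    ref: ReferencePanel,
    query: GenotypeMatrix,
    tol: float = 1e-6,
    max_iter: int = 2000,
    update_F_with_queries: bool = False,
) -> AdmixtureFit:
    """Supervised admixture fit: reference rows one-hot, query Q estimated.

    The query matrix must already be aligned to the reference SNPs
    (same ids, same order; use ``align_on_shared_snps`` first). F is
    initialized from the observed group frequencies. When
    ``update_F_with_queries`` is False (default), the one-hot reference
    rows make the group frequencies an exact fixed point of the F
    update, so F stays fixed and EM runs on the query rows only — the
    stationary points are identical to the joint update restricted to
    reference rows, just cheaper. When True, queries also contribute to
    F re-estimation each iteration (the behaviour of supervised
    ADMIXTURE-style tools).

    Convergence: iterate until the log-likelihood improves by less than
    ``tol`` (EM is monotone, so the signed change is the absolute one
    up to float round-off) or ``max_iter`` iterations.
    """
    if query.snp_ids != ref.genotypes.snp_ids:
        raise ValueError("query must be aligned to the reference SNPs "
                         "(same ids in the same order)")
    groups, F = group_frequencies(ref)
    K = len(groups)
    group_index = {g: k for k, g in enumerate(groups)}
    n_ref = ref.genotypes.n_samples
    n_query = query.n_samples

    Q_ref = np.zeros((n_ref, K))
    for i, g in enumerate(ref.ancestry_group):
        Q_ref[i, group_index[g]] = 1.0
    Q_query = np.full((n_query, K), 1.0 / K)

    sample_ids = list(ref.genotypes.sample_ids) + list(query.sample_ids)
    trace: list[float] = []
    converged = False

    if not update_F_with_queries:
        # F fixed at the group frequencies (exact fixed point; see docstring)
        ref_ll = admixture_loglik(ref.genotypes, Q_ref, F)
        G_q = query.dosages
        ll = ref_ll + admixture_loglik(G_q, Q_query, F)
        trace.append(ll)
        it = 0
        for it in range(1, max_iter + 1):
            Q_query, _ = em_step(G_q, Q_query, F, frozen_F=True)
            new_ll = ref_ll + admixture_loglik(G_q, Q_query, F)
            if not np.isfinite(new_ll):
                raise FloatingPointError(f"non-finite likelihood at iteration {it}")
            delta, ll = new_ll - ll, new_ll
            trace.append(ll)
            if delta < tol:
                converged = True
                break
        Q_all = np.vstack([Q_ref, Q_query]) if n_query else Q_ref
        n_it = it
    else:
        G_all = (
            np.vstack([ref.genotypes.dosages, query.dosages])
            if n_query else ref.genotypes.dosages
        )
        Q_all = np.vstack([Q_ref, Q_query]) if n_query else Q_ref
        frozen = np.arange(n_ref)
        ll = admixture_loglik(G_all, Q_all, F)
        trace.append(ll)
        it = 0
        for it in range(1, max_iter + 1):
            Q_all, F = em_step(G_all, Q_all, F, frozen_q_rows=frozen)
            new_ll = admixture_loglik(G_all, Q_all, F)
            if not np.isfinite(new_ll):
                raise FloatingPointError(f"non-finite likelihood at iteration {it}")
            delta, ll = new_ll - ll, new_ll
            trace.append(ll)
            if delta < tol:
                converged = True
                break
        n_it = it

    return AdmixtureFit(
        sample_ids=sample_ids,
        groups=groups,
        Q=Q_all,
        F=F,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_it,
        n_reference=n_ref,
    )


def assign_from_proportions(
    fit_or_probs: AdmixtureFit | tuple[Sequence[str], Sequence[str], np.ndarray],
    queries_only: bool = True,
) -> list[AncestryCall]:
    """Argmax assignment (lexicographic tie-break) from proportion rows.

    Accepts an :class:`AdmixtureFit` (by default only its query rows
    are assigned) or a ``(sample_ids, groups, matrix)`` triple. A row
    of all zeros is an error.
    """
    if isinstance(fit_or_probs, AdmixtureFit):
        groups = fit_or_probs.groups
        if queries_only:
            ids, mat = fit_or_probs.query_sample_ids, fit_or_probs.query_Q
        else:
            ids, mat = fit_or_probs.sample_ids, fit_or_probs.Q
    else:
        ids, groups, mat = fit_or_probs
        groups = list(groups)
    mat = np.asarray(mat, dtype=float)
    calls = []
    for i, sid in enumerate(ids):
        row = mat[i]
        if np.any(row < 0):
            raise ValueError(f"negative proportion for sample {sid!r}")
        if row.max() <= 0:
            raise ValueError(f"all-zero proportion row for sample {sid!r}")
        props = dict(zip(groups, (float(v) for v in row)))
        calls.append(AncestryCall(sid, props, _argmax_group(props)))
    return calls
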