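"""Evaluation harnesses: leave-one-population-out error, error sweeps,
admixture-proportion recovery, and within-group inference.

The central design is strict leave-out: for every fold the held-out
population is removed from the reference *before* LD pruning, PCA, and
group-frequency estimation, so no information about the removed
population leaks into the model it is classified with. Genotype errors
are injected only into the held-out (query) genotypes, emulating noisy
variant calls queried against a clean reference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    assign_from_proportions,
    centroid_classify,
    fit_supervised_admixture,
    group_frequencies,
    rf_classify,
    AdmixtureFit,
)
from .genotype import GenotypeMatrix, ReferencePanel
from .pca import fit_reference_pca, project
from .qc import PruneParams, ld_prune
from .simulate import inject_genotype_errors

logger = logging.getLogger(__name__)

METHODS = ("distance", "rf", "admixture")
CONDITIONS = ("all_snps", "sc_snps", "sc_snps_error")

_Z95 = float(stats.norm.ppf(0.975))


def wilson_ci(k: int, n: int) -> tuple[float, float]:
    """95% Wilson score interval for an error proportion k / n.

    Well-behaved at the boundary: k = 0 gives a lower bound of exactly
    0 and k = n an upper bound of exactly 1, which matters for the
    near-zero error rates this evaluation produces.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0 and n > 0:
        lo = 0.0
    else:
        lo = _wilson_bound(k, n, -1.0)
    if k == n:
        hi = 1.0
    else:
        hi = _wilson_bound(k, n, +1.0)
    return lo, hi


def _wilson_bound(k: int, n: int, sign: float) -> float:
    z = _Z95
    p = k / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2 * n)
    spread = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return float(np.clip((centre + sign * spread) / denom, 0.0, 1.0))


@dataclass
class EvaluationResult:
    """Classification evaluation: confusion matrix and error rates with CIs."""

    method: str
    condition: str
    confusion: pd.DataFrame          # rows = true group, cols = predicted
    per_group_error: dict[str, tuple[float, float, float]]
    overall_error: tuple[float, float, float]
    per_population_error: dict[str, tuple[float, float, float]]
    error_rate: float = 0.0
    failed_folds: list[str] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return int(self.confusion.to_numpy().sum())


@dataclass
class RecoveryResult:
    """OLS concordance of estimated vs true admixture proportions."""

    slope: float
    intercept: float
    pearson_r: float
    n: int
    pairs: pd.DataFrame   # columns: truth, estimate

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need at least 3 paired values")
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("invalid correlation")


def admixture_recovery(
    truth_q: Sequence[float], est_q: Sequence[float]
) -> RecoveryResult:
    """OLS (with intercept) of estimate on truth, plus Pearson r."""
    truth = np.asarray(truth_q, dtype=float)
    est = np.asarray(est_q, dtype=float)
    if truth.shape != est.shape or truth.ndim != 1:
        raise ValueError("truth and estimate must be equal-length vectors")
    if len(truth) < 3:
        raise ValueError("need at least 3 paired values")
    if np.var(truth) == 0:
        raise ValueError("zero variance in truth proportions")
    fit = stats.linregress(truth, est)
    return RecoveryResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n=len(truth),
        pairs=pd.DataFrame({"truth": truth, "estimate": est}),
    )


def gold_standard_selection(
    fit_full: AdmixtureFit, group: str, threshold: float = 1.0 / 8.0
) -> pd.DataFrame:
    """Select query samples with estimated ``group`` proportion strictly > threshold.

    Mirrors the admixed-cohort rule "more than 1/8" ancestry from the
    full SNP panel: a sample at exactly the threshold is excluded. The
    returned frame pairs each selected sample with its full-panel
    proportion, to be used as the gold standard for sparse-panel runs.
    """
    if group not in fit_full.groups:
        raise KeyError(f"group {group!r} not in fit groups {fit_full.groups}")
    k = fit_full.groups.index(group)
    props = fit_full.query_Q[:, k]
    sel = props > threshold
    if not sel.any():
        warnings.warn(f"no sample exceeds {threshold:g} {group} ancestry")
    return pd.DataFrame(
        {
            "sample_id": [s for s, keep in zip(fit_full.query_sample_ids, sel) if keep],
            "gold_proportion": props[sel],
        }
    )


# ---------------------------------------------------------------------------
# Leave-one-population-out machinery
# ---------------------------------------------------------------------------

def _prepare_reference(
    ref: ReferencePanel,
    method: str,
    prune_params: PruneParams,
    n_components: int,
) -> dict:
    """Per-fold model prep on the reduced reference: prune, then PCA or F."""
    kept = ld_prune(ref.genotypes, prune_params)
    ref_pruned = ref.subset_snp_ids(kept)
    prep = {"panel": ref_pruned, "kept_snps": kept}
    if method in ("distance", "rf"):
        model = fit_reference_pca(ref_pruned, n_components=n_components)
        prep["pca"] = model
        prep["ref_scores"] = model.reference_scores
    return prep


def _infer(
    prep: dict, query: GenotypeMatrix, method: str, rf_seed: int, n_trees: int
) -> list[str]:
    """Classify query samples against a prepared reference; returns groups."""
    ref: ReferencePanel = prep["panel"]
    query = query.subset_snp_ids(prep["kept_snps"])
    if method == "distance":
        scores = project(prep["pca"], query)
        calls = centroid_classify(
            prep["ref_scores"], ref.ancestry_group, scores, query.sample_ids
        )
    elif method == "rf":
        scores = project(prep["pca"], query)
        calls = rf_classify(
            prep["ref_scores"], ref.ancestry_group, scores, query.sample_ids,
            n_trees=n_trees, seed=rf_seed,
        )
    elif method == "admixture":
        fit = fit_supervised_admixture(ref, query)
        calls = assign_from_proportions(fit)
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return [c.assigned_group for c in calls]


def _summarize(
    records: list[tuple[str, str, str, str]],
    groups: list[str],
    method: str,
    condition: str,
    error_rate: float,
    failed: list[str],
) -> EvaluationResult:
    """Aggregate (sample, population, true group, predicted) into a result."""
    confusion = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    pop_counts: dict[str, list[int]] = {}
    for _sid, pop, true_g, pred_g in records:
        confusion.loc[true_g, pred_g] += 1
        k_n = pop_counts.setdefault(pop, [0, 0])
        k_n[0] += int(pred_g != true_g)
        k_n[1] += 1
    per_group = {}
    for g in groups:
        n_g = int(confusion.loc[g].sum())
        if n_g == 0:
            continue
        k_g = n_g - int(confusion.loc[g, g])
        per_group[g] = (k_g / n_g, *wilson_ci(k_g, n_g))
    total = int(confusion.to_numpy().sum())
    wrong = total - int(np.trace(confusion.to_numpy()))
    overall = (wrong / total, *wilson_ci(wrong, total)) if total else (np.nan, np.nan, np.nan)
    per_pop = {p: (k / n, *wilson_ci(k, n)) for p, (k, n) in sorted(pop_counts.items())}
    return EvaluationResult(
        method=method, condition=condition, confusion=confusion,
        per_group_error=per_group, overall_error=overall,
        per_population_error=per_pop, error_rate=error_rate, failed_folds=failed,
    )


def _lopo_run(
    panel: ReferencePanel,
    method: str,
    rates: Sequence[float],
    snp_subset: Sequence[str] | None,
    seed: int,
    prune_params: PruneParams,
    n_components: int,
    n_trees: int,
    condition_of_rate,
) -> dict[float, EvaluationResult]:
    """Shared-fold LOPO over several error rates.

    Fold preparation (reduced reference, pruning, PCA / frequencies) is
    computed once per population and reused for every rate; the
    error-injection stream and the forest seed are derived per fold
    from ``seed`` and do not depend on the rate, so a rate of 0
    reproduces the error-free run bit for bit.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    if snp_subset is not None:
        panel = panel.subset_snp_ids(list(snp_subset))
    groups = panel.groups
    populations = panel.populations
    root = np.random.SeedSequence(seed)
    fold_seeds = root.spawn(len(populations))

    per_rate_records: dict[float, list] = {r: [] for r in rates}
    failed: dict[float, list[str]] = {r: [] for r in rates}
    for fold_i, pop in enumerate(populations):
        group_of_pop = panel.group_of_population(pop)
        query_idx = np.nonzero(panel.population == pop)[0]
        query = panel.genotypes.take_samples(query_idx)
        reduced = panel.drop_population(pop)
        remaining_in_group = set(
            reduced.population[reduced.ancestry_group == group_of_pop]
        )
        if len(remaining_in_group) < 2:
            warnings.warn(
                f"group {group_of_pop!r} has fewer than 2 populations left "
                f"after removing {pop!r}"
            )
        err_seed, rf_seed_seq = fold_seeds[fold_i].spawn(2)
        rf_seed = int(rf_seed_seq.generate_state(1)[0] % (2**31))
        try:
            prep = _prepare_reference(reduced, method, prune_params, n_components)
        except Exception as exc:  # fold-level failure: record, continue
            logger.error("fold %s: reference prep failed: %s", pop, exc)
            for r in rates:
                failed[r].append(pop)
            continue
        for r in rates:
            q = inject_genotype_errors(query, r, np.random.default_rng(err_seed)) \
                if r > 0 else query
            try:
                preds = _infer(prep, q, method, rf_seed, n_trees)
            except Exception as exc:
                logger.error("fold %s (rate %g): inference failed: %s", pop, r, exc)
                failed[r].append(pop)
                continue
            per_rate_records[r] += [
                (sid, pop, group_of_pop, pred)
                for sid, pred in zip(q.sample_ids, preds)
            ]
    return {
        r: _summarize(per_rate_records[r], groups, method, condition_of_rate(r),
                      r, failed[r])
        for r in rates
    }


def leave_one_population_out(
    panel: ReferencePanel,
    method: str = "admixture",
    condition: str = "sc_snps",
    error_rate: float = 0.08,
    snp_subset: Sequence[str] | None = None,
    seed: int = 0,
    prune_params: PruneParams = PruneParams(),
    n_components: int = 5,
    n_trees: int = 100,
) -> EvaluationResult:
    """Leave-one-population-out evaluation of one method under one condition.

    For each population, its individuals are removed from the
    reference, the model is refit from scratch on the remainder
    (pruning included), the held-out individuals — restricted to
    ``snp_subset`` if given, with genotype errors injected at
    ``error_rate`` under the ``sc_snps_error`` condition — are
    classified, and assignments are compared to the population's true
    ancestry group.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    rate = error_rate if condition == "sc_snps_error" else 0.0
    out = _lopo_run(
        panel, method, [rate], snp_subset, seed, prune_params,
        n_components, n_trees, condition_of_rate=lambda r: condition,
    )
    return out[rate]


def error_rate_sweep(
    panel: ReferencePanel,
    method: str = "admixture",
    rates: Sequence[float] = (0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12),
    snp_subset: Sequence[str] | None = None,
    seed: int = 0,
    prune_params: PruneParams = PruneParams(),
    n_components: int = 5,
    n_trees: int = 100,
) -> dict[float, EvaluationResult]:
    """LOPO across a grid of genotype-error rates with shared folds.

    Only the error injection differs between rates; rate 0 equals the
    plain no-error LOPO bit for bit under the same seed.
    """
    rates = list(rates)
    if rates != sorted(rates):
        raise ValueError("rates must be sorted ascending")
    return _lopo_run(
        panel, method, rates, snp_subset, seed, prune_params,
        n_components, n_trees,
        condition_of_rate=lambda r: "sc_snps" if r == 0 else "sc_snps_error",
    )


def within_group_inference(
    panel: ReferencePanel,
    group: str,
    method: str = "admixture",
    condition: str = "sc_snps",
    error_rate: float = 0.08,
    seed: int = 0,
    prune_params: PruneParams = PruneParams(),
    n_components: int = 5,
    n_trees: int = 100,
) -> EvaluationResult:
    """Sub-population inference inside one ancestry group.

    The group's populations become the classes and evaluation is
    leave-one-individual-out (populations cannot be held out wholesale
    or their class would vanish): for each individual, the model is
    refit on the group minus that individual and the individual is
    classified among the group's populations. Singleton populations are
    excluded with a warning.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    idx = np.nonzero(panel.ancestry_group == group)[0]
    if len(idx) == 0:
        raise KeyError(f"no samples in group {group!r}")
    sub_pops = panel.population[idx]
    pop_sizes = pd.Series(sub_pops).value_counts()
    keep_pops = set(pop_sizes[pop_sizes >= 2].index)
    dropped = set(pop_sizes.index) - keep_pops
    if dropped:
        warnings.warn(f"excluding singleton populations {sorted(dropped)}")
    if len(keep_pops) < 2:
        raise ValueError(f"group {group!r} needs >= 2 non-singleton populations")
    idx = idx[np.isin(sub_pops, list(keep_pops))]
    # re-label: population becomes the class ("ancestry group") so the whole
    # classification stack can be reused unchanged (a single-group subset is
    # never materialized as a panel, which would violate the K >= 2 invariant)
    relabelled = ReferencePanel(
        panel.genotypes.take_samples(idx), panel.population[idx],
        panel.population[idx],
    )

    rate = error_rate if condition == "sc_snps_error" else 0.0
    n = relabelled.genotypes.n_samples
    root = np.random.SeedSequence(seed)
    fold_seeds = root.spawn(n)
    records, failed = [], []
    for i in range(n):
        rest = relabelled.take_samples([j for j in range(n) if j != i])
        query = relabelled.genotypes.take_samples([i])
        true_pop = str(relabelled.ancestry_group[i])
        err_seed, rf_seed_seq = fold_seeds[i].spawn(2)
        rf_seed = int(rf_seed_seq.generate_state(1)[0] % (2**31))
        if rate > 0:
            query = inject_genotype_errors(query, rate, np.random.default_rng(err_seed))
        try:
            prep = _prepare_reference(rest, method, prune_params, n_components)
            pred = _infer(prep, query, method, rf_seed, n_trees)[0]
        except Exception as exc:
            logger.error("within-group fold %s: %s", query.sample_ids[0], exc)
            failed.append(query.sample_ids[0])
            continue
        records.append((query.sample_ids[0], true_pop, true_pop, pred))
    return _summarize(records, sorted(keep_pops), method, condition, rate, failed)
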