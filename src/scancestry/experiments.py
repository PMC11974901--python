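"""Canned benchmark experiments at desk scale.

Two study designs are packaged here so that tests, scripts, and users
run exactly the same procedures:

* :func:`recovery_experiment` — admixture-proportion recovery: a flat
  K-group reference (Balding–Nichols, FST 0.1), admixed queries with
  Dirichlet(1,...,1) mixing proportions, supervised-admixture fits on
  clean and on error-injected genotypes, and per-component OLS
  concordance of estimate against the generating truth.
* :func:`lopo_experiment` — leave-one-population-out classification
  on the default hierarchical panel (6 groups x 3 populations x 20
  samples, 3,000 SNPs), for any of the three methods, across a grid of
  injected genotype-error rates.

Both are pure functions of their parameters and seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .classify import fit_supervised_admixture
from .evaluate import (
    EvaluationResult,
    RecoveryResult,
    admixture_recovery,
    error_rate_sweep,
    leave_one_population_out,
)
from .genotype import GenotypeMatrix, ReferencePanel
from .simulate import (
    SimScenario,
    _make_snp_records,
    inject_genotype_errors,
    make_scenario,
    sample_admixed_genotypes,
    sample_frequencies,
    sample_genotypes,
)


def simulate_flat_panel(
    n_groups: int, n_per_group: int, n_snps: int, fst: float, seed,
) -> tuple[ReferencePanel, np.ndarray]:
    """One population per ancestry group, drawn directly at the group level.

    Returns the labelled panel and the true group frequency matrix
    (useful for generating admixed queries from the same frequencies).
    """
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_freq, ss_geno = root.spawn(2)
    _, group_F = sample_frequencies(n_snps, n_groups, fst, ss_freq)
    snps = _make_snp_records(n_snps)
    names = [f"G{k + 1}" for k in range(n_groups)]
    blocks, grps, ids = [], [], []
    for k, child in enumerate(ss_geno.spawn(n_groups)):
        gm = sample_genotypes(group_F[k], n_per_group, child,
                              sample_prefix=f"{names[k]}_", snps=snps)
        blocks.append(gm.dosages)
        grps += [names[k]] * n_per_group
        ids += gm.sample_ids
    panel = ReferencePanel(
        GenotypeMatrix(ids, snps, np.vstack(blocks)),
        np.array(grps, dtype=object), np.array(grps, dtype=object),
    )
    return panel, group_F


def recovery_experiment(
    seed: int = 0,
    n_groups: int = 3,
    n_per_group: int = 100,
    n_snps: int = 5000,
    fst: float = 0.1,
    n_queries: int = 50,
    error_rate: float = 0.08,
) -> dict[str, list[RecoveryResult]]:
    """Admixture-proportion recovery against the generating truth.

    Returns per-component :class:`RecoveryResult` lists under keys
    ``"clean"`` (error-free genotypes) and ``"error"`` (genotypes with
    ``error_rate`` uniform-substitution errors injected), components
    ordered as the fit's (lexicographic) group order.
    """
    root = np.random.SeedSequence(seed)
    ss_panel, ss_q, ss_admix, ss_err = root.spawn(4)
    panel, group_F = simulate_flat_panel(n_groups, n_per_group, n_snps, fst, ss_panel)
    snps = panel.genotypes.snps

    q_rng = np.random.default_rng(ss_q)
    truth_q = q_rng.dirichlet(np.ones(n_groups), size=n_queries)
    blocks = [
        sample_admixed_genotypes(group_F, q, 1, child, snps=snps).dosages
        for q, child in zip(truth_q, ss_admix.spawn(n_queries))
    ]
    queries = GenotypeMatrix(
        [f"Q{i + 1:03d}" for i in range(n_queries)], snps, np.vstack(blocks)
    )
    noisy = inject_genotype_errors(queries, error_rate, ss_err)

    out: dict[str, list[RecoveryResult]] = {}
    for label, q_matrix in (("clean", queries), ("error", noisy)):
        fit = fit_supervised_admixture(panel, q_matrix)
        out[label] = [
            admixture_recovery(truth_q[:, k], fit.query_Q[:, k])
            for k in range(n_groups)
        ]
    return out


def lopo_experiment(
    seed: int = 0,
    method: str = "admixture",
    rates: Sequence[float] = (0.0, 0.02, 0.04, 0.06, 0.08, 0.10, 0.12),
    scenario: SimScenario | None = None,
) -> dict[float, EvaluationResult]:
    """Leave-one-population-out error across genotype-error rates.

    The panel is the default hierarchical scenario (regenerated from
    ``seed``); folds are shared across rates so only error injection
    varies. Passing a single rate reduces to a plain LOPO run.
    """
    root = np.random.SeedSequence(seed)
    ss_panel, ss_eval = root.spawn(2)
    if scenario is None:
        scenario = SimScenario(seed=int(ss_panel.generate_state(1)[0] % (2**31)))
    panel, _, _ = make_scenario(scenario)
    eval_seed = int(ss_eval.generate_state(1)[0] % (2**31))
    rates = list(rates)
    if len(rates) == 1:
        condition = "sc_snps" if rates[0] == 0 else "sc_snps_error"
        res = leave_one_population_out(
            panel, method=method, condition=condition,
            error_rate=rates[0], seed=eval_seed,
        )
        return {rates[0]: res}
    return error_rate_sweep(panel, method=method, rates=rates, seed=eval_seed)
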