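"""Synthetic reference panels, admixed queries, sparsity, and genotype errors.

Stands in for a harmonized worldwide reference panel (continental
ancestry groups each containing several populations) and for the
sparse, error-prone genotypes recoverable from scRNA-seq reads.
Allele-frequency differentiation follows the Balding–Nichols model:
per-group frequencies are Beta(p(1-F)/F, (1-p)(1-F)/F) draws around an
ancestral frequency p (so E[f] = p, Var[f] = p(1-p)·F), with a second
nested draw inside each group for its populations. Genotypes are
Hardy-Weinberg binomial draws; SNPs are independent (no LD is
simulated). Admixed individuals draw each of their two allele copies
from group k with probability q_k, which is exactly the generative
model the supervised-admixture likelihood assumes.

All generators are pure functions of (parameters, seed): a single
scenario seed is expanded into per-operation substreams, so repeated
calls are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genotype import MISSING, GenotypeMatrix, ReferencePanel, SnpRecord

#: Continental-scale group names used when K <= 6.
DEFAULT_GROUP_NAMES = ("AFR", "AMR", "EAS", "EUR", "MID", "SAS")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimScenario:
    """A complete simulation recipe.

    Defaults mirror the leave-one-population-out study conditions: 6
    ancestry groups x 3 populations x 20 samples over 3,000 common
    SNPs (the sc-SNP scale), between-group differentiation FST 0.1,
    within-group FST 0.01, ancestral MAF floor 0.05. Missingness and
    genotype errors default to 0 because the evaluation layer injects
    them per condition; set them here to bake them into the query set.
    ``admixed_specs`` lists (q vector over groups, count) pairs for
    admixed query individuals.
    """

    n_groups: int = 6
    populations_per_group: int = 3
    samples_per_population: int = 20
    n_snps: int = 3000
    fst_between: float = 0.1
    fst_within: float = 0.01
    maf_floor: float = 0.05
    missing_rate: float = 0.0
    error_rate: float = 0.0
    admixed_specs: Sequence[tuple[Sequence[float], int]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst_within < self.fst_between < 1:
            raise ValueError("need 0 < fst_within < fst_between < 1")
        for rate in (self.missing_rate, self.error_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if not 0 <= self.maf_floor < 0.5:
            raise ValueError("maf_floor must lie in [0, 0.5)")
        for q, count in self.admixed_specs:
            q = np.asarray(q, dtype=float)
            if len(q) != self.n_groups or np.any(q < 0) or abs(q.sum() - 1) > 1e-8:
                raise ValueError("each admixed q must be a simplex vector of length K")
            if count < 0:
                raise ValueError("admixed counts must be nonnegative")

    @property
    def group_names(self) -> list[str]:
        if self.n_groups <= len(DEFAULT_GROUP_NAMES):
            return list(DEFAULT_GROUP_NAMES[: self.n_groups])
        return [f"GRP{k + 1:02d}" for k in range(self.n_groups)]


def sample_frequencies(
    n_snps: int, n_groups: int, fst: float, seed, maf_floor: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral p ~ Uniform(floor, 1-floor) and Balding–Nichols group draws.

    Returns (p of length M, K x M group frequency matrix). As fst -> 0
    the Beta variance p(1-p)·fst vanishes and group frequencies
    collapse onto p.
    """
    if not 0 < fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    rng = _rng(seed)
    p = rng.uniform(maf_floor, 1.0 - maf_floor, size=n_snps)
    a = p * (1.0 - fst) / fst
    b = (1.0 - p) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_groups, n_snps))
    return p, np.clip(freqs, 1e-9, 1.0 - 1e-9)


def sample_population_frequencies_nested(
    group_freqs: np.ndarray, fst_within: float, seed, populations_per_group: int = 1
) -> np.ndarray:
    """Second Balding–Nichols draw: populations nested inside each group.

    Returns a (K, P, M) array; E[f_pop] = f_group, and as fst_within ->
    0 the populations collapse onto their group.
    """
    if not 0 < fst_within < 1:
        raise ValueError("fst_within must lie in (0, 1)")
    rng = _rng(seed)
    g = np.asarray(group_freqs, dtype=float)
    a = g * (1.0 - fst_within) / fst_within
    b = (1.0 - g) * (1.0 - fst_within) / fst_within
    out = rng.beta(
        np.broadcast_to(a, (populations_per_group,) + g.shape),
        np.broadcast_to(b, (populations_per_group,) + g.shape),
    )
    return np.clip(np.moveaxis(out, 0, 1), 1e-9, 1.0 - 1e-9)


def _make_snp_records(n_snps: int) -> list[SnpRecord]:
    # non-strand-ambiguous allele pairs, cycled; 1 kb spacing on chrom 1
    pairs = (("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"))
    return [
        SnpRecord(f"1:{(j + 1) * 1000}:{r}:{a}", "1", (j + 1) * 1000, r, a)
        for j, (r, a) in ((j, pairs[j % 4]) for j in range(n_snps))
    ]


def sample_genotypes(
    freqs: np.ndarray, n: int, seed, sample_prefix: str = "S",
    snps: list[SnpRecord] | None = None,
) -> GenotypeMatrix:
    """Hardy-Weinberg genotypes: g_ij ~ Binomial(2, f_j), independent SNPs."""
    rng = _rng(seed)
    freqs = np.asarray(freqs, dtype=float)
    dosages = rng.binomial(2, freqs, size=(n, len(freqs))).astype(np.int8)
    if snps is None:
        snps = _make_snp_records(len(freqs))
    ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(ids, snps, dosages)


def sample_admixed_genotypes(
    pop_freqs: np.ndarray, q: Sequence[float], n: int, seed,
    sample_prefix: str = "Q", snps: list[SnpRecord] | None = None,
) -> GenotypeMatrix:
    """Admixed genotypes: each allele copy from group k w.p. q_k, then Bernoulli(f_kj).

    The marginal ALT probability per copy is sum_k q_k f_kj, matching
    the admixture likelihood's mixture exactly.
    """
    rng = _rng(seed)
    F = np.asarray(pop_freqs, dtype=float)
    q = np.asarray(q, dtype=float)
    if abs(q.sum() - 1.0) > 1e-8 or np.any(q < 0):
        raise ValueError("q must be a simplex vector")
    K, M = F.shape
    dosages = np.zeros((n, M), dtype=np.int8)
    for _copy in range(2):
        origins = rng.choice(K, size=(n, M), p=q)
        alt = rng.random((n, M)) < F[origins, np.arange(M)[None, :]]
        dosages += alt.astype(np.int8)
    if snps is None:
        snps = _make_snp_records(M)
    ids = [f"{sample_prefix}{i + 1:04d}" for i in range(n)]
    return GenotypeMatrix(ids, snps, dosages)


def subsample_snps(m: GenotypeMatrix, target_count: int, seed) -> GenotypeMatrix:
    """Uniform SNP subset without replacement, original order preserved."""
    if not 0 < target_count <= m.n_snps:
        raise ValueError("target_count must lie in [1, n_snps]")
    if target_count == m.n_snps:
        return m.take_snps(np.arange(m.n_snps))
    rng = _rng(seed)
    idx = np.sort(rng.choice(m.n_snps, size=target_count, replace=False))
    return m.take_snps(idx)


def inject_missingness(m: GenotypeMatrix, rate: float, seed) -> GenotypeMatrix:
    """Set each non-missing cell to missing independently with probability rate."""
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    if rate == 0:
        return GenotypeMatrix(list(m.sample_ids), list(m.snps), m.dosages.copy())
    rng = _rng(seed)
    dosages = m.dosages.copy()
    hit = (rng.random(dosages.shape) < rate) & (dosages != MISSING)
    dosages[hit] = MISSING
    return GenotypeMatrix(list(m.sample_ids), list(m.snps), dosages)


def inject_genotype_errors(m: GenotypeMatrix, rate: float, seed) -> GenotypeMatrix:
    """Replace each non-missing genotype, w.p. ``rate``, by one of the two others.

    The replacement is uniform over {0,1,2} minus the original value,
    so an altered cell never equals its original and the marginal
    discordance probability versus truth is exactly ``rate`` — the way
    an observed genotyping error rate (e.g. ~8% for scRNA-seq calls
    against SNP-array truth) is re-injected.
    """
    if not 0 <= rate <= 1:
        raise ValueError("rate must lie in [0, 1]")
    dosages = m.dosages.copy()
    if rate > 0:
        rng = _rng(seed)
        hit = (rng.random(dosages.shape) < rate) & (dosages != MISSING)
        # offset 1 or 2 mod 3 maps each genotype to one of the two others
        offsets = rng.integers(1, 3, size=dosages.shape).astype(np.int8)
        dosages[hit] = (dosages[hit] + offsets[hit]) % 3
    return GenotypeMatrix(list(m.sample_ids), list(m.snps), dosages)


def make_scenario(
    s: SimScenario,
) -> tuple[ReferencePanel, GenotypeMatrix, pd.DataFrame]:
    """Compose a full study: labelled reference panel, queries, truth table.

    Returns ``(panel, queries, truth)`` where truth has one row per
    query with its generating ancestry proportions (``q_<group>``
    columns) and ``true_group`` = argmax q (lexicographic tie-break).
    Missingness and genotype errors (if configured) apply to the query
    matrix only; the reference panel stays fully observed, as a curated
    reference would be.
    """
    root = np.random.SeedSequence(s.seed)
    (ss_freq, ss_nested, ss_geno, ss_admix, ss_miss, ss_err) = root.spawn(6)
    K, P, M = s.n_groups, s.populations_per_group, s.n_snps
    groups = s.group_names
    snps = _make_snp_records(M)

    _, group_F = sample_frequencies(M, K, s.fst_between, ss_freq, s.maf_floor)
    pop_F = sample_population_frequencies_nested(group_F, s.fst_within, ss_nested, P)

    geno_children = ss_geno.spawn(K * P)
    blocks, pops, grps, sample_ids = [], [], [], []
    for k, g in enumerate(groups):
        for p_i in range(P):
            pop_name = f"{g}_P{p_i + 1}"
            gm = sample_genotypes(
                pop_F[k, p_i], s.samples_per_population,
                geno_children[k * P + p_i],
                sample_prefix=f"{pop_name}_", snps=snps,
            )
            blocks.append(gm.dosages)
            pops += [pop_name] * s.samples_per_population
            grps += [g] * s.samples_per_population
            sample_ids += gm.sample_ids
    panel = ReferencePanel(
        GenotypeMatrix(sample_ids, snps, np.vstack(blocks)),
        np.array(pops, dtype=object),
        np.array(grps, dtype=object),
    )

    admix_children = ss_admix.spawn(max(len(s.admixed_specs), 1))
    q_blocks, truth_rows = [], []
    counter = 0
    for spec_i, (q, count) in enumerate(s.admixed_specs):
        if count == 0:
            continue
        gm = sample_admixed_genotypes(
            group_F, q, count, admix_children[spec_i],
            sample_prefix=f"ADM{spec_i + 1}_", snps=snps,
        )
        q_blocks.append(gm.dosages)
        q_arr = np.asarray(q, dtype=float)
        best = q_arr.max()
        true_group = min(g for g, v in zip(groups, q_arr) if v == best)
        for i in range(count):
            counter += 1
            row = {"sample_id": f"ADM{counter:04d}", "true_group": true_group}
            row.update({f"q_{g}": float(v) for g, v in zip(groups, q_arr)})
            truth_rows.append(row)
    if q_blocks:
        query_ids = [r["sample_id"] for r in truth_rows]
        queries = GenotypeMatrix(query_ids, snps, np.vstack(q_blocks))
        if s.missing_rate > 0:
            queries = inject_missingness(queries, s.missing_rate, ss_miss)
        if s.error_rate > 0:
            queries = inject_genotype_errors(queries, s.error_rate, ss_err)
    else:
        queries = GenotypeMatrix([], snps, np.zeros((0, M), dtype=np.int8))
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "true_group"] + [f"q_{g}" for g in groups],
    )
    return panel, queries, truth
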