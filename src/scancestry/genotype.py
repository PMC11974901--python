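"""Genotype matrices, reference panels, and standard-format I/O.

Dosages count the ALT allele of the reference panel: 0 (hom REF),
1 (het), 2 (hom ALT), with :data:`MISSING` (-1) as the in-memory
missing-genotype sentinel ("NA" on disk). Only biallelic SNVs are
supported; the reference panel is the single orientation authority,
so query matrices are strand/allele-reconciled against it with
:func:`align_on_shared_snps` before any joint analysis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: In-memory sentinel for a missing genotype. "NA" in the TSV dialect.
MISSING: int = -1

_VALID_ALLELES = frozenset("ACGT")
#: Strand-ambiguous allele pairs (indistinguishable after complement).
_AMBIGUOUS_PAIRS = frozenset({frozenset("AT"), frozenset("CG")})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeIOError(ValueError):
    """Malformed input file or inconsistent genotype data."""


@dataclass(frozen=True)
class SnpRecord:
    """Identity of one biallelic SNV: id, locus, and REF/ALT alleles."""

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.id}: pos must be >= 1, got {self.pos}")
        for allele in (self.ref_allele, self.alt_allele):
            if allele not in _VALID_ALLELES:
                raise ValueError(f"SNP {self.id}: invalid allele {allele!r}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.id}: REF equals ALT ({self.ref_allele})")

    @property
    def key(self) -> tuple[str, int]:
        """(chrom, pos) matching key; rsIDs are not trusted across call sets."""
        return (self.chrom, self.pos)

    @property
    def is_strand_ambiguous(self) -> bool:
        return frozenset((self.ref_allele, self.alt_allele)) in _AMBIGUOUS_PAIRS


@dataclass
class GenotypeMatrix:
    """Samples x SNPs ALT-dosage matrix with missing-data support.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per row of ``dosages``.
    snps
        One :class:`SnpRecord` per column of ``dosages``.
    dosages
        Integer matrix with entries in {0, 1, 2, MISSING}.
    """

    sample_ids: list[str]
    snps: list[SnpRecord]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.snps = list(self.snps)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-dimensional (samples x SNPs)")
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.snps):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len({s.id for s in self.snps}) != m:
            raise ValueError("SNP ids are not unique")
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid dosage {self.dosages[i, j]} at sample "
                f"{self.sample_ids[i]!r}, SNP {self.snps[j].id!r}"
            )

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.id for s in self.snps]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples x SNPs mask, True where the genotype is missing."""
        return self.dosages == MISSING

    # -- subsetting -----------------------------------------------------
    def take_samples(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.snps,
            self.dosages[idx, :].copy(),
        )

    def take_snps(self, idx: np.ndarray | list[int]) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=np.intp)
        return GenotypeMatrix(
            list(self.sample_ids),
            [self.snps[j] for j in idx],
            self.dosages[:, idx].copy(),
        )

    def subset_snp_ids(self, ids: list[str]) -> "GenotypeMatrix":
        """Restrict to the given SNP ids, preserving this matrix's order."""
        want = set(ids)
        idx = [j for j, s in enumerate(self.snps) if s.id in want]
        return self.take_snps(idx)


@dataclass
class ReferencePanel:
    """Labelled reference genotypes: per-sample population and ancestry group.

    Every population maps to exactly one of the K >= 2 ancestry groups
    (the continental-scale scheme: e.g. Africa, America, East Asia,
    Europe, Middle East, South Asia).
    """

    genotypes: GenotypeMatrix
    population: np.ndarray
    ancestry_group: np.ndarray

    def __post_init__(self) -> None:
        self.population = np.asarray(self.population, dtype=object)
        self.ancestry_group = np.asarray(self.ancestry_group, dtype=object)
        n = self.genotypes.n_samples
        if len(self.population) != n or len(self.ancestry_group) != n:
            raise ValueError("label arrays must have one entry per sample")
        if any(p is None or p == "" for p in self.population):
            raise ValueError("every sample needs a population label")
        if any(g is None or g == "" for g in self.ancestry_group):
            raise ValueError("every sample needs an ancestry_group label")
        mapping: dict[str, str] = {}
        for pop, grp in zip(self.population, self.ancestry_group):
            if mapping.setdefault(pop, grp) != grp:
                raise ValueError(
                    f"population {pop!r} maps to multiple ancestry groups"
                )
        if len(set(self.ancestry_group)) < 2:
            raise ValueError("a reference panel needs at least 2 ancestry groups")

    @property
    def groups(self) -> list[str]:
        """Ancestry-group labels, sorted lexicographically."""
        return sorted(set(self.ancestry_group))

    @property
    def populations(self) -> list[str]:
        return sorted(set(self.population))

    def group_of_population(self, pop: str) -> str:
        idx = np.nonzero(self.population == pop)[0]
        if len(idx) == 0:
            raise KeyError(f"no such population: {pop!r}")
        return str(self.ancestry_group[idx[0]])

    def take_samples(self, idx: np.ndarray | list[int]) -> "ReferencePanel":
        idx = np.asarray(idx)
        return ReferencePanel(
            self.genotypes.take_samples(idx),
            self.population[idx],
            self.ancestry_group[idx],
        )

    def drop_population(self, pop: str) -> "ReferencePanel":
        keep = np.nonzero(self.population != pop)[0]
        return self.take_samples(keep)

    def subset_snp_ids(self, ids: list[str]) -> "ReferencePanel":
        return ReferencePanel(
            self.genotypes.subset_snp_ids(ids), self.population, self.ancestry_group
        )


# ---------------------------------------------------------------------------
# VCF / metadata readers
# ---------------------------------------------------------------------------

def read_vcf(path: str, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read GT fields of a VCF/VCF.gz into a :class:`GenotypeMatrix`.

    Genotypes map as 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, ./. -> MISSING
    (phase is ignored). With ``biallelic_only``, multiallelic and
    non-SNV records are skipped; otherwise such records raise, since
    only biallelic SNVs have a dosage encoding here.
    """
    from cyvcf2 import VCF  # heavy import kept local

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # htslib raises plain Exceptions
        raise GenotypeIOError(f"cannot open VCF {path}: {exc}") from exc

    sample_ids = list(vcf.samples)
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
    lut = np.array([0, 1, MISSING, 2], dtype=np.int8)
    seen_ids: set[str] = set()
    try:
        for rec_no, variant in enumerate(vcf, start=1):
            alts = variant.ALT
            is_snv = (
                len(alts) == 1
                and len(variant.REF) == 1
                and len(alts[0]) == 1
                and variant.REF in _VALID_ALLELES
                and alts[0] in _VALID_ALLELES
            )
            if not is_snv:
                if biallelic_only:
                    continue
                raise GenotypeIOError(
                    f"{path}: record {rec_no} ({variant.CHROM}:{variant.POS}) "
                    "is multiallelic or not a SNV; only biallelic SNVs are supported"
                )
            snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}:{variant.REF}:{alts[0]}"
            if snp_id in seen_ids:
                snp_id = f"{snp_id}#{rec_no}"
            seen_ids.add(snp_id)
            snps.append(
                SnpRecord(snp_id, str(variant.CHROM), variant.POS, variant.REF, alts[0])
            )
            gt = np.asarray(variant.gt_types)
            columns.append(lut[np.clip(gt, 0, 3)])
    except GenotypeIOError:
        raise
    except Exception as exc:
        raise GenotypeIOError(
            f"malformed VCF {path} near record {len(snps) + 1}: {exc}"
        ) from exc

    if not snps:
        raise GenotypeIOError(f"{path}: no biallelic SNVs retained")
    dosages = np.column_stack(columns)
    return GenotypeMatrix(sample_ids, snps, dosages)


_METADATA_COLUMNS = ("sample_id", "population", "ancestry_group")


def read_metadata(path: str) -> dict[str, tuple[str, str]]:
    """Read the sample-metadata TSV: sample_id -> (population, ancestry_group)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing_cols = [c for c in _METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise GenotypeIOError(f"{path}: missing metadata columns {missing_cols}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if len(dup):
        raise GenotypeIOError(f"{path}: duplicated sample_id {dup.iloc[0]!r}")
    if df[list(_METADATA_COLUMNS)].isna().any().any():
        row = int(df[list(_METADATA_COLUMNS)].isna().any(axis=1).idxmax())
        raise GenotypeIOError(f"{path}: empty metadata cell in row {row + 2}")
    return {
        r.sample_id: (r.population, r.ancestry_group)
        for r in df.itertuples(index=False)
    }


def build_reference_panel(
    genotypes: GenotypeMatrix, metadata: dict[str, tuple[str, str]]
) -> ReferencePanel:
    """Join genotypes with metadata labels into a :class:`ReferencePanel`."""
    pops, grps = [], []
    for sid in genotypes.sample_ids:
        if sid not in metadata:
            raise GenotypeIOError(
                f"sample {sid!r} present in genotypes but absent from metadata"
            )
        pop, grp = metadata[sid]
        pops.append(pop)
        grps.append(grp)
    return ReferencePanel(genotypes, np.array(pops, dtype=object),
                          np.array(grps, dtype=object))


# ---------------------------------------------------------------------------
# SNP alignment between call sets
# ---------------------------------------------------------------------------

def align_on_shared_snps(
    a: GenotypeMatrix, b: GenotypeMatrix, drop_ambiguous: bool = True
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Intersect two matrices on (chrom, pos) and reconcile alleles to ``a``.

    ``a`` is the orientation authority (the reference panel): where
    ``b`` has REF/ALT swapped, its dosages are flipped g -> 2 - g and
    its records replaced by ``a``'s. Strand-ambiguous A/T and C/G SNPs
    are dropped when ``drop_ambiguous``; allele sets that neither match
    nor swap are dropped. Both outputs carry identical SNP lists, in
    ``a``'s order.
    """
    b_by_key: dict[tuple[str, int], int] = {}
    for j, snp in enumerate(b.snps):
        if snp.key in b_by_key:
            logger.warning("duplicate locus %s in second matrix; keeping first", snp.key)
            continue
        b_by_key[snp.key] = j

    a_idx: list[int] = []
    b_idx: list[int] = []
    flip: list[bool] = []
    n_dropped = 0
    for i, snp_a in enumerate(a.snps):
        j = b_by_key.get(snp_a.key)
        if j is None:
            continue
        snp_b = b.snps[j]
        if drop_ambiguous and (snp_a.is_strand_ambiguous or snp_b.is_strand_ambiguous):
            n_dropped += 1
            continue
        pair_a = (snp_a.ref_allele, snp_a.alt_allele)
        pair_b = (snp_b.ref_allele, snp_b.alt_allele)
        comp_b = (_COMPLEMENT[snp_b.ref_allele], _COMPLEMENT[snp_b.alt_allele])
        if pair_b == pair_a or comp_b == pair_a:
            flip.append(False)
        elif pair_b == pair_a[::-1] or comp_b == pair_a[::-1]:
            flip.append(True)
        else:
            n_dropped += 1
            continue
        a_idx.append(i)
        b_idx.append(j)

    logger.info(
        "align_on_shared_snps: kept %d shared SNPs, dropped %d "
        "(ambiguous or irreconcilable alleles)", len(a_idx), n_dropped,
    )
    a_out = a.take_snps(a_idx)
    b_dos = b.dosages[:, b_idx].copy()
    flip_arr = np.asarray(flip, dtype=bool)
    if flip_arr.any():
        cols = b_dos[:, flip_arr]
        observed = cols != MISSING
        cols[observed] = 2 - cols[observed]
        b_dos[:, flip_arr] = cols
    b_out = GenotypeMatrix(list(b.sample_ids), list(a_out.snps), b_dos)
    return a_out, b_out


# ---------------------------------------------------------------------------
# Genotype TSV dialect
# ---------------------------------------------------------------------------
# ``##SNP <id> <chrom> <pos> <ref> <alt>`` comment lines (tab-separated)
# carry the SNP records; the body is rows=samples, columns=SNP ids,
# cells in {0,1,2,NA}. A single file thus round-trips exactly.

_SNP_HEADER_RE = re.compile(r"^##SNP\t")


def write_genotype_tsv(m: GenotypeMatrix, path: str) -> None:
    """Write the genotype TSV dialect (see module notes); errors on empty."""
    if m.n_samples == 0 or m.n_snps == 0:
        raise GenotypeIOError("refusing to write an empty genotype matrix")
    with open(path, "w") as fh:
        for s in m.snps:
            fh.write(f"##SNP\t{s.id}\t{s.chrom}\t{s.pos}\t{s.ref_allele}\t{s.alt_allele}\n")
        fh.write("sample_id\t" + "\t".join(m.snp_ids) + "\n")
        for i, sid in enumerate(m.sample_ids):
            cells = ["NA" if g == MISSING else str(g) for g in m.dosages[i]]
            fh.write(sid + "\t" + "\t".join(cells) + "\n")


def read_genotype_tsv(path: str) -> GenotypeMatrix:
    """Read the genotype TSV dialect written by :func:`write_genotype_tsv`."""
    snps: list[SnpRecord] = []
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for line in lines:
        if _SNP_HEADER_RE.match(line):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise GenotypeIOError(f"{path}: malformed ##SNP line: {line!r}")
            _, sid, chrom, pos, ref, alt = parts
            snps.append(SnpRecord(sid, chrom, int(pos), ref, alt))
            body_start += 1
        else:
            break
    if not snps:
        raise GenotypeIOError(f"{path}: no ##SNP header lines")
    header = lines[body_start].rstrip("\n").split("\t")
    if header[0] != "sample_id" or header[1:] != [s.id for s in snps]:
        raise GenotypeIOError(f"{path}: body header does not match ##SNP lines")
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for line_no, line in enumerate(lines[body_start + 1:], start=body_start + 2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(snps) + 1:
            raise GenotypeIOError(
                f"{path}:{line_no}: expected {len(snps) + 1} columns, got {len(parts)}"
            )
        sample_ids.append(parts[0])
        try:
            rows.append(
                np.array(
                    [MISSING if c == "NA" else int(c) for c in parts[1:]],
                    dtype=np.int8,
                )
            )
        except ValueError as exc:
            raise GenotypeIOError(f"{path}:{line_no}: bad dosage cell: {exc}") from exc
    if not sample_ids:
        raise GenotypeIOError(f"{path}: no sample rows")
    return GenotypeMatrix(sample_ids, snps, np.vstack(rows))


def write_metadata_tsv(panel: ReferencePanel, path: str) -> None:
    """Write the sample-metadata TSV for a labelled panel."""
    pd.DataFrame(
        {
            "sample_id": panel.genotypes.sample_ids,
            "population": panel.population,
            "ancestry_group": panel.ancestry_group,
        }
    ).to_csv(path, sep="\t", index=False)
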