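"""Ploidy-aware genotype classification and heterozygosity.

Each genotype at each PASS SNP is scored as homozygous reference (AA),
homozygous variant (BB) or heterozygous (AB). In autotetraploids the AB
state deliberately lumps the three heterozygous dosage classes (ABBB,
AABB, AAAB): short-read counts at moderate depth cannot resolve dosage
reliably, so no dosage estimation is attempted.

The "core set" restricts diversity statistics to SNPs with at least
``min_genotype_depth`` reads (default 10) in every genotype of the panel,
so that every per-genotype comparison rests on the same sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    MISSING,
    STATE_AA,
    STATE_AB,
    STATE_BB,
    STATE_LABELS,
    CountsTable,
    DataError,
)

__all__ = [
    "CallParams",
    "GenotypeMatrix",
    "classify_genotype",
    "classify_matrix",
    "core_set",
    "heterozygosity",
    "pool_diploids",
    "write_genotype_matrix",
    "read_genotype_matrix",
]


@dataclass
class CallParams:
    """Read-count -> AA/AB/BB classification thresholds.

    ``max_hom_fraction`` is the largest minor-read fraction still called
    homozygous (boundary inclusive); it is kept below 0.5 and paired with
    ``min_het_reads_each_allele`` so that a single miscalled read at the
    depth floor cannot create a heterozygote.
    """

    min_genotype_depth: int = 10
    max_hom_fraction: float = 0.10
    min_het_reads_each_allele: int = 2

    def validate(self) -> None:
        if not 0.0 <= self.max_hom_fraction < 0.5:
            raise DataError("max_hom_fraction must lie in [0, 0.5)")
        if self.min_genotype_depth < 1:
            raise DataError("min_genotype_depth must be >= 1")


@dataclass
class GenotypeMatrix:
    """Sites x genotypes call-state matrix over {AA, AB, BB, missing}.

    ``codes`` uses the shared integer encoding (AA=0, AB=1, BB=2,
    missing=-1); ``sites`` carries at least contig and pos0 per row.
    """

    sites: pd.DataFrame
    genotypes: list[str]
    codes: np.ndarray
    ploidy: dict[str, int]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[0]

    def column(self, genotype_id: str) -> np.ndarray:
        try:
            j = self.genotypes.index(genotype_id)
        except ValueError:
            raise DataError(f"unknown genotype {genotype_id!r}") from None
        return self.codes[:, j]

    def columns(self, genotype_ids: list[str]) -> np.ndarray:
        return np.column_stack([self.column(g) for g in genotype_ids])


def classify_matrix(ref_reads, var_reads, params: CallParams | None = None) -> np.ndarray:
    """Vectorised AA/AB/BB/missing classification of read-count arrays.

    depth < min_genotype_depth -> missing; variant fraction f <=
    max_hom_fraction -> AA; f >= 1 - max_hom_fraction -> BB; otherwise AB
    provided both alleles carry >= min_het_reads_each_allele reads, else
    missing (ambiguous intermediate).
    """
    params = params or CallParams()
    params.validate()
    ref = np.asarray(ref_reads, dtype=np.int64)
    var = np.asarray(var_reads, dtype=np.int64)
    if (ref < 0).any() or (var < 0).any():
        raise DataError("negative read counts")
    depth = ref + var
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, var / np.maximum(depth, 1), 0.0)

    out = np.full(ref.shape, MISSING, dtype=np.int8)
    deep = depth >= params.min_genotype_depth
    out[deep & (frac <= params.max_hom_fraction)] = STATE_AA
    out[deep & (frac >= 1.0 - params.max_hom_fraction)] = STATE_BB
    het = (
        deep
        & (frac > params.max_hom_fraction)
        & (frac < 1.0 - params.max_hom_fraction)
        & (ref >= params.min_het_reads_each_allele)
        & (var >= params.min_het_reads_each_allele)
    )
    out[het] = STATE_AB
    return out


def classify_genotype(ref_reads: int, var_reads: int,
                      params: CallParams | None = None) -> str:
    """Scalar convenience wrapper returning 'AA'/'AB'/'BB'/'NA'."""
    code = classify_matrix(np.array([ref_reads]), np.array([var_reads]), params)[0]
    return STATE_LABELS[int(code)]


def core_set(calls: pd.DataFrame, counts: CountsTable, groups=None,
             params: CallParams | None = None) -> GenotypeMatrix:
    """Build the core genotype matrix for diversity statistics.

    Keeps PASS SNPs (InDels excluded) where every genotype reaches
    ``min_genotype_depth`` reads, then classifies every entry. The depth
    rule guarantees the matrix has no depth-induced missing entries.
    """
    params = params or CallParams()
    if len(calls) != counts.n_sites:
        raise DataError("calls and counts are not aligned")
    depth = counts.depth
    keep = (
        (calls["verdict"] == "PASS").to_numpy()
        & (calls["variant_class"] == "SNP").to_numpy()
        & (depth >= params.min_genotype_depth).all(axis=1)
    )
    sub = counts.subset(keep)
    codes = classify_matrix(sub.ref_reads, sub.var_reads, params)
    ploidy = dict(groups.ploidy) if groups is not None else {g: 4 for g in sub.genotypes}
    return GenotypeMatrix(
        sites=sub.sites.reset_index(drop=True),
        genotypes=list(sub.genotypes),
        codes=codes,
        ploidy=ploidy,
    )


def heterozygosity(matrix: GenotypeMatrix, genotype_id: str) -> float:
    """Percent heterozygous calls for one genotype over the core set.

    #AB / #(AA + AB + BB) x 100; missing entries drop out of both
    numerator and denominator. Undefined (error) with zero classified
    sites.
    """
    col = matrix.column(genotype_id)
    classified = col != MISSING
    n = int(classified.sum())
    if n == 0:
        raise DataError(f"genotype {genotype_id!r} has no classified sites")
    return float((col[classified] == STATE_AB).sum() / n * 100.0)


def pool_diploids(matrix: GenotypeMatrix, genotype_a: str, genotype_b: str) -> np.ndarray:
    """Pool two diploid genotypes into one synthetic four-chromosome column.

    Treating the two diploids of a subspecies as one individual with four
    chromosomes makes their pooled heterozygosity directly comparable to a
    tetraploid's. Per site: missing if either is missing; AB if either is
    AB or the two homozygous states differ; else the shared homozygote.
    """
    for gid in (genotype_a, genotype_b):
        if matrix.ploidy.get(gid) != 2:
            raise DataError(f"pool_diploids requires diploid genotypes; {gid!r} is not")
    a = matrix.column(genotype_a)
    b = matrix.column(genotype_b)
    pooled = np.full(a.shape, MISSING, dtype=np.int8)
    both = (a != MISSING) & (b != MISSING)
    same_hom = both & (a == b) & (a != STATE_AB)
    pooled[same_hom] = a[same_hom]
    het = both & ~same_hom
    pooled[het] = STATE_AB
    return pooled


# ---------------------------------------------------------------------------
# genotype-matrix TSV (sites as rows, genotypes as columns)

def write_genotype_matrix(matrix: GenotypeMatrix, path) -> None:
    df = matrix.sites[["contig", "pos0"]].copy()
    labels = np.array(["NA", "AA", "AB", "BB"])  # index by code + 1
    for j, gid in enumerate(matrix.genotypes):
        df[gid] = labels[matrix.codes[:, j] + 1]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_genotype_matrix(path, ploidy: dict[str, int] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    genotypes = [c for c in df.columns if c not in ("contig", "pos0")]
    code_of = {"NA": MISSING, "AA": STATE_AA, "AB": STATE_AB, "BB": STATE_BB}
    codes = np.empty((len(df), len(genotypes)), dtype=np.int8)
    for j, gid in enumerate(genotypes):
        try:
            codes[:, j] = df[gid].map(code_of).to_numpy()
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path}: invalid state in column {gid!r}") from exc
    return GenotypeMatrix(
        sites=df[["contig", "pos0"]].copy(),
        genotypes=genotypes,
        codes=codes,
        ploidy=dict(ploidy) if ploidy else {g: 4 for g in genotypes},
    )
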