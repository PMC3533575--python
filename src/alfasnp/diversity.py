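"""Group-level polymorphism accounting and candidate-contig detection.

These operations answer the domestication/breeding questions: which SNPs
still segregate within elite germplasm, which are shared across breeding
programs (Venn regions), whether any site is fixed for opposite alleles
between groups, and which contigs concentrate wild-only polymorphism
(candidate domestication or speciation genes).

"Polymorphic within a group" is defined on genotype calls, not raw reads:
among the group's non-missing calls at a site, at least one AB call, or
two opposite homozygotes, demonstrates that both alleles segregate there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, STATE_AA, STATE_AB, STATE_BB, DataError, GroupSpec
from .genotyping import GenotypeMatrix

__all__ = [
    "PolymorphismProfile",
    "group_polymorphism",
    "venn_regions",
    "fixed_differences",
    "candidate_contigs",
    "snp_density_windows",
    "percent",
]

log = logging.getLogger(__name__)


@dataclass
class PolymorphismProfile:
    """Per-SNP, per-group polymorphism flags.

    ``flags[i, g]`` is True iff SNP i is polymorphic within group g;
    ``defined[i, g]`` is False where the group had no non-missing call
    (the flag is then meaningless and the site is excluded from Venn
    totals).
    """

    sites: pd.DataFrame
    group_names: list[str]
    flags: np.ndarray
    defined: np.ndarray


def _polymorphic_flags(cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(flags, defined) for one pooled genotype set, vectorised over sites."""
    nonmiss = cols != MISSING
    defined = nonmiss.any(axis=1)
    any_ab = ((cols == STATE_AB) & nonmiss).any(axis=1)
    any_aa = ((cols == STATE_AA) & nonmiss).any(axis=1)
    any_bb = ((cols == STATE_BB) & nonmiss).any(axis=1)
    return (any_ab | (any_aa & any_bb)) & defined, defined


def group_polymorphism(matrix: GenotypeMatrix, groups: GroupSpec,
                       group_names: list[str] | None = None) -> PolymorphismProfile:
    """Flag, per SNP and group, whether both alleles segregate in the group."""
    names = group_names if group_names is not None else list(groups.groups)
    flags = np.zeros((matrix.n_sites, len(names)), dtype=bool)
    defined = np.zeros_like(flags)
    for g, name in enumerate(names):
        cols = matrix.columns(groups.members(name))
        flags[:, g], defined[:, g] = _polymorphic_flags(cols)
    return PolymorphismProfile(matrix.sites, list(names), flags, defined)


def venn_regions(profile: PolymorphismProfile) -> dict[tuple[str, ...], int]:
    """Exclusive Venn-region counts over the 2^k - 1 nonempty patterns.

    Each SNP polymorphic in at least one group lands in exactly one
    region, keyed by the sorted tuple of group names it is polymorphic
    in; the counts therefore partition that SNP set. Sites where any
    group's flag is undefined are excluded (and logged).
    """
    if len(profile.group_names) < 2:
        raise DataError("venn_regions needs at least 2 groups")
    usable = profile.defined.all(axis=1)
    dropped = int((~usable).sum())
    if dropped:
        log.warning("venn_regions: %d sites dropped (undefined group flags)", dropped)
    flags = profile.flags[usable]
    names = profile.group_names
    counts: dict[tuple[str, ...], int] = {}
    k = len(names)
    for pattern in range(1, 2**k):
        member = np.array([(pattern >> g) & 1 == 1 for g in range(k)])
        n = int(((flags == member).all(axis=1)).sum())
        key = tuple(names[g] for g in range(k) if member[g])
        counts[key] = n
    return counts


def fixed_differences(matrix: GenotypeMatrix, groups: GroupSpec,
                      pair: tuple[str, str]) -> pd.DataFrame:
    """Sites fixed for opposite homozygous alleles between two groups.

    A fixed difference requires every non-missing call in one group to be
    AA and every non-missing call in the other to be BB (either
    orientation), with at least one non-missing call on each side. Any AB
    in either group rules the site out.
    """
    ga, gb = pair
    a = matrix.columns(groups.members(ga))
    b = matrix.columns(groups.members(gb))
    if set(groups.members(ga)) & set(groups.members(gb)):
        raise DataError(f"groups {ga!r} and {gb!r} share genotypes")

    def all_hom(cols: np.ndarray, state: int) -> np.ndarray:
        nonmiss = cols != MISSING
        return nonmiss.any(axis=1) & ((cols == state) | ~nonmiss).all(axis=1)

    fixed = (all_hom(a, STATE_AA) & all_hom(b, STATE_BB)) | (
        all_hom(a, STATE_BB) & all_hom(b, STATE_AA)
    )
    return matrix.sites.loc[fixed].reset_index(drop=True)


def candidate_contigs(matrix: GenotypeMatrix, groups: GroupSpec,
                      polymorphic_in: list[str], fixed_in: list[str],
                      min_cluster: int = 5, label: str = "candidate") -> pd.DataFrame:
    """Contigs concentrating polymorphism private to one genotype set.

    A qualifying SNP is polymorphic within the pooled ``polymorphic_in``
    genotypes (the pool is treated as one set, so a difference *between*
    its members counts) while every genotype of ``fixed_in`` is fixed:
    all their non-missing calls are the same homozygote, with no AB
    anywhere. Contigs carrying >= ``min_cluster`` qualifying SNPs are
    returned with their counts and SNP positions.
    """
    poly_ids = groups.members(*polymorphic_in)
    fixed_ids = groups.members(*fixed_in)
    if set(poly_ids) & set(fixed_ids):
        raise DataError("polymorphic_in and fixed_in genotype sets overlap")

    poly_flags, _ = _polymorphic_flags(matrix.columns(poly_ids))
    fcols = matrix.columns(fixed_ids)
    nonmiss = fcols != MISSING
    no_het = ~((fcols == STATE_AB) & nonmiss).any(axis=1)
    all_aa = ((fcols == STATE_AA) | ~nonmiss).all(axis=1)
    all_bb = ((fcols == STATE_BB) | ~nonmiss).all(axis=1)
    mono = nonmiss.any(axis=1) & no_het & (all_aa | all_bb)

    qualifying = poly_flags & mono
    qual_sites = matrix.sites.loc[qualifying]
    rows = []
    for contig, grp in qual_sites.groupby("contig", sort=True):
        if len(grp) >= min_cluster:
            rows.append(
                {
                    "contig": contig,
                    "n_snps": len(grp),
                    "positions": ";".join(str(p) for p in sorted(grp["pos0"])),
                    "criterion": label,
                }
            )
    return pd.DataFrame(rows, columns=["contig", "n_snps", "positions", "criterion"])


def snp_density_windows(calls: pd.DataFrame, contigs: pd.DataFrame,
                        window: int = 500_000) -> pd.DataFrame:
    """SNP density per kbp in fixed-origin windows along anchor chromosomes.

    Each PASS SNP on an anchored contig is projected to genome coordinate
    anchor_pos + pos0; each chromosome is tiled into half-open
    ``[k*window, (k+1)*window)`` intervals from the origin and density is
    SNPs-per-1000-bp within each window. Contigs without an anchor are
    skipped (count logged). Output is BEDGRAPH-shaped: chrom, start, end,
    density.
    """
    if "anchor_chrom" not in contigs.columns:
        raise DataError("contig table has no anchor coordinates")
    anchored = contigs.dropna(subset=["anchor_chrom", "anchor_pos"])
    skipped = len(contigs) - len(anchored)
    if skipped:
        log.info("snp_density_windows: %d unanchored contigs skipped", skipped)
    anchor = anchored.set_index("contig")[["anchor_chrom", "anchor_pos"]]

    passed = calls[(calls["verdict"] == "PASS") & (calls["variant_class"] == "SNP")]
    merged = passed.merge(anchor, left_on="contig", right_index=True, how="inner")
    rows = []
    for chrom, grp in merged.groupby("anchor_chrom", sort=True):
        gpos = (grp["anchor_pos"].to_numpy() + grp["pos0"].to_numpy()).astype(np.int64)
        chrom_contigs = anchored[anchored["anchor_chrom"] == chrom]
        span = int((chrom_contigs["anchor_pos"] + chrom_contigs["length"]).max())
        n_win = int(np.ceil(span / window))
        hist = np.bincount(gpos // window, minlength=n_win)
        for w in range(n_win):
            rows.append(
                {
                    "chrom": chrom,
                    "start": w * window,
                    "end": (w + 1) * window,
                    "density": hist[w] / (window / 1000.0),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "density"])


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage of ``numerator`` over ``denominator``, rounded.

    The accounting helper behind every "X% of the core SNPs" figure;
    errors on a zero denominator rather than returning NaN.
    """
    if denominator == 0:
        raise DataError("percentage undefined: zero denominator")
    return round(numerator / denominator * 100.0, decimals)
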