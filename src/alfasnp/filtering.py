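"""SNP filter cascade and genotypic contingency test.

A candidate variant site is retained as a true SNP/InDel only if it clears
three filters, applied in cascade order:

1. sample support — at least one genotype shows the variant allele on >= 2
   reads, with mean variant-base quality >= 20 Phred, at >= 20% of that
   genotype's reads covering the site;
2. total depth — the summed read depth over all genotypes is strictly
   greater than 20;
3. genotypic contingency test — a 2 x K contingency table (reference and
   variant read counts as rows, the K genotypes with nonzero depth as
   columns) must reject independence at p < 0.01. Uniform low-level
   sequencing error produces the same variant fraction in every genotype
   and is independent of genotype, so it fails this test; a genuine
   segregating polymorphism shows genotype-specific allele proportions.

The default test is Pearson's chi-square with K - 1 degrees of freedom; a
seeded permutation alternative (shuffling allele labels among reads while
preserving per-genotype depths) guards against sparse tables where the
chi-square approximation is poor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountsTable, DataError

__all__ = [
    "FilterParams",
    "sample_support_filter",
    "total_depth_filter",
    "contingency_test",
    "call_variants",
    "hrm_eligible",
]

log = logging.getLogger(__name__)

FAIL_SUPPORT = "sample_support"
FAIL_DEPTH = "total_depth"
FAIL_TEST = "contingency"
PASS = "PASS"


@dataclass
class FilterParams:
    """Thresholds of the filter cascade.

    All boundary semantics follow the rules above: minimums are inclusive
    except ``min_total_reads_exclusive`` which is a strict ``>``.
    """

    min_var_reads: int = 2
    min_mean_quality: float = 20.0
    min_var_fraction: float = 0.20
    min_total_reads_exclusive: int = 20
    alpha: float = 0.01
    p_value_method: str = "chi2"  # or "permutation"
    n_permutations: int = 10_000
    seed: int = 0

    def validate(self) -> None:
        if self.min_var_reads < 0 or self.min_mean_quality < 0:
            raise DataError("thresholds must be non-negative")
        if not 0.0 <= self.min_var_fraction <= 1.0:
            raise DataError("min_var_fraction must lie in [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must lie in (0, 1)")
        if self.p_value_method not in ("chi2", "permutation"):
            raise DataError(f"unknown p_value_method {self.p_value_method!r}")


# ---------------------------------------------------------------------------
# individual filters (single-site forms used for small inputs and as the
# reference semantics; call_variants vectorises the same rules)

def _support_matrix(ref: np.ndarray, var: np.ndarray, qual: np.ndarray,
                    params: FilterParams) -> np.ndarray:
    depth = ref + var
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(depth > 0, var / np.maximum(depth, 1), 0.0)
    return (
        (var >= params.min_var_reads)
        & (qual >= params.min_mean_quality)
        & (depth > 0)
        & (frac >= params.min_var_fraction)
    )


def sample_support_filter(ref_reads, var_reads, mean_var_qual,
                          params: FilterParams | None = None,
                          genotypes: list[str] | None = None):
    """Per-genotype variant support at one site.

    Returns ``(flag, supporting_ids)``: the site passes iff at least one
    genotype shows the variant at ``min_var_reads`` reads, quality
    ``min_mean_quality`` and read fraction ``min_var_fraction`` (all
    inclusive). A genotype with zero depth never supports.
    """
    params = params or FilterParams()
    ref = np.atleast_1d(np.asarray(ref_reads))
    var = np.atleast_1d(np.asarray(var_reads))
    qual = np.atleast_1d(np.asarray(mean_var_qual, dtype=float))
    sup = _support_matrix(ref, var, qual, params)
    ids = (
        [genotypes[j] for j in np.nonzero(sup)[0]]
        if genotypes is not None
        else list(np.nonzero(sup)[0])
    )
    return bool(sup.any()), ids


def total_depth_filter(ref_reads, var_reads, params: FilterParams | None = None) -> bool:
    """True iff summed depth over genotypes is strictly > the threshold."""
    params = params or FilterParams()
    total = int(np.sum(ref_reads) + np.sum(var_reads))
    return total > params.min_total_reads_exclusive


def contingency_test(ref_reads, var_reads, params: FilterParams | None = None,
                     rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Genotypic contingency test at one site.

    Builds the 2 x K table of (reference, variant) read counts over the K
    genotypes with nonzero depth and tests independence of allele and
    genotype. Default: Pearson chi-square, df = K - 1. Permutation mode
    shuffles allele labels among all reads, preserving per-genotype read
    totals, and reports p = (1 + #{stat_perm >= stat_obs}) / (1 + n_perm).

    Degenerate tables — fewer than two nonzero-depth genotypes, or an
    allele row summing to zero — carry no evidence against independence
    and get (0.0, 1.0).
    """
    params = params or FilterParams()
    ref = np.asarray(ref_reads, dtype=np.int64)
    var = np.asarray(var_reads, dtype=np.int64)
    depth = ref + var
    keep = depth > 0
    ref, var, depth = ref[keep], var[keep], depth[keep]
    k = len(depth)
    if k < 2:
        warnings.warn("contingency test undefined with fewer than 2 genotypes; p=1")
        return 0.0, 1.0
    if var.sum() == 0 or ref.sum() == 0:
        return 0.0, 1.0

    stat = _pearson_stat(ref, var)
    if params.p_value_method == "chi2":
        p = float(stats.chi2.sf(stat, df=k - 1))
        return float(stat), p

    rng = rng if rng is not None else np.random.default_rng(params.seed)
    labels = np.zeros(int(depth.sum()), dtype=np.int8)
    labels[: int(var.sum())] = 1
    splits = np.cumsum(depth)[:-1]
    exceed = 0
    for _ in range(params.n_permutations):
        rng.shuffle(labels)
        var_p = np.array([seg.sum() for seg in np.split(labels, splits)])
        if _pearson_stat(depth - var_p, var_p) >= stat - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + params.n_permutations)
    return float(stat), float(p)


def _pearson_stat(ref: np.ndarray, var: np.ndarray) -> float:
    depth = ref + var
    n = depth.sum()
    e_ref = ref.sum() * depth / n
    e_var = var.sum() * depth / n
    return float(((ref - e_ref) ** 2 / e_ref).sum() + ((var - e_var) ** 2 / e_var).sum())


# ---------------------------------------------------------------------------
# full cascade, vectorised over a counts table

def call_variants(counts: CountsTable, params: FilterParams | None = None) -> pd.DataFrame:
    """Apply the full filter cascade to every site of a counts table.

    Returns one row per site (aligned with ``counts.sites``) carrying the
    diagnostics of every stage and a ``verdict``: ``PASS``, or the first
    failing stage in cascade order (support -> depth -> contingency).
    """
    params = params or FilterParams()
    params.validate()

    ref, var, qual = counts.ref_reads, counts.var_reads, counts.mean_var_qual
    depth = ref + var
    support = _support_matrix(ref, var, qual, params)
    support_pass = support.any(axis=1)
    total_reads = depth.sum(axis=1)
    depth_pass = total_reads > params.min_total_reads_exclusive

    if params.p_value_method == "chi2":
        stat, pval = _vectorised_chi2(ref, var)
    else:
        rng = np.random.default_rng(params.seed)
        stat = np.zeros(counts.n_sites)
        pval = np.ones(counts.n_sites)
        for i in range(counts.n_sites):
            stat[i], pval[i] = contingency_test(ref[i], var[i], params, rng=rng)
    test_pass = pval < params.alpha

    verdict = np.full(counts.n_sites, PASS, dtype=object)
    verdict[~test_pass] = FAIL_TEST
    verdict[~depth_pass] = FAIL_DEPTH
    verdict[~support_pass] = FAIL_SUPPORT

    supporting = [
        ";".join(counts.genotypes[j] for j in np.nonzero(row)[0]) for row in support
    ]
    out = counts.sites.copy()
    out["passed_sample_support"] = support_pass
    out["supporting_genotypes"] = supporting
    out["total_reads"] = total_reads
    out["passed_total_depth"] = depth_pass
    out["statistic"] = stat
    out["p_value"] = pval
    out["passed_contingency"] = test_pass
    out["verdict"] = verdict

    n = counts.n_sites
    log.info("filter cascade: %d sites in", n)
    log.info("  sample support: %d survive", int(support_pass.sum()))
    log.info("  total depth:    %d survive", int((support_pass & depth_pass).sum()))
    log.info("  contingency:    %d PASS", int((verdict == PASS).sum()))
    return out


def _vectorised_chi2(ref: np.ndarray, var: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    depth = ref + var
    nonzero = depth > 0
    k = nonzero.sum(axis=1)
    n = depth.sum(axis=1).astype(float)
    r_tot = ref.sum(axis=1).astype(float)
    v_tot = var.sum(axis=1).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        e_ref = r_tot[:, None] * depth / np.maximum(n, 1)[:, None]
        e_var = v_tot[:, None] * depth / np.maximum(n, 1)[:, None]
        t_ref = np.where(nonzero & (e_ref > 0), (ref - e_ref) ** 2 / np.where(e_ref > 0, e_ref, 1), 0.0)
        t_var = np.where(nonzero & (e_var > 0), (var - e_var) ** 2 / np.where(e_var > 0, e_var, 1), 0.0)
    stat = t_ref.sum(axis=1) + t_var.sum(axis=1)

    degenerate = (k < 2) | (v_tot == 0) | (r_tot == 0)
    stat = np.where(degenerate, 0.0, stat)
    pval = np.ones(len(stat))
    ok = ~degenerate
    pval[ok] = stats.chi2.sf(stat[ok], df=k[ok] - 1)
    if (k < 2).any():
        log.warning("%d sites had <2 genotypes with reads; p set to 1", int((k < 2).sum()))
    return stat, pval


# ---------------------------------------------------------------------------
# HRM-assayable SNP selection

def hrm_eligible(calls: pd.DataFrame, contigs: pd.DataFrame, flank: int = 18) -> pd.DataFrame:
    """Select PASS SNPs with clean flanks suitable for an HRM melting assay.

    A PASS SNP is eligible iff no other PASS variant (SNP or InDel) lies
    within ``flank`` bases on either side on the same contig (a neighbour
    at distance d <= flank disqualifies: the assay needs >= ``flank``
    polymorphism-free bases on each side), and the SNP is at least
    ``flank`` bases from both contig ends.
    """
    lengths = dict(zip(contigs["contig"], contigs["length"]))
    passed = calls[calls["verdict"] == PASS]
    rows = []
    for contig, grp in passed.groupby("contig", sort=True):
        pos = np.sort(grp["pos0"].to_numpy())
        length = lengths.get(contig)
        if length is None:
            raise DataError(f"contig {contig!r} missing from contig metadata")
        snp_rows = grp[grp["variant_class"] == "SNP"]
        for _, row in snp_rows.iterrows():
            p = row["pos0"]
            others = pos[pos != p]
            if len(others) and np.min(np.abs(others - p)) <= flank:
                continue
            if p < flank or (length - 1 - p) < flank:
                continue
            rows.append(row)
    if not rows:
        return passed.iloc[0:0]
    return pd.DataFrame(rows).reset_index(drop=True)
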