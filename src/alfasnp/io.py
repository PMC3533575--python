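"""Interchange formats for the variant-calling pipeline.

Everything downstream operates on three plain-text inputs:

* a per-site read-count table (TSV) giving, for every candidate variant
  site and every genotype, the number of reads carrying the reference
  allele, the number carrying the variant allele, and the mean Phred
  quality of the variant-supporting bases;
* a group configuration (YAML) naming genotype groupings and per-genotype
  ploidy;
* a contig metadata table (TSV) with contig lengths and optional anchor
  coordinates on a reference pseudomolecule.

Internal coordinates are 0-based half-open throughout; VCF export converts
to 1-based positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountsTable",
    "GroupSpec",
    "DataError",
    "read_counts_table",
    "write_counts_table",
    "read_groups",
    "write_groups",
    "read_contigs",
    "write_contigs",
    "contig_length_summary",
    "write_vcf",
    "read_vcf_calls",
    "MISSING",
    "STATE_AA",
    "STATE_AB",
    "STATE_BB",
    "STATE_LABELS",
]

# genotype-call state codes shared across modules
MISSING = -1
STATE_AA = 0
STATE_AB = 1
STATE_BB = 2
STATE_LABELS = {MISSING: "NA", STATE_AA: "AA", STATE_AB: "AB", STATE_BB: "BB"}

SITE_COLUMNS = ["contig", "pos0", "ref_allele", "var_allele", "variant_class"]


class DataError(ValueError):
    """Malformed or inconsistent input data (exit code 3 in the CLI)."""


@dataclass
class CountsTable:
    """Per-site, per-genotype allele read counts.

    ``sites`` holds one row per variant site (contig, pos0, ref_allele,
    var_allele, variant_class) sorted by (contig, pos0); the three count
    matrices are aligned with it row-wise and with ``genotypes``
    column-wise.
    """

    sites: pd.DataFrame
    genotypes: list[str]
    ref_reads: np.ndarray
    var_reads: np.ndarray
    mean_var_qual: np.ndarray

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def depth(self) -> np.ndarray:
        """Total per-genotype read depth, sites x genotypes."""
        return self.ref_reads + self.var_reads

    def validate(self) -> None:
        n, g = self.ref_reads.shape
        if n != len(self.sites) or g != len(self.genotypes):
            raise DataError("count matrices not aligned with site/genotype lists")
        if (self.ref_reads < 0).any() or (self.var_reads < 0).any():
            raise DataError("negative read counts")
        if (self.mean_var_qual < 0).any():
            raise DataError("negative base quality")
        key = self.sites[["contig", "pos0", "var_allele"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise DataError(
                f"duplicate site {dup['contig']}:{dup['pos0']} ({dup['var_allele']})"
            )

    def subset(self, mask: np.ndarray) -> "CountsTable":
        """Row-subset by boolean mask or integer index, keeping alignment."""
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return CountsTable(
            sites=self.sites.iloc[idx].reset_index(drop=True),
            genotypes=list(self.genotypes),
            ref_reads=self.ref_reads[idx],
            var_reads=self.var_reads[idx],
            mean_var_qual=self.mean_var_qual[idx],
        )


@dataclass
class GroupSpec:
    """Named genotype groupings plus per-genotype ploidy.

    ``groups`` maps a group name (e.g. ``Group1`` or a breeding-program
    subgroup) to an ordered list of genotype ids; every id must appear in
    ``ploidy``.
    """

    groups: dict[str, list[str]] = field(default_factory=dict)
    ploidy: dict[str, int] = field(default_factory=dict)

    @property
    def genotypes(self) -> list[str]:
        return list(self.ploidy)

    def members(self, *names: str) -> list[str]:
        """Pooled, de-duplicated genotype list for one or more groups."""
        seen: dict[str, None] = {}
        for name in names:
            if name not in self.groups:
                raise DataError(f"unknown group {name!r}")
            for gid in self.groups[name]:
                seen.setdefault(gid)
        return list(seen)

    def validate(self) -> None:
        for gid, pl in self.ploidy.items():
            if pl not in (2, 4):
                raise DataError(f"genotype {gid!r}: ploidy must be 2 or 4, got {pl}")
        for name, ids in self.groups.items():
            if not ids:
                raise DataError(f"group {name!r} is empty")
            if len(set(ids)) != len(ids):
                raise DataError(f"group {name!r} lists a genotype twice")
            for gid in ids:
                if gid not in self.ploidy:
                    raise DataError(f"group {name!r} references unknown genotype {gid!r}")


# ---------------------------------------------------------------------------
# count-table TSV

def _genotype_columns(gid: str) -> list[str]:
    return [f"{gid}:ref_reads", f"{gid}:var_reads", f"{gid}:mean_var_quality"]


def write_counts_table(counts: CountsTable, path) -> None:
    cols = {c: counts.sites[c] for c in SITE_COLUMNS}
    for j, gid in enumerate(counts.genotypes):
        r, v, q = _genotype_columns(gid)
        cols[r] = counts.ref_reads[:, j]
        cols[v] = counts.var_reads[:, j]
        cols[q] = counts.mean_var_qual[:, j]
    df = pd.DataFrame(cols)
    df.to_csv(path, sep="\t", index=False, float_format="%.1f", lineterminator="\n")


def read_counts_table(path) -> CountsTable:
    """Read the count-table TSV, validating row by row.

    Raises :class:`DataError` naming the 1-based file line for malformed
    rows (negative counts, non-numeric fields) and for duplicate sites.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    except (ValueError, OSError) as exc:
        raise DataError(f"{path}: {exc}") from exc
    for col in SITE_COLUMNS:
        if col not in df.columns:
            raise DataError(f"{path}: missing required column {col!r}")
    suffix_cols = [c for c in df.columns if ":" in c]
    genotypes: list[str] = []
    for c in suffix_cols:
        gid = c.rsplit(":", 1)[0]
        if gid not in genotypes:
            genotypes.append(gid)
    for gid in genotypes:
        for c in _genotype_columns(gid):
            if c not in df.columns:
                raise DataError(f"{path}: genotype {gid!r} missing column {c!r}")

    n = len(df)
    ref = np.zeros((n, len(genotypes)), dtype=np.int64)
    var = np.zeros((n, len(genotypes)), dtype=np.int64)
    qual = np.zeros((n, len(genotypes)), dtype=float)
    for j, gid in enumerate(genotypes):
        rcol, vcol, qcol = _genotype_columns(gid)
        for col, out in ((rcol, ref), (vcol, var)):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
            if bad.any():
                line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
                raise DataError(f"{path}:{line}: invalid read count in column {col!r}")
            out[:, j] = vals.astype(np.int64)
        qvals = pd.to_numeric(df[qcol], errors="coerce")
        bad = qvals.isna() | (qvals < 0)
        if bad.any():
            line = int(bad.idxmax()) + 2
            raise DataError(f"{path}:{line}: invalid quality in column {qcol!r}")
        qual[:, j] = qvals.astype(float)

    sites = df[SITE_COLUMNS].copy()
    sites["pos0"] = pd.to_numeric(sites["pos0"]).astype(np.int64)
    order = np.lexsort((sites["pos0"].to_numpy(), sites["contig"].to_numpy()))
    counts = CountsTable(
        sites=sites.iloc[order].reset_index(drop=True),
        genotypes=genotypes,
        ref_reads=ref[order],
        var_reads=var[order],
        mean_var_qual=qual[order],
    )
    counts.validate()
    return counts


# ---------------------------------------------------------------------------
# group config (YAML)

def write_groups(spec: GroupSpec, path) -> None:
    doc = {
        "ploidy": dict(spec.ploidy),
        "groups": {k: list(v) for k, v in spec.groups.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_groups(path) -> GroupSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "ploidy" not in doc or "groups" not in doc:
        raise DataError(f"{path}: expected top-level 'ploidy' and 'groups' mappings")
    spec = GroupSpec(
        groups={str(k): [str(g) for g in v] for k, v in doc["groups"].items()},
        ploidy={str(k): int(v) for k, v in doc["ploidy"].items()},
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# contig metadata

def write_contigs(contigs: pd.DataFrame, path) -> None:
    df = contigs.copy()
    for col in ("anchor_chrom", "anchor_pos"):
        if col not in df.columns:
            df[col] = np.nan
    df["anchor_chrom"] = df["anchor_chrom"].fillna(".")
    df["anchor_pos"] = df["anchor_pos"].map(
        lambda x: "." if (x is None or (isinstance(x, float) and math.isnan(x))) else str(int(x))
    )
    df[["contig", "length", "anchor_chrom", "anchor_pos"]].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_contigs(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "anchor_chrom": str})
    if "contig" not in df.columns or "length" not in df.columns:
        raise DataError(f"{path}: expected columns 'contig' and 'length'")
    df["length"] = df["length"].astype(np.int64)
    if (df["length"] <= 0).any():
        raise DataError(f"{path}: contig lengths must be positive")
    if "anchor_chrom" in df.columns:
        df["anchor_chrom"] = df["anchor_chrom"].replace(".", np.nan)
        df["anchor_pos"] = pd.to_numeric(df["anchor_pos"].replace(".", np.nan))
    return df


def contig_length_summary(contigs: pd.DataFrame, bin_edges: list[tuple[float, float]]):
    """Count contigs per length bin (closed-open ``[lo, hi)`` intervals).

    Returns a DataFrame with one row per bin (lo, hi, count, proportion)
    plus the helper :func:`proportion_at_least` below for threshold
    queries. Bins must be non-overlapping and jointly cover every length;
    an empty contig table is an error (proportions undefined).
    """
    if len(contigs) == 0:
        raise DataError("empty contig table: proportions undefined")
    edges = sorted(bin_edges)
    for (lo1, hi1), (lo2, hi2) in zip(edges, edges[1:]):
        if hi1 > lo2:
            raise DataError("overlapping length bins")
    lengths = contigs["length"].to_numpy()
    rows = []
    covered = np.zeros(len(lengths), dtype=bool)
    for lo, hi in bin_edges:
        inbin = (lengths >= lo) & (lengths < hi)
        covered |= inbin
        rows.append({"lo": lo, "hi": hi, "count": int(inbin.sum())})
    if not covered.all():
        raise DataError("length bins do not cover all contigs")
    out = pd.DataFrame(rows)
    out["proportion"] = out["count"] / len(lengths)
    return out


def proportion_at_least(summary: pd.DataFrame, threshold: float) -> float:
    """Fraction of contigs in bins whose lower edge is >= threshold."""
    total = summary["count"].sum()
    if total == 0:
        raise DataError("empty summary")
    return float(summary.loc[summary["lo"] >= threshold, "count"].sum() / total)


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FILTER=<ID=sample_support,Description="No genotype with sufficient variant reads, quality and frequency">
##FILTER=<ID=total_depth,Description="Total aligned reads across all genotypes not greater than threshold">
##FILTER=<ID=contingency,Description="Genotypic contingency test p-value not below threshold">
##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNP or InDel)">
##INFO=<ID=CS,Number=1,Type=Float,Description="Contingency test statistic">
##INFO=<ID=CP,Number=1,Type=Float,Description="Contingency test p-value">
##INFO=<ID=TR,Number=1,Type=Integer,Description="Total reads across all genotypes">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype call, heterozygous dosage classes lumped">
##FORMAT=<ID=DL,Number=1,Type=Integer,Description="1 if the call lumps tetraploid heterozygous dosage classes">
"""


def write_vcf(calls: pd.DataFrame, path, genotype_codes: np.ndarray | None = None,
              genotypes: list[str] | None = None,
              contigs: pd.DataFrame | None = None) -> None:
    """Write filter-cascade calls (and optional genotype calls) as VCF 4.2.

    ``calls`` is the DataFrame produced by the filter cascade: one row per
    site with contig/pos0/alleles/class plus verdict diagnostics. Internal
    0-based positions become 1-based VCF POS. The FILTER column carries the
    first failing cascade stage, or PASS. If ``genotype_codes`` (sites x
    genotypes state codes) is given, per-sample GT fields are emitted with
    heterozygotes encoded 0/1 and flagged as dosage-lumped for tetraploids.
    """
    lines = [_VCF_HEADER.rstrip("\n")]
    if contigs is not None:
        for _, row in contigs.iterrows():
            lines.append(f"##contig=<ID={row['contig']},length={int(row['length'])}>")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO"]
    ploidy = None
    if genotype_codes is not None:
        if genotypes is None:
            raise DataError("genotype ids required when writing genotype calls")
        header_cols += ["FORMAT"] + list(genotypes)
    lines.append("\t".join(header_cols))

    gt_map = {STATE_AA: "0/0", STATE_AB: "0/1", STATE_BB: "1/1", MISSING: "./."}
    for i, row in enumerate(calls.itertuples(index=False)):
        info = (
            f"VC={row.variant_class};CS={row.statistic:.4f};"
            f"CP={row.p_value:.6g};TR={int(row.total_reads)}"
        )
        rec = [
            str(row.contig),
            str(int(row.pos0) + 1),
            ".",
            str(row.ref_allele),
            str(row.var_allele),
            ".",
            "PASS" if row.verdict == "PASS" else str(row.verdict),
            info,
        ]
        if genotype_codes is not None:
            rec.append("GT:DL")
            for code in genotype_codes[i]:
                lumped = 1 if code == STATE_AB else 0
                rec.append(f"{gt_map[int(code)]}:{lumped}")
        lines.append("\t".join(rec))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf_calls(path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a calls DataFrame."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            filt = list(rec.filter.keys())
            rows.append(
                {
                    "contig": rec.chrom,
                    "pos0": rec.pos - 1,
                    "ref_allele": rec.ref,
                    "var_allele": rec.alts[0] if rec.alts else ".",
                    "variant_class": rec.info.get("VC", "SNP"),
                    "statistic": float(rec.info.get("CS", np.nan)),
                    "p_value": float(rec.info.get("CP", np.nan)),
                    "total_reads": int(rec.info.get("TR", 0)),
                    "verdict": filt[0] if filt else "PASS",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig",
            "pos0",
            "ref_allele",
            "var_allele",
            "variant_class",
            "statistic",
            "p_value",
            "total_reads",
            "verdict",
        ],
    )
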