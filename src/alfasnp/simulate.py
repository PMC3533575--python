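"""Synthetic mixed-ploidy panel generator with known truth.

The generator emulates the kind of panel this pipeline targets: 27
genotypes in three groups (16 elite tetraploids from four breeding-program
subgroups of four, 6 cultivated tetraploid mapping parents, and 5 wild
genotypes — two diploid caerulea, two diploid falcata, one tetraploid
falcata), genotyped at biallelic transcript-contig sites.

Model, per site:

* an ancestral variant-allele frequency p is drawn from a U-shaped Beta
  law (default Beta(0.5, 0.5), a realistic site-frequency spectrum) or a
  uniform law on a configurable support;
* each group's frequency drifts from p under the Balding-Nichols model:
  Beta(p (1-F)/F, (1-p)(1-F)/F) with per-group divergence F (F = 0 copies
  p exactly; F = 1 is degenerate and rejected);
* each genotype's variant dosage is Binomial(ploidy, group frequency) —
  tetrasomic (ploidy 4) or disomic (ploidy 2) Hardy-Weinberg within the
  group;
* read depth per genotype is negative binomial (overdispersed, as in
  transcriptome data) with Poisson as the infinite-dispersion limit; each
  read carries the variant allele with probability dosage/ploidy, flipped
  by a per-read miscall probability; the mean variant-base quality is
  Gaussian on the Phred scale, truncated at zero.

Every random draw flows from the single config seed, so identical configs
produce byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CountsTable, DataError, GroupSpec, write_contigs, write_counts_table, write_groups

__all__ = ["PanelConfig", "TruthSet", "simulate_frequencies", "simulate_genotypes",
           "simulate_read_counts", "simulate_panel", "write_panel", "default_panel_config"]

_BASES = np.array(list("ACGT"))


@dataclass
class PanelConfig:
    """All knobs of the panel simulation; the defaults mirror the target
    study design (27 genotypes, 3 groups, 4 elite subgroups, mixed ploidy,
    ~56x mean transcriptome depth)."""

    group_sizes: tuple[int, ...] = (16, 6, 5)
    group_names: tuple[str, ...] = ("Group1", "Group2", "Group3")
    # ploidy per genotype, concatenated in group order; None -> all 4x
    # except the default wild group layout (2x,2x,2x,2x,4x)
    ploidies: tuple[int, ...] | None = None
    n_contigs: int = 200
    sites_per_contig: int = 10
    contig_length: int = 1065  # bp, study-scale average transcript contig
    # ancestral-frequency law: U-shaped Beta by default (realistic site
    # frequency spectrum), or uniform on [maf_low, maf_high]
    maf_law: str = "beta"
    beta_a: float = 0.5
    beta_b: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.95
    group_divergence: tuple[float, ...] = (0.05, 0.05, 0.30)
    mean_depth: float = 56.0
    depth_dispersion: float | None = 5.0  # NB size; None = Poisson
    error_rate: float = 0.005
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    indel_fraction: float = 0.035
    anchor_fraction: float = 0.65
    n_chromosomes: int = 8
    chromosome_length: int = 50_000_000
    seed: int = 0

    def validate(self) -> None:
        if len(self.group_sizes) != len(self.group_names) or len(self.group_sizes) != len(self.group_divergence):
            raise DataError("group_sizes, group_names, group_divergence lengths differ")
        if any(s < 1 for s in self.group_sizes):
            raise DataError("group sizes must be positive")
        for f in self.group_divergence:
            if not 0.0 <= f < 1.0:
                raise DataError("group divergence F must lie in [0, 1); F=1 is degenerate")
        for p in (self.error_rate, self.indel_fraction, self.anchor_fraction):
            if not 0.0 <= p <= 1.0:
                raise DataError("probabilities must lie in [0, 1]")
        if not 0.0 <= self.maf_low <= self.maf_high <= 1.0:
            raise DataError("ancestral frequency support must satisfy 0 <= low <= high <= 1")
        if self.maf_law not in ("beta", "uniform"):
            raise DataError(f"unknown maf_law {self.maf_law!r}")
        if self.maf_law == "beta" and (self.beta_a <= 0 or self.beta_b <= 0):
            raise DataError("beta parameters must be positive")
        if self.mean_depth <= 0:
            raise DataError("mean_depth must be positive")
        if self.depth_dispersion is not None and self.depth_dispersion <= 0:
            raise DataError("depth_dispersion must be positive (or None for Poisson)")
        for p in self.ploidy_list():
            if p not in (2, 4):
                raise DataError("ploidy must be 2 or 4")

    @property
    def n_genotypes(self) -> int:
        return sum(self.group_sizes)

    @property
    def n_sites(self) -> int:
        return self.n_contigs * self.sites_per_contig

    def genotype_ids(self) -> list[str]:
        if self.group_sizes == (16, 6, 5):
            elite = [f"{prog}-{i}" for prog in ("FGI", "CW", "PIO", "DL") for i in range(1, 5)]
            parents = [f"MP-{i}" for i in range(1, 7)]
            wild = ["CAE-1", "CAE-2", "FAL-1", "FAL-2", "FALT-1"]
            return elite + parents + wild
        out = []
        for name, size in zip(self.group_names, self.group_sizes):
            out.extend(f"{name}.{i}" for i in range(1, size + 1))
        return out

    def ploidy_list(self) -> list[int]:
        if self.ploidies is not None:
            if len(self.ploidies) != self.n_genotypes:
                raise DataError("ploidies length must equal total genotype count")
            return list(self.ploidies)
        if self.group_sizes == (16, 6, 5):
            return [4] * 22 + [2, 2, 2, 2, 4]
        return [4] * self.n_genotypes

    def group_index(self) -> np.ndarray:
        """Group index per genotype, in genotype order."""
        idx = []
        for g, size in enumerate(self.group_sizes):
            idx.extend([g] * size)
        return np.array(idx)

    def group_spec(self) -> GroupSpec:
        ids = self.genotype_ids()
        ploidy = dict(zip(ids, self.ploidy_list()))
        groups: dict[str, list[str]] = {}
        start = 0
        for name, size in zip(self.group_names, self.group_sizes):
            groups[name] = ids[start : start + size]
            start += size
        if self.group_sizes == (16, 6, 5):
            for prog in ("FGI", "CW", "PIO", "DL"):
                groups[prog] = [g for g in ids if g.startswith(prog + "-")]
        return GroupSpec(groups=groups, ploidy=ploidy)


@dataclass
class TruthSet:
    """Ground truth behind a simulated panel."""

    sites: pd.DataFrame  # contig, pos0, ref_allele, var_allele, variant_class
    group_frequencies: np.ndarray  # sites x groups
    dosages: np.ndarray  # sites x genotypes, variant-allele copies
    ploidy: np.ndarray  # per genotype
    is_snp: np.ndarray  # per site: SNP class AND segregating in the panel

    def validate(self) -> None:
        if (self.dosages > self.ploidy[None, :]).any() or (self.dosages < 0).any():
            raise DataError("dosage out of [0, ploidy]")
        if ((self.group_frequencies < 0) | (self.group_frequencies > 1)).any():
            raise DataError("frequency out of [0, 1]")


def simulate_frequencies(config: PanelConfig,
                         rng: np.random.Generator | None = None,
                         ancestral: np.ndarray | None = None) -> np.ndarray:
    """Draw per-group variant-allele frequencies for every site.

    Ancestral p follows the configured law unless supplied; each group's
    frequency is Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols) with that
    group's F, copying p exactly at F = 0 and collapsing to 0/1 at fixed
    ancestral alleles.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_sites if ancestral is None else len(ancestral)
    if ancestral is not None:
        p = np.asarray(ancestral, dtype=float)
    elif config.maf_law == "beta":
        p = rng.beta(config.beta_a, config.beta_b, size=n)
    else:
        p = rng.uniform(config.maf_low, config.maf_high, size=n)
    if ((p < 0) | (p > 1)).any():
        raise DataError("ancestral frequencies must lie in [0, 1]")
    freqs = np.empty((n, len(config.group_sizes)))
    for g, f in enumerate(config.group_divergence):
        if f == 0.0:
            freqs[:, g] = p
            continue
        scale = (1.0 - f) / f
        interior = (p > 0) & (p < 1)
        freqs[~interior, g] = p[~interior]
        freqs[interior, g] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    return freqs


def simulate_genotypes(frequencies: np.ndarray, config: PanelConfig,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Dosage ~ Binomial(ploidy, group frequency), independent per genotype."""
    if ((frequencies < 0) | (frequencies > 1)).any():
        raise DataError("frequencies must lie in [0, 1]")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gidx = config.group_index()
    ploidy = np.array(config.ploidy_list())
    n_sites = frequencies.shape[0]
    dosages = np.empty((n_sites, config.n_genotypes), dtype=np.int8)
    for j in range(config.n_genotypes):
        dosages[:, j] = rng.binomial(ploidy[j], frequencies[:, gidx[j]])
    return dosages


def _site_frame(config: PanelConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Contig layout, positions and alleles for every simulated site."""
    width = len(str(config.n_contigs))
    contigs = [f"ctg{(i + 1):0{width}d}" for i in range(config.n_contigs)]
    rows = {"contig": [], "pos0": []}
    for c in contigs:
        pos = np.sort(
            rng.choice(config.contig_length, size=config.sites_per_contig, replace=False)
        )
        rows["contig"].extend([c] * config.sites_per_contig)
        rows["pos0"].extend(int(p) for p in pos)
    n = len(rows["contig"])
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    is_indel = rng.random(n) < config.indel_fraction
    ins = _BASES[rng.integers(0, 4, size=n)]
    ref = _BASES[ref_idx]
    var = np.where(is_indel, np.char.add(_BASES[ref_idx], ins), _BASES[alt_idx])
    return pd.DataFrame(
        {
            "contig": rows["contig"],
            "pos0": rows["pos0"],
            "ref_allele": ref,
            "var_allele": var,
            "variant_class": np.where(is_indel, "InDel", "SNP"),
        }
    )


def simulate_read_counts(truth: TruthSet, config: PanelConfig,
                         rng: np.random.Generator | None = None) -> CountsTable:
    """Sequencing layer: depth, allele sampling with miscalls, qualities."""
    truth.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_sites, n_geno = truth.dosages.shape
    shape = (n_sites, n_geno)
    if config.depth_dispersion is None:
        depth = rng.poisson(config.mean_depth, size=shape)
    else:
        r = config.depth_dispersion
        depth = rng.negative_binomial(r, r / (r + config.mean_depth), size=shape)
    p_true = truth.dosages / truth.ploidy[None, :]
    e = config.error_rate
    p_var = p_true * (1 - e) + (1 - p_true) * e
    var = rng.binomial(depth, p_var)
    ref = depth - var
    qual = np.maximum(rng.normal(config.quality_mean, config.quality_sd, size=shape), 0.0)
    qual = np.round(np.where(var > 0, qual, 0.0), 1)
    return CountsTable(
        sites=truth.sites.copy(),
        genotypes=config.genotype_ids(),
        ref_reads=ref.astype(np.int64),
        var_reads=var.astype(np.int64),
        mean_var_qual=qual,
    )


def simulate_panel(config: PanelConfig) -> tuple[CountsTable, TruthSet, GroupSpec, pd.DataFrame]:
    """Full panel: frequencies -> dosages -> read counts (+ contig metadata).

    One generator seeded from ``config.seed`` drives all stages in a fixed
    order, so the result is fully determined by the config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = _site_frame(config, rng)
    freqs = simulate_frequencies(config, rng=rng)
    dosages = simulate_genotypes(freqs, config, rng=rng)
    ploidy = np.array(config.ploidy_list())
    segregating = (dosages.sum(axis=1) > 0) & ((ploidy[None, :] - dosages).sum(axis=1) > 0)
    truth = TruthSet(
        sites=sites,
        group_frequencies=freqs,
        dosages=dosages,
        ploidy=ploidy,
        is_snp=segregating & (sites["variant_class"] == "SNP").to_numpy(),
    )
    counts = simulate_read_counts(truth, config, rng=rng)
    contigs = _contig_frame(config, rng)
    return counts, truth, config.group_spec(), contigs


def _contig_frame(config: PanelConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(config.n_contigs))
    names = [f"ctg{(i + 1):0{width}d}" for i in range(config.n_contigs)]
    anchored = rng.random(config.n_contigs) < config.anchor_fraction
    chrom = rng.integers(1, config.n_chromosomes + 1, size=config.n_contigs)
    pos = rng.integers(0, max(config.chromosome_length - config.contig_length, 1),
                       size=config.n_contigs)
    return pd.DataFrame(
        {
            "contig": names,
            "length": config.contig_length,
            "anchor_chrom": np.where(anchored, np.char.add("chr", chrom.astype(str)), None),
            "anchor_pos": np.where(anchored, pos.astype(float), np.nan),
        }
    )


def default_panel_config(seed: int = 0, **overrides) -> PanelConfig:
    return replace(PanelConfig(seed=seed), **overrides)


# ---------------------------------------------------------------------------
# on-disk panel

def write_panel(counts: CountsTable, truth: TruthSet, groups: GroupSpec,
                contigs: pd.DataFrame, directory) -> dict[str, str]:
    """Write counts TSV, truth VCF, group config and contig metadata.

    Re-reading the files through :mod:`alfasnp.io` reproduces the objects;
    identical inputs give byte-identical files.
    """
    from pathlib import Path

    out = Path(directory)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": str(out / "counts.tsv"),
        "truth_vcf": str(out / "truth.vcf"),
        "groups": str(out / "groups.yaml"),
        "contigs": str(out / "contigs.tsv"),
    }
    write_counts_table(counts, paths["counts"])
    write_groups(groups, paths["groups"])
    write_contigs(contigs, paths["contigs"])
    _write_truth_vcf(truth, counts.genotypes, contigs, paths["truth_vcf"])
    return paths


def _write_truth_vcf(truth: TruthSet, genotypes: list[str],
                     contigs: pd.DataFrame, path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class">',
        '##INFO=<ID=SEG,Number=0,Type=Flag,Description="Site segregates in the panel">',
        '##FORMAT=<ID=DS,Number=1,Type=Integer,Description="True variant-allele dosage">',
    ]
    for _, row in contigs.iterrows():
        lines.append(f"##contig=<ID={row['contig']},length={int(row['length'])}>")
    lines.append("\t".join(["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                            "INFO", "FORMAT"] + genotypes))
    seg = truth.is_snp
    for i, row in enumerate(truth.sites.itertuples(index=False)):
        info = f"VC={row.variant_class}" + (";SEG" if seg[i] else "")
        rec = [row.contig, str(row.pos0 + 1), ".", row.ref_allele, row.var_allele,
               ".", "PASS", info, "DS"]
        rec.extend(str(int(d)) for d in truth.dosages[i])
        lines.append("\t".join(rec))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_truth_vcf(path) -> pd.DataFrame:
    """Truth VCF back as a tidy frame (one row per site, dosage columns)."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            row = {
                "contig": rec.chrom,
                "pos0": rec.pos - 1,
                "ref_allele": rec.ref,
                "var_allele": rec.alts[0],
                "variant_class": rec.info.get("VC", "SNP"),
                "segregating": "SEG" in rec.info,
            }
            for s in samples:
                row[s] = rec.samples[s]["DS"]
            rows.append(row)
    return pd.DataFrame(rows)
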