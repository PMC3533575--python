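"""End-to-end orchestration: simulate/ingest -> call -> genotype ->
partition -> structure, with a machine-readable run report.

A run is driven by a single YAML config (see :class:`RunConfig`); every
stochastic stage draws from the one configured seed, and every output file
is formatted deterministically, so rerunning a config reproduces the
output bytes exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, filtering, genotyping, io, simulate, structure

__all__ = ["RunConfig", "PipelineError", "run_full", "summarize_validation", "load_config"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name for the CLI error message."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "alfasnp_run"
    counts_path: str | None = None
    groups_path: str | None = None
    contigs_path: str | None = None
    simulate: dict | None = None  # PanelConfig overrides; None = use files
    filter_params: filtering.FilterParams = field(default_factory=filtering.FilterParams)
    call_params: genotyping.CallParams = field(default_factory=genotyping.CallParams)
    hrm_flank: int = 18
    venn: list[list[str]] = field(default_factory=list)  # group-name lists
    fixed_difference_pairs: list[list[str]] = field(default_factory=list)
    candidate_scans: list[dict] = field(default_factory=list)
    pooled_diploid_pairs: list[list[str]] = field(default_factory=list)
    density_window: int = 500_000
    clamp_negative_branches: bool = False
    seed: int = 0

    @classmethod
    def demo(cls, out_dir: str, seed: int = 0) -> "RunConfig":
        """Self-contained demo: simulated default panel, full analysis."""
        return cls(
            out_dir=out_dir,
            simulate={"seed": seed},
            venn=[["Group1", "Group2", "Group3"], ["FGI", "CW", "PIO", "DL"]],
            fixed_difference_pairs=[["Group1", "Group3"], ["Group2", "Group3"], ["Group1", "Group2"]],
            candidate_scans=[
                {"label": "domestication", "polymorphic_in": ["Group3"],
                 "fixed_in": ["Group1", "Group2"]},
            ],
            pooled_diploid_pairs=[["CAE-1", "CAE-2"], ["FAL-1", "FAL-2"]],
            seed=seed,
        )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise io.DataError(f"{path}: config must be a mapping")
    cfg = RunConfig()
    simple = {
        "out_dir", "counts_path", "groups_path", "contigs_path", "simulate",
        "hrm_flank", "venn", "fixed_difference_pairs", "candidate_scans",
        "pooled_diploid_pairs", "density_window", "clamp_negative_branches", "seed",
    }
    for key, val in doc.items():
        if key in simple:
            setattr(cfg, key, val)
        elif key == "filter_params":
            cfg.filter_params = filtering.FilterParams(**val)
        elif key == "call_params":
            cfg.call_params = genotyping.CallParams(**val)
        else:
            raise io.DataError(f"{path}: unknown config key {key!r}")
    return cfg


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - report stage + cause
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


def run_full(config: RunConfig) -> dict:
    """Run the whole pipeline; returns the run report (also written as JSON).

    Emits, under ``config.out_dir``: calls.vcf, genotypes.tsv,
    heterozygosity.tsv, venn_*.tsv, fixed_differences.tsv,
    candidate_contigs.tsv, hrm_eligible.tsv, snp_density.bedgraph,
    distances.phylip, tree.nwk, pca_scores.tsv, pca_variance.tsv and
    report.json.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    counts, groups, contigs = _ingest(config, out)
    report["sites_in"] = counts.n_sites
    report["n_genotypes"] = len(counts.genotypes)

    calls = _call_stage(counts, config)
    n_pass = int((calls["verdict"] == filtering.PASS).sum())
    pass_class = calls.loc[calls["verdict"] == filtering.PASS, "variant_class"]
    report["calls"] = {
        "pass": n_pass,
        "pass_snps": int((pass_class == "SNP").sum()),
        "pass_indels": int((pass_class == "InDel").sum()),
        "fail_sample_support": int((calls["verdict"] == filtering.FAIL_SUPPORT).sum()),
        "fail_total_depth": int((calls["verdict"] == filtering.FAIL_DEPTH).sum()),
        "fail_contingency": int((calls["verdict"] == filtering.FAIL_TEST).sum()),
    }
    io.write_vcf(calls, out / "calls.vcf", contigs=contigs)

    hrm = _hrm_stage(calls, contigs, config)
    report["hrm_eligible"] = len(hrm)
    hrm.to_csv(out / "hrm_eligible.tsv", sep="\t", index=False,
               float_format="%.6g", lineterminator="\n")

    matrix = _genotype_stage(calls, counts, groups, config)
    report["core_set_size"] = matrix.n_sites
    genotyping.write_genotype_matrix(matrix, out / "genotypes.tsv")

    report["heterozygosity_pct"] = _het_stage(matrix, groups, config, out)
    report["venn"] = _partition_stage(matrix, groups, calls, contigs, config, out)
    report.update(_structure_stage(matrix, config, out))

    if report["core_set_size"] > n_pass:
        raise PipelineError("report", "core set larger than PASS set")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


@_stage("ingest")
def _ingest(config: RunConfig, out: Path):
    if config.simulate is not None:
        sim_cfg = simulate.default_panel_config(**{"seed": config.seed, **config.simulate})
        counts, truth, groups, contigs = simulate.simulate_panel(sim_cfg)
        simulate.write_panel(counts, truth, groups, contigs, out / "panel")
        return counts, groups, contigs
    if not (config.counts_path and config.groups_path and config.contigs_path):
        raise io.DataError("need counts_path, groups_path and contigs_path (or a simulate block)")
    counts = io.read_counts_table(config.counts_path)
    groups = io.read_groups(config.groups_path)
    contigs = io.read_contigs(config.contigs_path)
    return counts, groups, contigs


@_stage("call")
def _call_stage(counts, config: RunConfig):
    params = config.filter_params
    params.seed = config.seed
    return filtering.call_variants(counts, params)


@_stage("hrm_select")
def _hrm_stage(calls, contigs, config: RunConfig):
    return filtering.hrm_eligible(calls, contigs, flank=config.hrm_flank)


@_stage("genotype")
def _genotype_stage(calls, counts, groups, config: RunConfig):
    return genotyping.core_set(calls, counts, groups, config.call_params)


@_stage("heterozygosity")
def _het_stage(matrix, groups, config: RunConfig, out: Path) -> dict:
    het: dict[str, float] = {}
    if matrix.n_sites:
        for gid in matrix.genotypes:
            het[gid] = round(genotyping.heterozygosity(matrix, gid), 2)
        for pair in config.pooled_diploid_pairs:
            a, b = pair
            pooled = genotyping.pool_diploids(matrix, a, b)
            classified = pooled != io.MISSING
            if classified.any():
                het[f"pooled:{a}+{b}"] = round(
                    float((pooled[classified] == io.STATE_AB).mean() * 100.0), 2
                )
    pd.DataFrame(sorted(het.items()), columns=["genotype", "heterozygosity_pct"]).to_csv(
        out / "heterozygosity.tsv", sep="\t", index=False, lineterminator="\n"
    )
    return het


@_stage("partition")
def _partition_stage(matrix, groups, calls, contigs, config: RunConfig, out: Path) -> dict:
    venn_report: dict = {}
    for names in config.venn:
        profile = diversity.group_polymorphism(matrix, groups, list(names))
        regions = diversity.venn_regions(profile)
        tag = "_".join(names)
        rows = [
            {"region": "&".join(key), "count": cnt}
            for key, cnt in sorted(regions.items())
        ]
        pd.DataFrame(rows).to_csv(out / f"venn_{tag}.tsv", sep="\t", index=False,
                                  lineterminator="\n")
        venn_report[tag] = {"total_polymorphic": int(sum(regions.values()))}

    fixed_rows = []
    for pair in config.fixed_difference_pairs:
        fd = diversity.fixed_differences(matrix, groups, (pair[0], pair[1]))
        for _, row in fd.iterrows():
            fixed_rows.append({"group_a": pair[0], "group_b": pair[1],
                               "contig": row["contig"], "pos0": row["pos0"]})
    pd.DataFrame(fixed_rows, columns=["group_a", "group_b", "contig", "pos0"]).to_csv(
        out / "fixed_differences.tsv", sep="\t", index=False, lineterminator="\n"
    )
    venn_report["fixed_differences"] = len(fixed_rows)

    cand_frames = []
    for scan in config.candidate_scans:
        cand_frames.append(
            diversity.candidate_contigs(
                matrix, groups,
                polymorphic_in=list(scan["polymorphic_in"]),
                fixed_in=list(scan["fixed_in"]),
                min_cluster=int(scan.get("min_cluster", 5)),
                label=str(scan.get("label", "candidate")),
            )
        )
    cand = (
        pd.concat(cand_frames, ignore_index=True)
        if cand_frames
        else pd.DataFrame(columns=["contig", "n_snps", "positions", "criterion"])
    )
    cand.to_csv(out / "candidate_contigs.tsv", sep="\t", index=False, lineterminator="\n")
    venn_report["candidate_contigs"] = len(cand)

    dens = diversity.snp_density_windows(calls, contigs, window=config.density_window)
    dens.to_csv(out / "snp_density.bedgraph", sep="\t", index=False, header=False,
                float_format="%.6f", lineterminator="\n")
    venn_report["density_windows"] = len(dens)
    return venn_report


@_stage("structure")
def _structure_stage(matrix, config: RunConfig, out: Path) -> dict:
    if matrix.n_sites == 0 or len(matrix.genotypes) < 3:
        raise io.DataError("structure stage needs a non-empty matrix and >= 3 genotypes")
    dist = structure.simple_matching_distance(matrix)
    structure.write_phylip_distances(dist, out / "distances.phylip")
    tree = structure.neighbor_joining(dist, clamp_negative=config.clamp_negative_branches)
    structure.write_newick(tree, out / "tree.nwk")
    pc = structure.pca(matrix)
    structure.write_pca(pc, out / "pca_scores.tsv", out / "pca_variance.tsv")
    return {
        "distance_max": round(float(dist.values.max()), 6),
        "pca_variance_pct": [round(float(v * 100), 2) for v in pc.variance_fraction[:5]],
    }


def summarize_validation(attempted: int, amplified: int, concordant: int) -> dict:
    """Assay-validation accounting: amplification and concordance rates.

    Amplification rate = amplified/attempted, concordance = concordant/
    amplified, both as integer-rounded percentages (matching how such
    assay panels are reported).
    """
    if attempted <= 0:
        raise io.DataError("no assays attempted: rates undefined")
    if amplified > attempted or concordant > amplified or amplified < 0 or concordant < 0:
        raise io.DataError("inconsistent validation counts")
    out = {
        "attempted": attempted,
        "amplified": amplified,
        "amplification_pct": round(amplified / attempted * 100),
    }
    if amplified == 0:
        out["concordance_pct"] = None
    else:
        out["concordant"] = concordant
        out["concordance_pct"] = round(concordant / amplified * 100)
    return out
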