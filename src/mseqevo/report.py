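"""Cross-module summaries and the end-to-end pipeline driver.

The single-region vs multi-region comparison quantifies the 'illusion of
clonality': a mutation that is heterogeneous tumour-wide (shared or
private across regions) yet reaches CCF >= 0.7 in some region would be
mis-read as clonal from that region alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .catalogs import default_driver_catalog, synthetic_signature_catalog
from .clonality import CCF_CLONAL_THRESHOLD, build_ccf_matrix, ccf_wide, time_gains
from .cna import SegmentProfile, detect_loh, ploidy, wgii
from .io import sha256_file, write_fasta, write_segments, write_truth, write_tsv
from .phylo import assign_clades, build_tree, cluster_ccfs, detect_parallel_evolution, explain_conflicts
from .selection import build_opportunity, dnds
from .signatures import fit_groups, report_exposures, spectra_by_group
from .simdata import SimulationConfig, simulate_normal_panel, simulate_tumour
from .variants import (
    PresenceMatrix,
    categorize_counts,
    classify_driver,
    cross_germline_filter,
    quality_filter,
    two_tier_call,
)

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class ClonalityComparison:
    per_region: pd.DataFrame  # total/clonal/ubiquitous loads + percent diffs
    per_gene: pd.DataFrame  # driver-gene illusion fractions
    overall_illusion_pct: float


def illusion_of_clonality(
    pm: PresenceMatrix,
    ccf_long: pd.DataFrame,
    driver_flags: pd.Series,
    threshold: float = CCF_CLONAL_THRESHOLD,
) -> ClonalityComparison:
    """Single-region vs multi-region clonality comparison.

    An observation (mutation, region) is illusory iff the mutation is
    heterogeneous (shared/private tumour-wide) yet its CCF in that region
    is >= ``threshold``.  Driver-level percentages count observations.
    """
    het_ids = set(pm.category[pm.category != "ubiquitous"].index)
    ub_count = int((pm.category == "ubiquitous").sum())
    obs = ccf_long.copy()
    obs["clonal_sr"] = obs["ccf"] >= threshold
    rows = []
    for rid in pm.regions:
        sub = obs[obs["region"] == rid]
        total = int(len(sub))
        clonal = int(sub["clonal_sr"].sum())
        rows.append(
            {
                "region": rid,
                "total_load": total,
                "clonal_load": clonal,
                "ubiquitous_load": ub_count,
                "pct_diff_total": 100.0 * (total - ub_count) / ub_count if ub_count else np.nan,
                "pct_diff_clonal": 100.0 * (clonal - ub_count) / ub_count if ub_count else np.nan,
            }
        )
    per_region = pd.DataFrame(rows)

    drv = driver_flags.reindex(pm.presence.index, fill_value=False)
    drv_het = obs[obs["mut_id"].isin(het_ids) & obs["mut_id"].map(drv).fillna(False)]
    gene_of = pm.sites["gene"] if "gene" in pm.sites.columns else pd.Series(dtype=object)
    gene_rows = []
    if not drv_het.empty:
        genes = drv_het["mut_id"].map(gene_of)
        for gene, grp in drv_het.groupby(genes):
            gene_rows.append(
                {
                    "gene": gene,
                    "n_observations": int(len(grp)),
                    "n_illusory": int(grp["clonal_sr"].sum()),
                    "illusion_pct": 100.0 * grp["clonal_sr"].mean(),
                }
            )
    per_gene = pd.DataFrame(
        gene_rows, columns=["gene", "n_observations", "n_illusory", "illusion_pct"]
    )
    overall = 100.0 * drv_het["clonal_sr"].mean() if len(drv_het) else float("nan")
    return ClonalityComparison(per_region=per_region, per_gene=per_gene, overall_illusion_pct=overall)


def subclonal_fraction(
    ccf_long: pd.DataFrame, threshold: float = CCF_CLONAL_THRESHOLD
) -> pd.Series:
    """Per-region fraction of present mutations with CCF < threshold."""
    if ccf_long.empty:
        raise ValueError("empty CCF table")
    frac = (
        ccf_long.assign(sub=ccf_long["ccf"] < threshold)
        .groupby("region")["sub"]
        .mean()
    )
    frac.name = "subclonal_fraction"
    return frac


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class PipelineResult:
    config: SimulationConfig
    sites_raw: pd.DataFrame
    sites: pd.DataFrame  # retained after all filters
    rejected: pd.DataFrame
    pm: PresenceMatrix
    segments: dict[str, SegmentProfile]
    cna_metrics: pd.DataFrame
    loh: pd.DataFrame
    ccf_long: pd.DataFrame
    timing: pd.DataFrame
    tree: object
    clades: pd.Series
    conflicts: pd.DataFrame
    parallel: pd.DataFrame
    exposures: pd.DataFrame
    dnds_table: pd.DataFrame
    comparison: ClonalityComparison
    subclonal: pd.Series
    truth: object = None
    genome: object = None
    driver_flags: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: SimulationConfig | dict,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Simulate -> filter -> CN metrics -> CCF -> tree -> signatures ->
    dN/dS -> summaries; optionally writes all outputs plus a manifest.

    Deterministic given ``config.seed``.
    """
    if isinstance(config, dict):
        config = SimulationConfig.from_dict(config)
    timings: dict[str, float] = {}

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc is not None and not isinstance(exc, StageError):
                    raise StageError(name, exc) from exc
                return False

        return _Ctx()

    with stage("simulate"):
        sites_raw, segments, truth, genome = simulate_tumour(config)
        panel, artifact_ids = simulate_normal_panel(config, sites_raw)
        truth.artifact_sites = artifact_ids

    with stage("variants"):
        retained, rej_q = quality_filter(sites_raw)
        retained, rej_pon = cross_germline_filter(retained, panel)
        pm = two_tier_call(retained)
        rejected = pd.concat([rej_q, rej_pon, pm.rejected])
        summary = categorize_counts(pm)
        driver_catalog = default_driver_catalog(genome.gene_table)
        drv = classify_driver(pm.sites, driver_catalog)
        driver_flags = drv["likely_driver"]

    with stage("cna"):
        cna_rows = []
        for rid, prof in segments.items():
            pl = ploidy(prof)
            score, cin = wgii(prof)
            cna_rows.append(
                {"region": rid, "purity": prof.purity, "ploidy": pl, "wgii": score, "cin": cin}
            )
        cna_metrics = pd.DataFrame(cna_rows)
        loh = detect_loh(segments, driver_catalog)

    with stage("clonality"):
        ccf_long = build_ccf_matrix(pm, segments)
        timing = time_gains(ccf_long, pm, segments)

    with stage("phylo"):
        wide = ccf_wide(ccf_long, pm.regions)
        wide = wide.reindex(pm.presence.index, fill_value=0.0)
        clusters, unassigned = cluster_ccfs(wide, driver_flags=driver_flags)
        trees = build_tree(clusters, unassigned=unassigned)
        tree = trees[0]
        clades = assign_clades(tree, pm.presence, wide, segments, pm.sites[["chrom", "pos"]])
        conflicts = explain_conflicts(pm.presence, tree, segments, pm.sites[["chrom", "pos"]], wide)
        parallel = detect_parallel_evolution(tree, pm.sites, driver_flags, clades)

    with stage("signatures"):
        catalog = (
            config.signature_catalog
            if config.signature_catalog is not None
            else synthetic_signature_catalog()
        )
        groups = pm.category.map(
            lambda c: "ubiquitous" if c == "ubiquitous" else "heterogeneous"
        )
        spectra = spectra_by_group(pm.sites, genome.chroms, groups)
        exposures = report_exposures(fit_groups(spectra, catalog))

    with stage("selection"):
        model = build_opportunity(genome.coding_sequences(), exclude_internal_stops=False)
        coding = pm.sites[
            (pm.sites["kind"] == "snv")
            & pm.sites["consequence"].isin(["missense", "synonymous", "stop_gained"])
        ]
        muts = _coding_mutation_table(coding, genome, pm.category)
        dnds_table = dnds(muts, model)

    with stage("report"):
        comparison = illusion_of_clonality(pm, ccf_long, driver_flags)
        subc = subclonal_fraction(ccf_long)

    result = PipelineResult(
        config=config, sites_raw=sites_raw, sites=pm.sites, rejected=rejected, pm=pm,
        segments=segments, cna_metrics=cna_metrics, loh=loh, ccf_long=ccf_long,
        timing=timing, tree=tree, clades=clades, conflicts=conflicts, parallel=parallel,
        exposures=exposures, dnds_table=dnds_table, comparison=comparison,
        subclonal=subc, truth=truth, genome=genome, driver_flags=driver_flags,
    )
    result.manifest = {
        "tool": "mseqevo",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": _config_hash(config),
        "category_summary": {k: float(v) for k, v in summary.items()},
        "stage_timings_s": timings,
    }
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _coding_mutation_table(coding: pd.DataFrame, genome, category: pd.Series) -> pd.DataFrame:
    from .contexts import category_of
    from .selection import EDGE_CLASS

    classes = []
    for row in coding.itertuples():
        seq = genome.chroms[str(row.chrom)]
        pos = int(row.pos)
        if pos <= 1 or pos >= len(seq):
            classes.append(EDGE_CLASS)
        else:
            classes.append(category_of(seq[pos - 2 : pos + 1], row.alt))
    return pd.DataFrame(
        {
            "context_class": classes,
            "is_synonymous": (coding["consequence"] == "synonymous").to_numpy(),
            "compartment": category.reindex(coding.index).to_numpy(),
        },
        index=coding.index,
    )


def _config_hash(config: SimulationConfig) -> str:
    payload = {
        k: v
        for k, v in dataclasses.asdict(config).items()
        if not isinstance(v, pd.DataFrame)
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_outputs(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(result.sites_raw, out / "variants_raw.tsv")
    write_tsv(result.sites, out / "variants_filtered.tsv")
    write_tsv(result.rejected, out / "variants_rejected.tsv")
    write_tsv(result.pm.presence.astype(int), out / "presence_matrix.tsv", index=True)
    write_tsv(result.cna_metrics, out / "cna_metrics.tsv")
    write_tsv(result.loh, out / "loh.tsv")
    write_tsv(result.ccf_long, out / "ccf_matrix.tsv")
    write_tsv(result.timing, out / "gain_timing.tsv")
    write_tsv(result.conflicts, out / "conflicts.tsv")
    write_tsv(result.parallel, out / "parallel_evolution.tsv")
    write_tsv(result.exposures, out / "signature_exposures.tsv", index=True)
    write_tsv(result.dnds_table, out / "dnds.tsv")
    write_tsv(result.comparison.per_region, out / "clonality_per_region.tsv")
    write_tsv(result.comparison.per_gene, out / "clonality_per_gene.tsv")
    write_tsv(result.subclonal.reset_index(), out / "subclonal_fraction.tsv")
    for rid, prof in result.segments.items():
        write_segments(prof, out / "segments" / f"{rid}.seg.tsv")
    (out / "tree.nwk").write_text(result.tree.newick() + "\n")
    (out / "tree.json").write_text(result.tree.to_json())
    if result.truth is not None:
        write_truth(result.truth, out / "truth.json")
    if result.genome is not None:
        write_fasta(result.genome.chroms, out / "reference.fa")
    hashes = {
        p.relative_to(out).as_posix(): sha256_file(p)
        for p in sorted(out.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    result.manifest["output_sha256"] = hashes
    result.manifest["manifest_hash"] = hashlib.sha256(
        json.dumps(
            {
                "files": hashes,
                "config": result.manifest["config_sha256"],
                "seed": result.manifest["seed"],
            },
            sort_keys=True,
        ).encode()
    ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
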