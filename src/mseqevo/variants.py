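"""Multi-region somatic mutation filtering and categorisation.

Implements the two-tier multi-region calling strategy: quality filters
(per-region tumour depth, germline depth and germline evidence, sex
chromosomes excluded), a cross-germline panel-of-normals filter, and the
two-tier VAF rule — a mutation is kept if at least one region reaches
VAF >= 5% (tier 1), and per-region presence then requires VAF > 2.5%
(tier 2).  Retained mutations are categorised as ubiquitous (present in
all regions), shared (some but not all) or private (exactly one).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalogs import DISRUPTING_CONSEQUENCES, KNOWN_CONSEQUENCES, parse_changes, parse_positions

log = logging.getLogger(__name__)

_REGION_RE = re.compile(r"REGION_(.+)_DEPTH$")
_SEX_CHROMS = {"X", "Y", "chrX", "chrY"}
NON_SILENT = ("missense", "stop_gained", "frameshift", "splice_site", "inframe_indel")


def region_ids(sites: pd.DataFrame) -> list[str]:
    """Region identifiers encoded in REGION_<id>_DEPTH column names."""
    ids = [m.group(1) for c in sites.columns if (m := _REGION_RE.match(c))]
    if not ids:
        raise ValueError("no REGION_<id>_DEPTH columns found")
    return ids


def vaf_frame(sites: pd.DataFrame) -> pd.DataFrame:
    """Per-mutation, per-region VAF (alt/depth); zero-depth regions get VAF 0."""
    out = {}
    zero_logged = False
    for rid in region_ids(sites):
        depth = sites[f"REGION_{rid}_DEPTH"].to_numpy(dtype=float)
        alt = sites[f"REGION_{rid}_ALT"].to_numpy(dtype=float)
        zero = depth == 0
        if zero.any() and not zero_logged:
            log.warning("zero-depth observations treated as VAF 0")
            zero_logged = True
        out[rid] = np.where(zero, 0.0, alt / np.where(zero, 1.0, depth))
    return pd.DataFrame(out, index=sites.index)


@dataclass
class FilterParams:
    min_region_depth: int = 70
    min_germline_depth: int = 20
    max_germline_vaf: float = 0.02
    max_germline_alt: int = 2
    exclude_sex_chromosomes: bool = True
    # caller-level QC thresholds, recorded for provenance only (raw reads
    # are not inputs to this pipeline)
    provenance: dict = field(
        default_factory=lambda: {
            "min_avg_mapping_quality": 55,
            "min_avg_base_quality": 35,
            "caller_min_vaf": 0.02,
        }
    )


def quality_filter(
    sites: pd.DataFrame, params: FilterParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply depth/germline quality filters.

    Returns (retained, rejected); rejected rows carry a single ``reason``
    — the first failing rule in the fixed order sex_chromosome ->
    tumour_depth -> germline_depth -> germline_evidence.  A germline
    rejection requires BOTH germline VAF > 2% and germline alt count > 2.
    """
    params = params or FilterParams()
    rids = region_ids(sites)
    depth_cols = [f"REGION_{r}_DEPTH" for r in rids]
    tumour_min = sites[depth_cols].min(axis=1)
    g_depth = sites["NORMAL_DEPTH"].to_numpy(dtype=float)
    g_alt = sites["NORMAL_ALT"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        g_vaf = np.where(g_depth > 0, g_alt / np.where(g_depth > 0, g_depth, 1.0), 0.0)

    reason = pd.Series("", index=sites.index, dtype=object)
    if params.exclude_sex_chromosomes:
        sex = sites["chrom"].astype(str).isin(_SEX_CHROMS)
        reason[sex] = "sex_chromosome"
    bad_tumour = (tumour_min < params.min_region_depth) & (reason == "")
    reason[bad_tumour] = "tumour_depth"
    bad_gdepth = (g_depth < params.min_germline_depth) & (reason == "")
    reason[bad_gdepth] = "germline_depth"
    bad_germ = (
        (g_vaf > params.max_germline_vaf)
        & (g_alt > params.max_germline_alt)
        & (reason == "")
    )
    reason[bad_germ] = "germline_evidence"

    retained = sites[reason == ""].copy()
    rejected = sites[reason != ""].copy()
    rejected["reason"] = reason[reason != ""]
    return retained, rejected


def cross_germline_filter(
    sites: pd.DataFrame,
    panel_vaf: pd.DataFrame,
    vaf_min: float = 0.02,
    prevalence: float = 0.20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Panel-of-normals filter: drop a site iff the fraction of normals
    with VAF >= ``vaf_min`` is >= ``prevalence``."""
    if panel_vaf.shape[1] == 0:
        raise ValueError("panel is empty")
    flagged = (panel_vaf >= vaf_min).mean(axis=1) >= prevalence
    flagged = flagged.reindex(sites.index, fill_value=False)
    retained = sites[~flagged].copy()
    rejected = sites[flagged].copy()
    rejected["reason"] = "panel_of_normals"
    return retained, rejected


@dataclass
class PresenceMatrix:
    """Tier-2 presence calls with categories for retained mutations."""

    presence: pd.DataFrame  # mutations x regions, bool
    vaf: pd.DataFrame  # mutations x regions
    category: pd.Series  # ubiquitous | shared | private
    sites: pd.DataFrame  # retained site annotations
    rejected: pd.DataFrame  # tier-1 failures

    @property
    def regions(self) -> list[str]:
        return list(self.presence.columns)


def categorize(presence: pd.DataFrame) -> pd.Series:
    n = presence.sum(axis=1)
    cat = pd.Series("shared", index=presence.index, dtype=object)
    cat[n == presence.shape[1]] = "ubiquitous"
    cat[n == 1] = "private"
    return cat


def two_tier_call(
    sites: pd.DataFrame, tier1_vaf: float = 0.05, tier2_vaf: float = 0.025
) -> PresenceMatrix:
    """Two-tier calling: keep a mutation iff some region reaches
    ``tier1_vaf`` (>=); call per-region presence at VAF strictly above
    ``tier2_vaf``."""
    vaf = vaf_frame(sites)
    keep = vaf.max(axis=1) >= tier1_vaf
    presence = vaf.loc[keep] > tier2_vaf
    rejected = sites[~keep].copy()
    rejected["reason"] = "tier1_max_vaf"
    return PresenceMatrix(
        presence=presence,
        vaf=vaf.loc[keep],
        category=categorize(presence),
        sites=sites.loc[keep].copy(),
        rejected=rejected,
    )


def categorize_counts(pm: PresenceMatrix, non_silent_only: bool = True) -> pd.Series:
    """Ubiquitous / heterogeneous summary (heterogeneous = shared + private)."""
    if non_silent_only and "consequence" in pm.sites.columns:
        mask = pm.sites["consequence"].isin(NON_SILENT)
    else:
        mask = pd.Series(True, index=pm.sites.index)
    cat = pm.category[mask.to_numpy()]
    total = int(len(cat))
    ub = int((cat == "ubiquitous").sum())
    het = total - ub
    return pd.Series(
        {
            "non_silent_total": total,
            "ubiquitous": ub,
            "heterogeneous": het,
            "pct_ubiquitous": 100.0 * ub / total if total else 0.0,
            "pct_heterogeneous": 100.0 * het / total if total else 0.0,
        }
    )


def classify_driver(sites: pd.DataFrame, driver_catalog: pd.DataFrame) -> pd.DataFrame:
    """Three-rule likely-driver classification.

    Rule 1: the exact amino-acid change is a known alteration for the gene.
    Rule 2: a disrupting mutation (frameshift / nonsense / splice-site) in
    a catalogued tumour suppressor gene.
    Rule 3: an amino-acid change at a catalogued altered position that is
    distinct from the known change.
    Returns a frame (likely_driver, driver_rule) indexed like ``sites``.
    """
    unknown = set(sites["consequence"].dropna().unique()) - KNOWN_CONSEQUENCES - {""}
    if unknown:
        raise ValueError(f"unknown consequence terms: {sorted(unknown)}")
    cat = driver_catalog.set_index("gene")
    flags = np.zeros(len(sites), dtype=bool)
    rules = np.array([""] * len(sites), dtype=object)
    pos_re = re.compile(r"[A-Z*](\d+)")
    for i, row in enumerate(sites.itertuples()):
        gene = getattr(row, "gene", "")
        if not gene or gene not in cat.index:
            continue
        entry = cat.loc[gene]
        change = getattr(row, "protein_change", "") or ""
        known_changes = parse_changes(entry["known_changes"])
        known_pos = parse_positions(entry["known_positions"])
        if change and change in known_changes:
            flags[i], rules[i] = True, "known_alteration"
            continue
        if row.consequence in DISRUPTING_CONSEQUENCES and entry["role"] == "TSG":
            flags[i], rules[i] = True, "disrupting_in_tsg"
            continue
        m = pos_re.match(change)
        if m and int(m.group(1)) in known_pos and change not in known_changes:
            flags[i], rules[i] = True, "known_position"
    return pd.DataFrame(
        {"likely_driver": flags, "driver_rule": rules}, index=sites.index
    )
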