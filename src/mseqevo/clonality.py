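"""Mutation copy number, multiplicity, cancer-cell fraction and gain timing.

The mutation copy number (copies of the mutant allele per cancer cell)
is computed from the VAF, tumour purity p and the locus total copy
number CN_t:

    MUT_CN = VAF * (1/p) * (p * CN_t + 2 * (1 - p))

Multiplicity m is the nearest integer to MUT_CN clamped to [1, cn_major],
and CCF = MUT_CN / m (reported capped at 1, raw value retained).  A
mutation-region observation is clonal when CCF >= 0.7.

Copy-number gains are timed from the multiplicity of ubiquitous
mutations inside the gained segment: a near-complete absence of
mutations at full multiplicity (fraction <= 5% by default) indicates
the gain preceded most mutation accrual (early); otherwise it is late.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cna import SegmentProfile
from .variants import PresenceMatrix

CCF_CLONAL_THRESHOLD = 0.7

CCF_COLUMNS = [
    "mut_id", "region", "vaf", "cn_total", "cn_major", "mut_cn",
    "multiplicity", "ccf", "ccf_raw", "clonal",
]


def mutation_copy_number(vaf, p, cn_total):
    """MUT_CN from VAF, purity and locus total copy number (vectorised)."""
    vaf = np.asarray(vaf, dtype=float)
    p = np.asarray(p, dtype=float)
    cn_total = np.asarray(cn_total, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("purity must be in (0, 1]")
    if np.any(cn_total <= 0):
        raise ValueError("cn_total must be positive")
    return vaf * (1.0 / p) * (p * cn_total + 2.0 * (1.0 - p))


def ccf(mut_cn, cn_major):
    """(multiplicity, capped CCF, raw CCF) via the nearest-integer rule."""
    mut_cn = np.asarray(mut_cn, dtype=float)
    cn_major = np.asarray(cn_major)
    if np.any(mut_cn < 0):
        raise ValueError("mut_cn must be non-negative")
    if np.any(np.asarray(cn_major) < 1):
        raise ValueError("cn_major must be >= 1")
    m = np.clip(np.rint(mut_cn), 1, cn_major).astype(int)
    raw = mut_cn / m
    return m, np.minimum(raw, 1.0), raw


def split_clonal(ccf_values, threshold: float = CCF_CLONAL_THRESHOLD):
    """Clonal iff CCF >= threshold (0.7 by default)."""
    return np.asarray(ccf_values, dtype=float) >= threshold


def build_ccf_matrix(
    pm: PresenceMatrix,
    segments: dict[str, SegmentProfile],
    clonal_threshold: float = CCF_CLONAL_THRESHOLD,
) -> pd.DataFrame:
    """Long-format CCF matrix over present (mutation, region) observations.

    CCF is undefined (row omitted) where tier-2 presence is absent.
    """
    sites = pm.sites
    chrom = sites["chrom"].astype(str).to_numpy()
    pos = sites["pos"].to_numpy()
    frames = []
    for rid in pm.regions:
        prof = segments[rid]
        present = pm.presence[rid].to_numpy()
        if not present.any():
            continue
        cn_t, cn_maj = _locus_cn(prof.segments, chrom[present], pos[present])
        vaf = pm.vaf[rid].to_numpy()[present]
        depth = (
            sites[f"REGION_{rid}_DEPTH"].to_numpy()[present]
            if f"REGION_{rid}_DEPTH" in sites.columns
            else np.full(present.sum(), np.nan)
        )
        mut_cn = mutation_copy_number(vaf, prof.purity, cn_t)
        m, capped, raw = ccf(mut_cn, np.maximum(cn_maj, 1))
        frames.append(
            pd.DataFrame(
                {
                    "mut_id": pm.presence.index[present],
                    "region": rid,
                    "vaf": vaf,
                    "depth": depth,
                    "cn_total": cn_t,
                    "cn_major": cn_maj,
                    "mut_cn": mut_cn,
                    "multiplicity": m,
                    "ccf": capped,
                    "ccf_raw": raw,
                    "clonal": split_clonal(capped, clonal_threshold),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=CCF_COLUMNS + ["depth"])
    return pd.concat(frames, ignore_index=True)


def ccf_wide(ccf_long: pd.DataFrame, regions: list[str] | None = None) -> pd.DataFrame:
    """Pivot the long CCF table to mutations x regions (absent -> 0)."""
    wide = ccf_long.pivot(index="mut_id", columns="region", values="ccf")
    if regions is not None:
        wide = wide.reindex(columns=regions)
    return wide.fillna(0.0)


def _locus_cn(seg: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray):
    cn_t = np.full(len(chrom), 2.0)
    cn_m = np.full(len(chrom), 1)
    for c, grp in seg.groupby(seg["chrom"].astype(str)):
        grp = grp.sort_values("start")
        mask = chrom == c
        if not mask.any():
            continue
        idx = np.searchsorted(grp["start"].to_numpy(), pos[mask], side="right") - 1
        idx = np.clip(idx, 0, len(grp) - 1)
        inside = (grp["end"].to_numpy()[idx] >= pos[mask]) & (idx >= 0)
        cn_t[mask] = np.where(inside, grp["cn_total"].to_numpy()[idx], 2.0)
        cn_m[mask] = np.where(inside, grp["cn_major"].to_numpy()[idx], 1)
    return cn_t, cn_m


def time_gain(
    multiplicities: np.ndarray,
    cn_major: int,
    min_mutations: int = 10,
    early_cutoff: float = 0.05,
) -> tuple[str, float]:
    """Time one gained segment from ubiquitous-mutation multiplicities.

    ``stat`` is the fraction of mutations at full multiplicity
    (m == cn_major); the gain is early iff stat <= early_cutoff.
    Returns (label, stat) with label in {early, late, unassessable}.
    """
    if cn_major < 2:
        raise ValueError("gain timing requires cn_major >= 2")
    m = np.asarray(multiplicities)
    if len(m) < min_mutations:
        return "unassessable", float("nan")
    stat = float((m == cn_major).mean())
    return ("early" if stat <= early_cutoff else "late"), stat


def time_gains(
    ccf_long: pd.DataFrame,
    pm: PresenceMatrix,
    segments: dict[str, SegmentProfile],
    min_mutations: int = 10,
    early_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Gain-timing report over all (region, gained segment) pairs.

    Only ubiquitous mutations inside the segment are used.
    """
    ub = set(pm.category[pm.category == "ubiquitous"].index)
    sites = pm.sites
    loc = sites[["chrom", "pos"]].astype({"chrom": str})
    rows = []
    for rid, prof in segments.items():
        sub = ccf_long[(ccf_long["region"] == rid) & ccf_long["mut_id"].isin(ub)]
        merged = sub.merge(loc, left_on="mut_id", right_index=True)
        for _, seg in prof.segments.iterrows():
            if seg["cn_major"] < 2:
                continue
            inside = merged[
                (merged["chrom"] == str(seg["chrom"]))
                & (merged["pos"] >= seg["start"])
                & (merged["pos"] <= seg["end"])
            ]
            label, stat = time_gain(
                inside["multiplicity"].to_numpy(),
                int(seg["cn_major"]),
                min_mutations,
                early_cutoff,
            )
            rows.append(
                {
                    "region": rid,
                    "chrom": seg["chrom"],
                    "start": seg["start"],
                    "end": seg["end"],
                    "cn_major": seg["cn_major"],
                    "n_mutations": len(inside),
                    "full_multiplicity_fraction": stat,
                    "timing": label,
                }
            )
    return pd.DataFrame(rows)
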