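"""Ploidy, weighted genome integrity index (wGII) and LOH calls from
allele-specific copy-number segment profiles.

Ploidy is the segment-length-weighted mean of the unrounded total copy
number.  wGII is, per autosome, the covered-length fraction whose rounded
integer total copy number differs from the rounded ploidy, averaged
(unweighted) over the autosomes present; values above 0.2 flag
chromosomal instability (CIN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_AUTOSOMES = {str(i) for i in range(1, 23)}

SEG_COLUMNS = ["chrom", "start", "end", "cn_total", "cn_major", "cn_minor"]


@dataclass
class SegmentProfile:
    """Allele-specific copy-number segments for one region.

    Coordinates are 1-based inclusive; ``cn_total`` may be unrounded,
    ``cn_major``/``cn_minor`` are integers with major >= minor >= 0.
    """

    region_id: str
    purity: float
    segments: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if not 0 < self.purity <= 1:
            raise ValueError(f"purity must be in (0, 1], got {self.purity}")
        seg = self.segments
        missing = [c for c in SEG_COLUMNS if c not in seg.columns]
        if missing:
            raise ValueError(f"segment table missing columns {missing}")
        if len(seg) and (seg["cn_major"] < seg["cn_minor"]).any():
            raise ValueError("cn_major must be >= cn_minor")
        if len(seg) and (seg["cn_minor"] < 0).any():
            raise ValueError("copy numbers must be non-negative")

    def lengths(self) -> pd.Series:
        return self.segments["end"] - self.segments["start"] + 1

    def state_at(self, chrom: str, pos: int) -> pd.Series | None:
        sub = self.segments[self.segments["chrom"].astype(str) == str(chrom)]
        hit = sub[(sub["start"] <= pos) & (sub["end"] >= pos)]
        if hit.empty:
            return None
        return hit.iloc[0]


def ploidy(profile: SegmentProfile) -> float:
    """Length-weighted mean total copy number over all segments."""
    seg = profile.segments
    if seg.empty:
        raise ValueError("empty segment profile")
    lengths = profile.lengths().to_numpy(dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total segment length must be positive")
    return float((seg["cn_total"].to_numpy() * lengths).sum() / total)


def wgii(profile: SegmentProfile, cin_cutoff: float = 0.2) -> tuple[float, bool]:
    """wGII score and CIN call (score strictly above ``cin_cutoff``).

    Per autosome present in the profile: the fraction of covered length
    in segments whose rounded integer total CN differs from the rounded
    ploidy; the score is the unweighted mean across those autosomes.
    Autosomes absent from the profile are excluded from the mean.
    """
    seg = profile.segments
    auto = seg[seg["chrom"].astype(str).str.removeprefix("chr").isin(_AUTOSOMES)]
    if auto.empty:
        raise ValueError("no autosomal segments")
    target = int(np.rint(ploidy(profile)))
    missing = _AUTOSOMES - set(auto["chrom"].astype(str).str.removeprefix("chr"))
    if missing:
        log.info("wGII: %d autosomes absent from profile, excluded", len(missing))
    fracs = []
    for _, grp in auto.groupby(auto["chrom"].astype(str)):
        lengths = (grp["end"] - grp["start"] + 1).to_numpy(dtype=float)
        aberrant = np.rint(grp["cn_total"].to_numpy()).astype(int) != target
        fracs.append((lengths * aberrant).sum() / lengths.sum())
    score = float(np.mean(fracs))
    return score, bool(score > cin_cutoff)


def detect_loh(
    profiles: dict[str, SegmentProfile], gene_catalog: pd.DataFrame
) -> pd.DataFrame:
    """Per-gene, per-region LOH (minor allele lost, at least one copy kept).

    ``gene_catalog`` needs columns gene, chrom, start, end.  Returns a long
    table (gene, region, loh, assessable) plus an ``ubiquitous`` column on
    the per-gene aggregation: True when LOH is present in every region.
    """
    rows = []
    for _, g in gene_catalog.iterrows():
        mid = (int(g["start"]) + int(g["end"])) // 2
        for rid, prof in profiles.items():
            state = prof.state_at(str(g["chrom"]), mid)
            if state is None:
                rows.append({"gene": g["gene"], "region": rid, "loh": False, "assessable": False})
                continue
            loh = bool(state["cn_minor"] == 0 and state["cn_major"] >= 1)
            rows.append({"gene": g["gene"], "region": rid, "loh": loh, "assessable": True})
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    ub = out.groupby("gene").apply(
        lambda d: bool(d["assessable"].all() and d["loh"].all()), include_groups=False
    )
    out["ubiquitous"] = out["gene"].map(ub)
    return out
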