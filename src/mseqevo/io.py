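"""Plain-text readers and writers (TSV / FASTA / JSON / Newick / YAML)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cna import SEG_COLUMNS, SegmentProfile
from .simdata import GroundTruth, SimulationConfig


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if "mut_id" in df.columns:
        df = df.set_index("mut_id", drop=False)
    for col in ("gene", "consequence", "protein_change"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return df


def write_segments(profile: SegmentProfile, path: str | Path) -> Path:
    out = profile.segments[SEG_COLUMNS].copy()
    out.insert(0, "region", profile.region_id)
    out["purity"] = profile.purity
    return write_tsv(out, path)


def read_segments(path: str | Path) -> SegmentProfile:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    region = str(df["region"].iloc[0]) if "region" in df.columns else Path(path).stem
    purity = float(df["purity"].iloc[0]) if "purity" in df.columns else 1.0
    return SegmentProfile(region_id=region, purity=purity, segments=df[SEG_COLUMNS])


def write_fasta(chroms: dict[str, str], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in chroms.items()]
    SeqIO.write(records, str(path), "fasta")
    return path


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "parent": {str(k): v for k, v in truth.parent.items()},
        "region_ids": truth.region_ids,
        "purity": {k: float(v) for k, v in truth.purity.items()},
        "clone_fractions": truth.clone_fractions.round(10).to_dict(orient="index"),
        "clone_ccf": truth.clone_ccf.round(10).to_dict(orient="index"),
        "mutation_clone": {k: int(v) for k, v in truth.mutation_clone.items()},
        "gain_timing": {str(k): v for k, v in truth.gain_timing.items()},
        "lost_mutations": sorted(list(map(list, truth.lost_mutations))),
        "artifact_sites": list(truth.artifact_sites),
        "events": [e.__dict__ for e in truth.events],
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimulationConfig.from_dict(data)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
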