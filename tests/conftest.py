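import logging

import numpy as np
import pandas as pd
import pytest

from mseqevo.report import run_pipeline
from mseqevo.simdata import SimulationConfig

logging.getLogger("mseqevo").setLevel(logging.ERROR)

REGIONS = ["R1", "R2", "R3"]


def make_sites(rows, regions=REGIONS):
    """Small variant-table builder.

    Each row: dict with chrom, pos, ref, alt, kind, optional gene /
    consequence / protein_change, vafs (list, one per region), and
    optional depth, normal_depth, normal_alt.
    """
    out = []
    for i, r in enumerate(rows):
        depth = r.get("depth", 200)
        rec = {
            "mut_id": r.get("mut_id", f"M{i + 1:04d}"),
            "chrom": str(r.get("chrom", "1")),
            "pos": int(r.get("pos", 1000 + i)),
            "ref": r.get("ref", "C"),
            "alt": r.get("alt", "T"),
            "kind": r.get("kind", "snv"),
            "gene": r.get("gene", ""),
            "consequence": r.get("consequence", "missense"),
            "protein_change": r.get("protein_change", ""),
            "NORMAL_DEPTH": r.get("normal_depth", 100),
            "NORMAL_ALT": r.get("normal_alt", 0),
        }
        depths = r.get("depths", [depth] * len(regions))
        for rid, vaf, d in zip(regions, r["vafs"], depths):
            rec[f"REGION_{rid}_DEPTH"] = d
            rec[f"REGION_{rid}_ALT"] = int(round(vaf * d))
        out.append(rec)
    df = pd.DataFrame(out)
    return df.set_index("mut_id", drop=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """One full pipeline run on the default study conditions."""
    out = tmp_path_factory.mktemp("demo")
    return run_pipeline(SimulationConfig(seed=3), out_dir=out)
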