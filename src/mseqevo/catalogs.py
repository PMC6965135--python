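"""Signature and driver-gene catalogs.

The signature catalog is a 96-context x S table of probability columns.
Real analyses refit against the COSMIC v2 catalog; since that table is
third-party data, :func:`synthetic_signature_catalog` builds a synthetic
30-column catalog of the same shape, with a few columns crafted to mimic
processes relevant to mismatch-repair-deficient tumours (spontaneous CpG
deamination, MSI-associated C>T/C>A richness) and the remainder drawn
from a sparse Dirichlet.  Tests also use orthogonal catalogs.

The driver catalog lists gene roles (oncogene / tumour suppressor),
known protein changes and known altered positions, which drive the
three-rule likely-driver classification.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .contexts import BASES, CONTEXT_LABELS, N_CONTEXTS, category_index


def synthetic_signature_catalog(n_signatures: int = 30, seed: int = 20) -> pd.DataFrame:
    """A synthetic, COSMIC-v2-shaped signature catalog (96 x ``n_signatures``).

    Columns are probability vectors named ``S1..Sn``.  S1 concentrates on
    N[C>T]G (CpG-deamination-like), S6 on broad C>T, S15 on C>T/C>G with a
    G 5' flank; the rest are random sparse spectra.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    cat = rng.dirichlet(np.full(N_CONTEXTS, 0.15), size=n_signatures).T
    catalog = pd.DataFrame(
        cat, index=CONTEXT_LABELS, columns=[f"S{i + 1}" for i in range(n_signatures)]
    )

    def _crafted(weights: dict[int, float], floor: float = 0.02) -> np.ndarray:
        v = np.full(N_CONTEXTS, floor / N_CONTEXTS)
        for idx, w in weights.items():
            v[idx] += w
        return v / v.sum()

    # S1-like: C>T at NpCpG
    catalog["S1"] = _crafted(
        {category_index("C>T", f5, "G"): 1.0 + 0.2 * i for i, f5 in enumerate(BASES)}
    )
    if n_signatures >= 6:
        # S6-like: broad C>T, strongest at G[C>T]N
        w = {}
        for f5 in BASES:
            for f3 in BASES:
                w[category_index("C>T", f5, f3)] = 2.0 if f5 == "G" else 0.5
        catalog["S6"] = _crafted(w)
    if n_signatures >= 15:
        # S15-like: C>T and C>G with G 5' flank
        w = {}
        for f3 in BASES:
            w[category_index("C>T", "G", f3)] = 1.0
            w[category_index("C>G", "G", f3)] = 0.8
            w[category_index("C>A", "T", f3)] = 0.3
        catalog["S15"] = _crafted(w)
    return catalog


def orthogonal_catalog(n_signatures: int = 4) -> pd.DataFrame:
    """A catalog of disjoint-support (hence orthogonal) signature columns."""
    if not 1 <= n_signatures <= 8:
        raise ValueError("n_signatures must be in 1..8")
    block = N_CONTEXTS // n_signatures
    cat = np.zeros((N_CONTEXTS, n_signatures))
    for j in range(n_signatures):
        lo = j * block
        hi = N_CONTEXTS if j == n_signatures - 1 else lo + block
        cat[lo:hi, j] = 1.0 / (hi - lo)
    return pd.DataFrame(
        cat, index=CONTEXT_LABELS, columns=[f"O{i + 1}" for i in range(n_signatures)]
    )


# ---------------------------------------------------------------------------
# Driver catalog
# ---------------------------------------------------------------------------

#: gene -> (chromosome, role, known protein changes, known altered positions)
_DRIVER_GENES: dict[str, tuple[str, str, tuple[str, ...], tuple[int, ...]]] = {
    "ARID1A": ("1", "TSG", (), ()),
    "NRAS": ("1", "oncogene", ("G12C", "Q61K"), (12, 13, 61)),
    "JAK1": ("1", "TSG", (), ()),
    "PRDM2": ("1", "TSG", (), ()),
    "MSH6": ("2", "TSG", (), ()),
    "ACVR2A": ("2", "TSG", (), ()),
    "MLH1": ("3", "TSG", (), ()),
    "PIK3CA": ("3", "oncogene", ("E545K", "H1047R", "Y1021C", "E418K"), (418, 542, 545, 1021, 1047)),
    "PBRM1": ("3", "TSG", (), ()),
    "ATR": ("3", "TSG", (), ()),
    "APC": ("5", "TSG", (), ()),
    "ARID1B": ("6", "TSG", (), ()),
    "JAK2": ("9", "TSG", (), ()),
    "KRAS": ("12", "oncogene", ("G12D", "G13D", "Q61H"), (12, 13, 61)),
    "B2M": ("15", "TSG", (), ()),
    "BLM": ("15", "TSG", (), ()),
    "TP53": ("17", "TSG", ("R175H", "R273C"), (175, 245, 248, 273, 282)),
    "RNF43": ("17", "TSG", (), ()),
    "SMARCA4": ("19", "TSG", (), ()),
    "ARID2": ("12", "TSG", (), ()),
    "CHEK2": ("22", "TSG", (), ()),
}

DISRUPTING_CONSEQUENCES = frozenset({"frameshift", "stop_gained", "splice_site"})
KNOWN_CONSEQUENCES = frozenset(
    {"missense", "synonymous", "stop_gained", "frameshift", "splice_site",
     "inframe_indel", "noncoding"}
)


def default_driver_catalog(gene_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Driver catalog as a DataFrame (gene, chrom, role, known_changes, known_positions).

    If a simulated ``gene_table`` (with chrom/start/end columns) is given,
    driver genes are mapped onto matching toy gene intervals so that the
    catalog can also be used for locus-based lookups (LOH assessment).
    """
    rows = []
    for gene, (chrom, role, changes, positions) in _DRIVER_GENES.items():
        rows.append(
            {
                "gene": gene,
                "chrom": chrom,
                "start": 0,
                "end": 0,
                "role": role,
                "known_changes": ",".join(changes),
                "known_positions": ",".join(str(p) for p in positions),
            }
        )
    cat = pd.DataFrame(rows)
    if gene_table is not None:
        coords = gene_table.set_index("gene")[["chrom", "start", "end"]]
        keep = cat["gene"].isin(coords.index)
        cat = cat.loc[keep].reset_index(drop=True)
        cat["chrom"] = cat["gene"].map(coords["chrom"])
        cat["start"] = cat["gene"].map(coords["start"])
        cat["end"] = cat["gene"].map(coords["end"])
    return cat


def parse_positions(cell: str) -> set[int]:
    if not cell or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    return {int(x) for x in str(cell).split(",") if x}


def parse_changes(cell: str) -> set[str]:
    if not cell or (isinstance(cell, float) and np.isnan(cell)):
        return set()
    return {x for x in str(cell).split(",") if x}
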