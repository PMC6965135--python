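"""Trinucleotide substitution contexts in the pyrimidine-centric 96-class frame.

Single-base substitutions are classified by the substituted pyrimidine
(C or T), its alternate allele, and the two flanking bases, giving the
96 categories used throughout mutational-signature analysis.  Categories
are ordered substitution-major, flanks alphabetical:
``A[C>A]A, A[C>A]C, ..., T[T>G]T``.
"""

from __future__ import annotations

import numpy as np

PYRIMIDINES = "CT"
BASES = "ACGT"
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def context_labels() -> list[str]:
    """The 96 context labels in canonical order."""
    labels = []
    for sub in SUBSTITUTIONS:
        ref, alt = sub[0], sub[2]
        for f5 in BASES:
            for f3 in BASES:
                labels.append(f"{f5}[{ref}>{alt}]{f3}")
    return labels


CONTEXT_LABELS = context_labels()
_LABEL_INDEX = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}
N_CONTEXTS = 96


def category_index(sub: str, f5: str, f3: str) -> int:
    """Index of category ``f5[sub]f3`` (pyrimidine frame assumed)."""
    return _LABEL_INDEX[f"{f5}[{sub}]{f3}"]


def category_of(trinucleotide: str, alt: str) -> int:
    """Classify a substitution given its genome-frame trinucleotide context.

    ``trinucleotide`` is the reference 3-mer centred on the mutated base;
    purine-reference substitutions are reverse-complemented into the
    pyrimidine frame.  Returns the 0..95 category index.
    """
    if len(trinucleotide) != 3:
        raise ValueError(f"need a 3-mer, got {trinucleotide!r}")
    ref = trinucleotide[1]
    if ref not in PYRIMIDINES:
        trinucleotide = revcomp(trinucleotide)
        alt = revcomp(alt)
        ref = trinucleotide[1]
    return _LABEL_INDEX[f"{trinucleotide[0]}[{ref}>{alt}]{trinucleotide[2]}"]


def category_parts(index: int) -> tuple[str, str, str, str]:
    """Decompose a category index into (ref, alt, f5, f3), pyrimidine frame."""
    sub = SUBSTITUTIONS[index // 16]
    f5 = BASES[(index % 16) // 4]
    f3 = BASES[index % 4]
    return sub[0], sub[2], f5, f3


def triple_index(f5: str, center: str, f3: str) -> int:
    """Index 0..31 of a pyrimidine-frame trinucleotide (center in {C, T})."""
    return PYRIMIDINES.index(center) * 16 + BASES.index(f5) * 4 + BASES.index(f3)


def pyrimidine_triples(seq: str) -> np.ndarray:
    """Per-position pyrimidine-frame triple index for a sequence.

    Returns an int array of length ``len(seq)``; positions 0 and -1 (no
    flank) and positions with non-ACGT bases are -1.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(arr.shape, -1, dtype=np.int64)
    for i, b in enumerate(BASES):
        code[arr == ord(b)] = i
    out = np.full(len(seq), -1, dtype=np.int64)
    if len(seq) < 3:
        return out
    c5, cc, c3 = code[:-2], code[1:-1], code[2:]
    valid = (c5 >= 0) & (cc >= 0) & (c3 >= 0)
    # pyrimidine-centred: use as-is; purine-centred: reverse complement
    pyr = valid & ((cc == 1) | (cc == 3))  # C or T
    pur = valid & ((cc == 0) | (cc == 2))  # A or G
    res = np.full(cc.shape, -1, dtype=np.int64)
    res[pyr] = np.where(cc[pyr] == 1, 0, 1) * 16 + c5[pyr] * 4 + c3[pyr]
    # revcomp: center A->T, G->C ; flanks swap and complement (comp = 3 - code)
    res[pur] = np.where(cc[pur] == 2, 0, 1) * 16 + (3 - c3[pur]) * 4 + (3 - c5[pur])
    out[1:-1] = res
    return out


def category_from_triple(triple: int, genome_ref: str, genome_alt: str) -> int:
    """Category index for a substitution at a site with known triple index."""
    center = PYRIMIDINES[triple // 16]
    f5 = BASES[(triple % 16) // 4]
    f3 = BASES[triple % 4]
    alt = genome_alt if genome_ref in PYRIMIDINES else revcomp(genome_alt)
    return _LABEL_INDEX[f"{f5}[{center}>{alt}]{f3}"]
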