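"""Codon-level helpers shared by the simulator and the dN/dS model."""

from __future__ import annotations

from functools import lru_cache

from Bio.Data import CodonTable

from .contexts import BASES


@lru_cache(maxsize=1)
def codon_to_aa() -> dict[str, str]:
    """Standard-code codon -> one-letter amino acid ('*' for stop)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@lru_cache(maxsize=1)
def sense_codons() -> tuple[str, ...]:
    """The 61 codons that do not encode a stop."""
    return tuple(sorted(c for c, aa in codon_to_aa().items() if aa != "*"))


def substitute(codon: str, within: int, alt: str) -> str:
    return codon[:within] + alt + codon[within + 1 :]


def classify_substitution(codon: str, within: int, alt: str) -> tuple[str, str, str]:
    """(consequence, aa_ref, aa_alt) for a single-base codon change.

    Consequence vocabulary: synonymous | missense | stop_gained.
    """
    aa = codon_to_aa()
    aa_ref = aa[codon]
    aa_alt = aa[substitute(codon, within, alt)]
    if aa_alt == aa_ref:
        return "synonymous", aa_ref, aa_alt
    if aa_alt == "*":
        return "stop_gained", aa_ref, aa_alt
    return "missense", aa_ref, aa_alt


def alt_bases(ref: str) -> tuple[str, ...]:
    return tuple(b for b in BASES if b != ref)
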