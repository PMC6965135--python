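"""Trinucleotide-context-adjusted dN/dS per mutation compartment.

The opportunity model enumerates every possible single-base substitution
over the supplied in-frame coding sequences, labelling each as
synonymous or non-synonymous and by its 96-class pyrimidine-frame
context (sites without a flanking base form a separate edge class).
Counts of observed synonymous mutations estimate per-context mutation
rates; dN/dS is the maximum-likelihood ratio omega in the Poisson model

    s_c ~ Poisson(lambda_c * L_S,c),   n_c ~ Poisson(omega * lambda_c * L_N,c)

with the per-context rates lambda_c profiled out.  The 95% confidence
interval is the chi-square(1) likelihood-ratio profile on omega.  This
adjusts the ratio for context-biased mutational processes (e.g. the
C>T-at-NpCpG excess typical of hypermutated tumours) that bias the naive
count ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from .coding import alt_bases, codon_to_aa, substitute
from .contexts import N_CONTEXTS, category_from_triple, pyrimidine_triples

log = logging.getLogger(__name__)

EDGE_CLASS = N_CONTEXTS  # sites lacking a flanking base
N_CLASSES = N_CONTEXTS + 1

COMPARTMENTS = ("ubiquitous", "shared", "private")


@dataclass
class CodingModel:
    """Opportunity matrix and per-opportunity arrays for a coding space."""

    L: np.ndarray  # (97, 2): [context class, syn(0)/nonsyn(1)] counts
    op_class: np.ndarray  # per-opportunity context class
    op_syn: np.ndarray  # per-opportunity synonymous flag
    n_sequences: int
    n_excluded: int

    @property
    def n_opportunities(self) -> int:
        return int(self.L.sum())


def build_opportunity(
    coding_sequences: dict[str, str], exclude_internal_stops: bool = True
) -> CodingModel:
    """Enumerate all single-base substitutions over in-frame sequences.

    Every coding site contributes exactly 3 opportunities, so totals are
    conserved (3 x total length).  Sequences containing an internal stop
    codon are excluded (logged) when ``exclude_internal_stops`` is set.
    """
    if not coding_sequences:
        raise ValueError("no coding sequences supplied")
    aa_of = codon_to_aa()
    syn_table: dict[tuple[str, int, str], bool] = {}
    for codon in aa_of:
        for within in range(3):
            for alt in alt_bases(codon[within]):
                syn_table[(codon, within, alt)] = (
                    aa_of[substitute(codon, within, alt)] == aa_of[codon]
                )

    classes: list[np.ndarray] = []
    syns: list[np.ndarray] = []
    n_excluded = 0
    n_used = 0
    for name, seq in coding_sequences.items():
        seq = seq.upper()
        if not seq or len(seq) % 3:
            raise ValueError(f"sequence {name!r} length must be a positive multiple of 3")
        if any(b not in "ACGT" for b in set(seq)):
            raise ValueError(f"sequence {name!r} contains non-ACGT characters")
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if exclude_internal_stops and any(aa_of[c] == "*" for c in codons[:-1]):
            n_excluded += 1
            log.info("excluding %r: internal stop codon", name)
            continue
        n_used += 1
        triples = pyrimidine_triples(seq)
        cls = np.empty(len(seq) * 3, dtype=np.int32)
        syn = np.empty(len(seq) * 3, dtype=bool)
        k = 0
        for i, ref in enumerate(seq):
            codon = codons[i // 3]
            within = i % 3
            for alt in alt_bases(ref):
                syn[k] = syn_table[(codon, within, alt)]
                cls[k] = (
                    category_from_triple(int(triples[i]), ref, alt)
                    if triples[i] >= 0
                    else EDGE_CLASS
                )
                k += 1
        classes.append(cls)
        syns.append(syn)
    if not classes:
        raise ValueError("all sequences excluded (internal stop codons)")
    op_class = np.concatenate(classes)
    op_syn = np.concatenate(syns)
    L = np.zeros((N_CLASSES, 2))
    np.add.at(L, (op_class, (~op_syn).astype(int)), 1.0)
    return CodingModel(
        L=L, op_class=op_class, op_syn=op_syn, n_sequences=n_used, n_excluded=n_excluded
    )


def sample_mutations(
    model: CodingModel,
    n: int,
    class_rates: np.ndarray | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw mutations from the opportunity space (selectively neutral).

    ``class_rates`` (length 97) weights opportunities by context class,
    modelling a context-biased but neutral mutation process.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.ones(len(model.op_class))
    if class_rates is not None:
        w = np.asarray(class_rates, dtype=float)[model.op_class]
    idx = rng.choice(len(w), size=n, replace=True, p=w / w.sum())
    return pd.DataFrame(
        {
            "context_class": model.op_class[idx],
            "is_synonymous": model.op_syn[idx],
        }
    )


def naive_ratio(n_syn: int, n_nonsyn: int, L: np.ndarray) -> float:
    """Unadjusted (N / L_N) / (S / L_S) count ratio."""
    L_S, L_N = L[:, 0].sum(), L[:, 1].sum()
    if n_syn == 0:
        return float("nan")
    return (n_nonsyn / L_N) / (n_syn / L_S)


def expected_neutral_naive_ratio(class_rates: np.ndarray, L: np.ndarray) -> float:
    """Closed-form expectation of the naive ratio under a neutral process
    with per-class rates; deviates from 1 whenever rates are non-uniform."""
    r = np.asarray(class_rates, dtype=float)
    e_n = (r * L[:, 1]).sum() / L[:, 1].sum()
    e_s = (r * L[:, 0]).sum() / L[:, 0].sum()
    return float(e_n / e_s)


def _profile_loglik(omega: float, s: np.ndarray, n: np.ndarray, L: np.ndarray) -> float:
    tot = s + n
    mask = tot > 0
    denom = L[mask, 0] + omega * L[mask, 1]
    lam = tot[mask] / denom
    with np.errstate(divide="ignore"):
        ll = tot[mask] * np.log(lam) + n[mask] * np.log(omega) - tot[mask]
    return float(np.where(np.isfinite(ll), ll, -np.inf).sum())


def _score(omega: float, s: np.ndarray, n: np.ndarray, L: np.ndarray) -> float:
    tot = s + n
    mask = tot > 0
    denom = L[mask, 0] + omega * L[mask, 1]
    return float(n.sum() / omega - (tot[mask] * L[mask, 1] / denom).sum())


def fit_ratio(
    s_counts: np.ndarray, n_counts: np.ndarray, L: np.ndarray, conf: float = 0.95
) -> tuple[float, float, float]:
    """(omega, ci_low, ci_high) by profile likelihood; NaNs if S == 0."""
    s = np.asarray(s_counts, dtype=float)
    n = np.asarray(n_counts, dtype=float)
    S, N = s.sum(), n.sum()
    if S == 0:
        return float("nan"), float("nan"), float("nan")
    crit = chi2.ppf(conf, df=1)
    if N == 0:
        # likelihood maximised at 0; only an upper bound exists
        ll0 = _profile_loglik_zero(s, L)
        hi = 1.0
        while 2 * (ll0 - _profile_loglik(hi, s, n, L)) < crit:
            hi *= 2
            if hi > 1e6:
                break
        upper = brentq(lambda w: 2 * (ll0 - _profile_loglik(w, s, n, L)) - crit, 1e-12, hi)
        return 0.0, 0.0, float(upper)
    hi = 4.0
    while _score(hi, s, n, L) > 0:
        hi *= 2
        if hi > 1e9:
            break
    omega = float(brentq(lambda w: _score(w, s, n, L), 1e-12, hi))
    ll_hat = _profile_loglik(omega, s, n, L)

    def g(w: float) -> float:
        return 2 * (ll_hat - _profile_loglik(w, s, n, L)) - crit

    lo_bracket = omega
    step = omega / 2
    while g(step) < 0 and step > 1e-12:
        lo_bracket, step = step, step / 4
    ci_low = float(brentq(g, step, lo_bracket)) if g(step) >= 0 else 0.0
    hi_bracket = omega * 2
    while g(hi_bracket) < 0:
        hi_bracket *= 2
        if hi_bracket > 1e9:
            break
    ci_high = float(brentq(g, omega, hi_bracket)) if g(hi_bracket) >= 0 else float("inf")
    return omega, ci_low, ci_high


def _profile_loglik_zero(s: np.ndarray, L: np.ndarray) -> float:
    mask = s > 0
    lam = s[mask] / L[mask, 0]
    return float((s[mask] * np.log(lam) - s[mask]).sum())


@dataclass
class DndsEstimate:
    compartment: str
    n_syn: int
    n_nonsyn: int
    ratio: float
    ci_low: float
    ci_high: float
    naive: float
    note: str = ""


def dnds(mutations: pd.DataFrame, model: CodingModel, conf: float = 0.95) -> pd.DataFrame:
    """Per-compartment context-adjusted dN/dS with profile-likelihood CIs.

    ``mutations`` needs columns context_class, is_synonymous and (unless a
    single unnamed compartment is intended) compartment.
    """
    if "compartment" not in mutations.columns:
        mutations = mutations.assign(compartment="all")
    rows = []
    for comp, grp in mutations.groupby("compartment"):
        s = np.zeros(N_CLASSES)
        n = np.zeros(N_CLASSES)
        cls = grp["context_class"].to_numpy()
        syn = grp["is_synonymous"].to_numpy(dtype=bool)
        np.add.at(s, cls[syn], 1.0)
        np.add.at(n, cls[~syn], 1.0)
        note = ""
        if s.sum() == 0:
            note = "undefined: no synonymous mutations"
            ratio = lo = hi = float("nan")
        else:
            ratio, lo, hi = fit_ratio(s, n, model.L, conf)
        rows.append(
            DndsEstimate(
                compartment=str(comp),
                n_syn=int(s.sum()),
                n_nonsyn=int(n.sum()),
                ratio=ratio,
                ci_low=lo,
                ci_high=hi,
                naive=naive_ratio(int(s.sum()), int(n.sum()), model.L),
                note=note,
            ).__dict__
        )
    out = pd.DataFrame(rows)
    order = {c: i for i, c in enumerate(COMPARTMENTS)}
    return out.sort_values(
        "compartment", key=lambda c: c.map(lambda x: order.get(x, 99))
    ).reset_index(drop=True)
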