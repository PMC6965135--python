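"""96-context mutational spectra and catalog refitting.

Spectra count single-base substitutions by trinucleotide context in the
pyrimidine frame.  Refitting finds nonnegative signature weights
minimising the Euclidean distance between the normalised spectrum and
the catalog reconstruction (nonnegative least squares); a reporting
layer masks signatures contributing less than 5% in every analysed
mutation group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .contexts import CONTEXT_LABELS, N_CONTEXTS, category_of

log = logging.getLogger(__name__)


@dataclass
class ExposureVector:
    weights: pd.Series  # signature_id -> weight, >= 0, sum <= 1
    residual: float  # L2 reconstruction error

    def reported(self, report_min: float = 0.05) -> pd.Series:
        return self.weights[self.weights >= report_min]


def count_contexts(
    sites: pd.DataFrame, reference: dict[str, str], normalize: bool = False
) -> pd.Series:
    """Tabulate SNVs into the 96 substitution-context categories.

    ``sites`` needs chrom/pos/ref/alt/kind columns; indels are excluded.
    Loci lacking a flanking base (contig edges) are excluded and logged.
    Counts conserve the number of usable SNVs.
    """
    counts = np.zeros(N_CONTEXTS, dtype=float)
    snvs = sites[sites["kind"] == "snv"] if "kind" in sites.columns else sites
    edge_skipped = 0
    for row in snvs.itertuples():
        seq = reference[str(row.chrom)]
        pos = int(row.pos)
        if pos <= 1 or pos >= len(seq):
            edge_skipped += 1
            continue
        tri = seq[pos - 2 : pos + 1]
        counts[category_of(tri, row.alt)] += 1
    if edge_skipped:
        log.info("excluded %d SNVs at contig edges (no flanking base)", edge_skipped)
    spectrum = pd.Series(counts, index=CONTEXT_LABELS, name="count")
    if normalize and spectrum.sum() > 0:
        spectrum = spectrum / spectrum.sum()
    return spectrum


def spectra_by_group(
    sites: pd.DataFrame, reference: dict[str, str], groups: pd.Series
) -> pd.DataFrame:
    """One spectrum column per group label (e.g. ubiquitous/heterogeneous)."""
    cols = {}
    for label in sorted(groups.dropna().unique()):
        members = groups.index[groups == label]
        cols[label] = count_contexts(sites.loc[sites.index.intersection(members)], reference)
    return pd.DataFrame(cols, index=CONTEXT_LABELS)


def fit_signatures(
    spectrum: pd.Series | np.ndarray,
    catalog: pd.DataFrame,
    cutoff: float = 0.0,
) -> ExposureVector:
    """Nonnegative least-squares refit of a spectrum against a catalog.

    The spectrum is normalised to frequencies; weights below ``cutoff``
    are zeroed and the remainder rescaled to preserve the fitted total.
    """
    values = np.asarray(
        spectrum.reindex(CONTEXT_LABELS).to_numpy()
        if isinstance(spectrum, pd.Series)
        else spectrum,
        dtype=float,
    )
    if values.shape != (N_CONTEXTS,):
        raise ValueError(f"spectrum must have {N_CONTEXTS} entries")
    total = values.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    target = values / total
    a = catalog.loc[CONTEXT_LABELS].to_numpy(dtype=float)
    w, _ = nnls(a, target)
    if cutoff > 0:
        pre = w.sum()
        w[w < cutoff] = 0.0
        if w.sum() > 0:
            w *= pre / w.sum()
    residual = float(np.linalg.norm(a @ w - target))
    return ExposureVector(
        weights=pd.Series(w, index=catalog.columns, name="weight"), residual=residual
    )


def fit_groups(
    spectra: pd.DataFrame, catalog: pd.DataFrame, cutoff: float = 0.0
) -> dict[str, ExposureVector]:
    return {
        group: fit_signatures(spectra[group], catalog, cutoff)
        for group in spectra.columns
        if spectra[group].sum() > 0
    }


def report_exposures(
    exposures: dict[str, ExposureVector], report_min: float = 0.05
) -> pd.DataFrame:
    """Exposure table keeping only signatures reaching ``report_min``
    (default 5% of mutations) in at least one group."""
    table = pd.DataFrame({g: ev.weights for g, ev in exposures.items()})
    keep = (table >= report_min).any(axis=1)
    return table.loc[keep]
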