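"""Ground-truthed multi-region tumour simulator.

Generates the statistical regime that multi-region exome analysis of
hypermutated (MSI-like) tumours assumes: a rooted clone tree with a long
trunk, regional clone mixtures with spatial locality, trinucleotide-context
substitutions drawn from signature mixtures that may differ between trunk
and branches, a 20-34% indel fraction, per-region purity, ~200x depth,
allele-specific copy-number events (early/late gains, allele losses that
delete previously acquired mutations) and a panel of normal samples with
recurrent artifact sites.

The observation model for a mutation carried on ``m`` chromosome copies by
a clone with cancer-cell fraction CCF in a region of purity ``p`` and bulk
total copy number ``CN_t`` is

    E[VAF] = p * m * CCF / (p * CN_t + 2 * (1 - p)),

with read depth Poisson(mean_depth) and alt reads Binomial(depth, E[VAF])
(plus an optional per-base error rate).  Everything is deterministic given
the config seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .catalogs import synthetic_signature_catalog
from .coding import alt_bases, classify_substitution, sense_codons
from .contexts import (
    BASES,
    CONTEXT_LABELS,
    PYRIMIDINES,
    category_parts,
    revcomp,
    triple_index,
    pyrimidine_triples,
)

_AUTOSOMES = [str(i) for i in range(1, 23)]
_RANDOM_TREE_RE = re.compile(r"random\((\d+)\s*,\s*(\d+)\s*-\s*(\d+)\)")


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study conditions for one simulated tumour.

    ``clone_tree_spec`` is a list of ``(parent_id, n_mutations)`` pairs,
    entry ``i`` describing clone ``i`` (clone 0 is the truncal root with
    parent ``None``), or a string ``"random(n_clones, lo-hi)"``.
    ``cna_events`` entries are dicts with keys ``clone, chrom, major,
    minor, timing`` (optionally ``start``/``end``); ``loss_events`` are
    dicts ``{clone, chrom[, start, end]}`` deleting the minor allele after
    the clone's mutations were acquired.
    """

    seed: int = 0
    n_regions: int = 7
    n_lymph_nodes: int = 0
    clone_tree_spec: Any = field(
        default_factory=lambda: [
            (None, 700),
            (0, 320),
            (0, 280),
            (1, 220),
            (1, 200),
            (2, 174),
        ]
    )
    truncal_mutations: int | None = None
    indel_fraction: float = 0.27
    signature_mix_trunk: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.30, "S6": 0.45, "S15": 0.25}
    )
    signature_mix_branch: dict[str, float] = field(
        default_factory=lambda: {"S1": 0.10, "S6": 0.50, "S15": 0.40}
    )
    purity_range: tuple[float, float] = (0.2, 0.9)
    mean_depth: int = 200
    normal_depth: int = 100
    genome: list[tuple[str, int]] | None = None  # None -> 22 autosomes x 30 kb
    chrom_length: int = 30_000
    cna_events: list[dict] = field(
        default_factory=lambda: [
            {"clone": 0, "chrom": "8", "major": 2, "minor": 1, "timing": "before_mutations"},
            {"clone": 0, "chrom": "20", "major": 2, "minor": 1, "timing": "after_mutations"},
            {"clone": 0, "chrom": "17", "major": 1, "minor": 0, "timing": "before_mutations"},
        ]
    )
    loss_events: list[dict] = field(
        default_factory=lambda: [{"clone": 1, "chrom": "18"}]
    )
    driver_events: list[dict] = field(
        default_factory=lambda: [
            {"clone": 0, "gene": "ARID1A", "protein_change": "M274fs", "consequence": "frameshift", "kind": "indel"},
            {"clone": 0, "gene": "TP53", "protein_change": "R175H", "consequence": "missense", "kind": "snv"},
            {"clone": 1, "gene": "KRAS", "protein_change": "G13D", "consequence": "missense", "kind": "snv"},
            {"clone": 2, "gene": "KRAS", "protein_change": "G13D", "consequence": "missense", "kind": "snv"},
            {"clone": 2, "gene": "B2M", "protein_change": "L15fs", "consequence": "frameshift", "kind": "indel"},
        ]
    )
    panel_size: int = 14
    artifact_rate: float = 0.02
    artifact_prevalence: float = 0.30
    error_rate: float = 0.001
    normal_contamination: float = 0.0
    noiseless: bool = False
    dominance: float = 0.5
    min_present_ccf: float = 0.15
    min_clone_separation: float = 0.10
    gene_length: int = 1500
    gene_gap: int = 300
    signature_catalog: pd.DataFrame | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "clone_tree_spec" in d and isinstance(d["clone_tree_spec"], list):
            d["clone_tree_spec"] = [tuple(x) for x in d["clone_tree_spec"]]
        if "purity_range" in d:
            d["purity_range"] = tuple(d["purity_range"])
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**d)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


def _validate_mix(mix: dict[str, float], catalog: pd.DataFrame, name: str) -> None:
    unknown = set(mix) - set(catalog.columns)
    if unknown:
        raise ValueError(f"{name} references unknown signature ids: {sorted(unknown)}")
    if any(w < 0 for w in mix.values()):
        raise ValueError(f"{name} has negative weights")
    if abs(sum(mix.values()) - 1.0) > 1e-8:
        raise ValueError(f"{name} weights must sum to 1")


def parse_clone_tree(spec: Any, rng: np.random.Generator) -> tuple[list[int | None], list[int]]:
    """Return (parents, n_mutations) lists; validates a single rooted tree."""
    if isinstance(spec, str):
        m = _RANDOM_TREE_RE.fullmatch(spec.strip())
        if not m:
            raise ValueError(f"cannot parse clone_tree_spec {spec!r}")
        k, lo, hi = (int(g) for g in m.groups())
        parents: list[int | None] = [None] + [int(rng.integers(0, i)) for i in range(1, k)]
        counts = [int(rng.integers(lo, hi + 1)) for _ in range(k)]
        return parents, counts
    parents = [p for p, _ in spec]
    counts = [int(n) for _, n in spec]
    roots = [i for i, p in enumerate(parents) if p is None]
    if roots != [0]:
        raise ValueError("clone_tree_spec must have exactly one root at index 0")
    for i, p in enumerate(parents[1:], start=1):
        if not isinstance(p, (int, np.integer)) or not 0 <= p < i:
            raise ValueError(f"clone {i} has invalid parent {p!r} (must precede it)")
    return parents, counts


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


@dataclass
class ToyGenome:
    chroms: dict[str, str]
    gene_table: pd.DataFrame  # gene, chrom, start, end (1-based inclusive)

    def sequence(self, chrom: str) -> str:
        return self.chroms[chrom]

    def coding_sequences(self) -> dict[str, str]:
        out = {}
        for row in self.gene_table.itertuples():
            out[row.gene] = self.chroms[row.chrom][row.start - 1 : row.end]
        return out

    def gene_at(self, chrom: str, pos: int) -> tuple[str, int] | None:
        """(gene, 0-based offset into the CDS) or None if intergenic."""
        sub = self._index().get(chrom)
        if sub is None:
            return None
        starts, ends, names = sub
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos <= ends[i]:
            return names[i], pos - starts[i]
        return None

    def _index(self):
        if not hasattr(self, "_idx"):
            idx = {}
            for chrom, grp in self.gene_table.groupby("chrom"):
                grp = grp.sort_values("start")
                idx[chrom] = (
                    grp["start"].to_numpy(),
                    grp["end"].to_numpy(),
                    grp["gene"].to_list(),
                )
            self._idx = idx
        return self._idx


_DRIVER_CHROM_GENES: dict[str, list[str]] = {}


def _driver_genes_by_chrom() -> dict[str, list[str]]:
    if not _DRIVER_CHROM_GENES:
        from .catalogs import _DRIVER_GENES

        for gene, (chrom, *_rest) in _DRIVER_GENES.items():
            _DRIVER_CHROM_GENES.setdefault(chrom, []).append(gene)
    return _DRIVER_CHROM_GENES


def build_genome(config: SimulationConfig, rng: np.random.Generator) -> ToyGenome:
    """Random toy genome with stop-free coding tiles named after driver genes
    where applicable (remaining tiles get generic names)."""
    spec = config.genome or [(c, config.chrom_length) for c in _AUTOSOMES]
    codons = np.array(sense_codons())
    base_arr = np.array(list(BASES))
    chroms: dict[str, str] = {}
    rows = []
    by_chrom = _driver_genes_by_chrom()
    for entry in spec:
        chrom, length = entry[0], int(entry[1])
        seq = base_arr[rng.integers(0, 4, size=length)]
        gene_slots = []
        start = 101
        glen = config.gene_length - config.gene_length % 3
        while start + glen - 1 <= length - 100:
            gene_slots.append(start)
            start += glen + config.gene_gap
        names = list(by_chrom.get(str(chrom), []))
        for i, gstart in enumerate(gene_slots):
            name = names[i] if i < len(names) else f"G{chrom}_{i + 1}"
            cds = np.array(
                list("".join(codons[rng.integers(0, len(codons), size=glen // 3)]))
            )
            seq[gstart - 1 : gstart - 1 + glen] = cds
            rows.append({"gene": name, "chrom": str(chrom), "start": gstart, "end": gstart + glen - 1})
        chroms[str(chrom)] = "".join(seq)
    return ToyGenome(chroms=chroms, gene_table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class CNAEvent:
    clone: int
    chrom: str
    start: int
    end: int
    major: int
    minor: int
    timing: str  # before_mutations | after_mutations
    kind: str  # gain | loss | cna


@dataclass
class GroundTruth:
    """Simulator truth: tree, mixtures, assignments, multiplicities, labels."""

    parent: dict[int, int | None]
    clone_fractions: pd.DataFrame  # region x clone own fractions (sum = purity share 1)
    clone_ccf: pd.DataFrame  # region x clone subtree CCF
    purity: pd.Series  # region -> purity
    mutation_clone: pd.Series  # mut_id -> clone
    mutation_multiplicity: pd.DataFrame  # mut x region integer copies
    expected_vaf: pd.DataFrame  # mut x region
    events: list[CNAEvent]
    gain_timing: dict[int, str]  # event index -> early | late
    lost_mutations: set[tuple[str, str]]
    region_ids: list[str]
    artifact_sites: list[str] = field(default_factory=list)

    def subtree(self, clone: int) -> set[int]:
        kids: dict[int, list[int]] = {}
        for c, p in self.parent.items():
            if p is not None:
                kids.setdefault(p, []).append(c)
        out, stack = set(), [clone]
        while stack:
            c = stack.pop()
            out.add(c)
            stack.extend(kids.get(c, []))
        return out

    def is_ancestor(self, a: int, b: int) -> bool:
        """True if ``a`` is a strict ancestor of ``b``."""
        p = self.parent.get(b)
        while p is not None:
            if p == a:
                return True
            p = self.parent.get(p)
        return False

    def true_presence(self) -> pd.DataFrame:
        """Noiseless per-region presence: carried (CCF>0) and not deleted."""
        return self.expected_vaf > 0

    def categories(self, ignore_losses: bool = False) -> pd.Series:
        pres = self.clone_ccf.loc[
            self.region_ids, :
        ].T.gt(0).loc[self.mutation_clone.to_numpy()]
        pres.index = self.mutation_clone.index
        if not ignore_losses:
            pres &= self.mutation_multiplicity > 0
        n = pres.sum(axis=1)
        cat = pd.Series("shared", index=pres.index)
        cat[n == len(self.region_ids)] = "ubiquitous"
        cat[n == 1] = "private"
        cat[n == 0] = "absent"
        return cat


# ---------------------------------------------------------------------------
# Clone mixtures with spatial locality
# ---------------------------------------------------------------------------


def _subtree_matrix(parents: list[int | None]) -> np.ndarray:
    """S[k, d] = 1 if clone d is in subtree(k)."""
    k = len(parents)
    anc = np.zeros((k, k), dtype=bool)
    for d in range(k):
        c: int | None = d
        while c is not None:
            anc[c, d] = True
            c = parents[c]
    return anc


def _draw_mixtures(
    config: SimulationConfig, parents: list[int | None], rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Own fractions and subtree CCFs per region; enforces locality,
    a presence floor, and a minimum pairwise clone-profile separation."""
    n_clones = len(parents)
    region_ids = [f"R{i + 1}" for i in range(config.n_regions)] + [
        f"LN{i + 1}" for i in range(config.n_lymph_nodes)
    ]
    n_total = len(region_ids)
    S = _subtree_matrix(parents)
    non_root = list(range(1, n_clones))
    floor = max(config.min_present_ccf, 0.05)

    for _ in range(400):
        own = np.zeros((n_total, n_clones))
        order = rng.permutation(non_root) if non_root else np.array([], dtype=int)
        region_perm = rng.permutation(config.n_regions)
        homes: dict[int, int] = {
            int(c): int(region_perm[i % config.n_regions]) for i, c in enumerate(order)
        }
        ok = True
        for r in range(config.n_regions):
            residents = {0} | {c for c, h in homes.items() if h == r}
            for c in list(residents - {0}):
                p = parents[c]
                if p not in (None, 0) and rng.random() < 0.5:
                    residents.add(p)
            residents = sorted(residents)
            for _try in range(500):
                w = rng.dirichlet(np.full(len(residents), 2.0))
                if w.min() >= floor:
                    break
            else:
                ok = False
                break
            own[r, residents] = w
        if not ok:
            continue
        for j in range(config.n_lymph_nodes):
            seed_clone = int(rng.choice(non_root)) if non_root else 0
            own[config.n_regions + j, seed_clone] = 1.0
        ccf = own @ S.T  # ccf[r, k] = sum of own fractions over subtree(k)
        present = ccf > 1e-12
        if not ((~present) | (ccf >= config.min_present_ccf - 1e-12)).all():
            continue
        if not present.any(axis=0).all():
            continue
        if config.min_clone_separation > 0 and n_clones > 1:
            sep = np.abs(ccf[:, :, None] - ccf[:, None, :]).max(axis=0)
            np.fill_diagonal(sep, np.inf)
            if sep.min() < config.min_clone_separation:
                continue
        return own, ccf, region_ids
    raise RuntimeError(
        "could not draw region clone mixtures satisfying the presence floor "
        "and separation constraints; relax min_present_ccf/min_clone_separation"
    )


# ---------------------------------------------------------------------------
# Context-aware mutation placement
# ---------------------------------------------------------------------------


def sample_contexts(
    signature_mix: dict[str, float],
    catalog: pd.DataFrame,
    n: int,
    seed: int | np.random.Generator = 0,
) -> list[str]:
    """Draw ``n`` 96-context substitution labels from a signature mixture."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    _validate_mix(signature_mix, catalog, "signature_mix")
    if n == 0:
        return []
    weights = pd.Series(signature_mix, dtype=float)
    spectrum = catalog.loc[CONTEXT_LABELS, weights.index].to_numpy() @ weights.to_numpy()
    spectrum = spectrum / spectrum.sum()
    idx = rng.choice(96, size=n, p=spectrum)
    return [CONTEXT_LABELS[i] for i in idx]


class _PositionPool:
    """Deterministic draw-without-replacement of genome positions by
    pyrimidine-frame trinucleotide (32 classes), plus uniform draws."""

    def __init__(self, genome: ToyGenome, rng: np.random.Generator):
        self.rng = rng
        self.by_triple: dict[int, list[tuple[str, int]]] = {t: [] for t in range(32)}
        chrom_names = list(genome.chroms)
        for chrom in chrom_names:
            triples = pyrimidine_triples(genome.chroms[chrom])
            for t in range(32):
                pos = np.flatnonzero(triples == t) + 1  # 1-based
                self.by_triple[t].extend((chrom, int(p)) for p in pos)
        for t in range(32):
            order = rng.permutation(len(self.by_triple[t]))
            self.by_triple[t] = [self.by_triple[t][i] for i in order]
        self.cursor = {t: 0 for t in range(32)}
        self.used: set[tuple[str, int]] = set()
        self.genome = genome

    def take_for_category(self, cat_idx: int) -> tuple[str, int]:
        ref, _alt, f5, f3 = category_parts(cat_idx)
        t = triple_index(f5, ref, f3)
        pool = self.by_triple[t]
        while self.cursor[t] < len(pool):
            site = pool[self.cursor[t]]
            self.cursor[t] += 1
            if site not in self.used:
                self.used.add(site)
                return site
        raise RuntimeError(f"exhausted genome positions for context class {t}")

    def take_uniform(self) -> tuple[str, int]:
        chroms = list(self.genome.chroms)
        for _ in range(10_000):
            chrom = chroms[int(self.rng.integers(0, len(chroms)))]
            pos = int(self.rng.integers(2, len(self.genome.chroms[chrom])))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("could not find an unused genome position")

    def take_in_interval(self, chrom: str, start: int, end: int) -> tuple[str, int]:
        for _ in range(10_000):
            pos = int(self.rng.integers(start, end + 1))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("could not find an unused position in interval")


def _annotate_snv(genome: ToyGenome, chrom: str, pos: int, ref: str, alt: str) -> dict:
    hit = genome.gene_at(chrom, pos)
    if hit is None:
        return {"gene": "", "consequence": "noncoding", "protein_change": ""}
    gene, offset = hit
    row = genome.gene_table.set_index("gene").loc[gene]
    seq = genome.chroms[chrom]
    ci, within = divmod(offset, 3)
    cstart = row["start"] - 1 + 3 * ci
    codon = seq[cstart : cstart + 3]
    consequence, aa_ref, aa_alt = classify_substitution(codon, within, alt)
    return {
        "gene": gene,
        "consequence": consequence,
        "protein_change": f"{aa_ref}{ci + 1}{aa_alt}",
    }


# ---------------------------------------------------------------------------
# Copy-number machinery
# ---------------------------------------------------------------------------


def _normalize_events(config: SimulationConfig, genome: ToyGenome, n_clones: int) -> list[CNAEvent]:
    events: list[CNAEvent] = []
    for ev in config.cna_events:
        chrom = str(ev["chrom"])
        if chrom not in genome.chroms:
            continue
        length = len(genome.chroms[chrom])
        e = CNAEvent(
            clone=int(ev["clone"]),
            chrom=chrom,
            start=int(ev.get("start", 1)),
            end=int(ev.get("end", length)),
            major=int(ev["major"]),
            minor=int(ev["minor"]),
            timing=str(ev.get("timing", "before_mutations")),
            kind="cna",
        )
        e.kind = "gain" if e.major + e.minor > 2 else ("loss" if e.minor == 0 else "cna")
        events.append(e)
    for ev in config.loss_events:
        chrom = str(ev["chrom"])
        if chrom not in genome.chroms:
            continue
        length = len(genome.chroms[chrom])
        events.append(
            CNAEvent(
                clone=int(ev["clone"]),
                chrom=chrom,
                start=int(ev.get("start", 1)),
                end=int(ev.get("end", length)),
                major=1,
                minor=0,
                timing="after_mutations",
                kind="loss",
            )
        )
    for e in events:
        if not 0 <= e.clone < n_clones:
            raise ValueError(f"event references unknown clone {e.clone}")
        if e.minor > e.major or e.major < 0 or e.minor < 0:
            raise ValueError(f"event {e} violates major >= minor >= 0")
        if e.timing not in ("before_mutations", "after_mutations"):
            raise ValueError(f"bad event timing {e.timing!r}")
    return events


def _events_in_order(events: list[CNAEvent], depth: dict[int, int]) -> list[int]:
    return sorted(range(len(events)), key=lambda i: (depth[events[i].clone], i))


def _clone_depths(parents: list[int | None]) -> dict[int, int]:
    depth = {}
    for c in range(len(parents)):
        d, p = 0, parents[c]
        while p is not None:
            d, p = d + 1, parents[p]
        depth[c] = d
    return depth


def _allele_state(
    events: list[CNAEvent], order: list[int], applicable: set[int], chrom: str, pos: int
) -> tuple[int, int]:
    """Apply a set of events (in lineage order) to the base (1,1) state."""
    major, minor = 1, 1
    for i in order:
        e = events[i]
        if i in applicable and e.chrom == chrom and e.start <= pos <= e.end:
            major, minor = e.major, e.minor
    return major, minor


# ---------------------------------------------------------------------------
# Main entry points
# ---------------------------------------------------------------------------


def simulate_tumour(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict[str, "SegmentProfile"], GroundTruth, ToyGenome]:
    """Simulate one multi-region tumour.

    Returns (variant table, per-region segment profiles, ground truth,
    toy genome).  The variant table has one row per candidate site with
    columns ``REGION_<id>_DEPTH/_ALT`` and ``NORMAL_DEPTH/_ALT``.
    """
    from .cna import SegmentProfile  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed)
    catalog = (
        config.signature_catalog
        if config.signature_catalog is not None
        else synthetic_signature_catalog()
    )
    _validate_mix(config.signature_mix_trunk, catalog, "signature_mix_trunk")
    _validate_mix(config.signature_mix_branch, catalog, "signature_mix_branch")
    if not (0 < config.purity_range[0] <= config.purity_range[1] <= 1):
        raise ValueError("purity_range must be within (0, 1]")
    if not 0 <= config.indel_fraction <= 1:
        raise ValueError("indel_fraction must be in [0, 1]")

    parents, counts = parse_clone_tree(config.clone_tree_spec, rng)
    if config.truncal_mutations is not None:
        counts = [config.truncal_mutations] + counts[1:]
    n_clones = len(parents)
    depth_of = _clone_depths(parents)

    genome = build_genome(config, rng)
    events = _normalize_events(config, genome, n_clones)
    ev_order = _events_in_order(events, depth_of)

    own, ccf, region_ids = _draw_mixtures(config, parents, rng)
    purity = rng.uniform(*config.purity_range, size=len(region_ids))

    truth_parent = {i: parents[i] for i in range(n_clones)}
    gt_stub = GroundTruth(
        parent=truth_parent,
        clone_fractions=pd.DataFrame(own, index=region_ids, columns=range(n_clones)),
        clone_ccf=pd.DataFrame(ccf, index=region_ids, columns=range(n_clones)),
        purity=pd.Series(purity, index=region_ids),
        mutation_clone=pd.Series(dtype=object),
        mutation_multiplicity=pd.DataFrame(),
        expected_vaf=pd.DataFrame(),
        events=events,
        gain_timing={},
        lost_mutations=set(),
        region_ids=region_ids,
    )

    # --- per-region dominant events and segment profiles -------------------
    dominant: dict[str, set[int]] = {}
    for r_i, rid in enumerate(region_ids):
        dom = {
            i
            for i, e in enumerate(events)
            if ccf[r_i, e.clone] > config.dominance
        }
        dominant[rid] = dom

    segments: dict[str, Any] = {}
    for r_i, rid in enumerate(region_ids):
        rows = []
        for chrom, seq in genome.chroms.items():
            length = len(seq)
            cuts = {1, length + 1}
            for i in dominant[rid]:
                e = events[i]
                if e.chrom == chrom:
                    cuts.update((e.start, e.end + 1))
            cuts = sorted(cuts)
            for a, b in zip(cuts[:-1], cuts[1:]):
                major, minor = _allele_state(events, ev_order, dominant[rid], chrom, a)
                rows.append(
                    {
                        "chrom": chrom,
                        "start": a,
                        "end": b - 1,
                        "cn_total": float(major + minor),
                        "cn_major": major,
                        "cn_minor": minor,
                    }
                )
        segments[rid] = SegmentProfile(
            region_id=rid, purity=float(purity[r_i]), segments=pd.DataFrame(rows)
        )

    # --- mutations ---------------------------------------------------------
    pool = _PositionPool(genome, rng)
    anc_matrix = _subtree_matrix(parents)  # anc_matrix[a, d]: a ancestor-or-self of d

    muts: list[dict] = []
    for clone in range(n_clones):
        mix = config.signature_mix_trunk if clone == 0 else config.signature_mix_branch
        n = counts[clone]
        n_indel = int(round(n * config.indel_fraction))
        n_snv = n - n_indel
        cat_labels = sample_contexts(mix, catalog, n_snv, rng)
        cat_idx = [CONTEXT_LABELS.index(lab) for lab in cat_labels]
        for ci in cat_idx:
            chrom, pos = pool.take_for_category(ci)
            ref = genome.chroms[chrom][pos - 1]
            _r, alt_p, _f5, _f3 = category_parts(ci)
            alt = alt_p if ref in PYRIMIDINES else revcomp(alt_p)
            ann = _annotate_snv(genome, chrom, pos, ref, alt)
            muts.append(
                {"clone": clone, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "kind": "snv", **ann}
            )
        for _ in range(n_indel):
            chrom, pos = pool.take_uniform()
            seq = genome.chroms[chrom]
            if rng.random() < 0.5 and pos < len(seq):
                ref, alt = seq[pos - 1], seq[pos - 1] + seq[pos - 1]  # homopolymer ins
            else:
                ref, alt = seq[pos - 1 : pos + 1], seq[pos - 1]  # 1-bp del
            hit = genome.gene_at(chrom, pos)
            gene = hit[0] if hit else ""
            muts.append(
                {"clone": clone, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "kind": "indel", "gene": gene,
                 "consequence": "frameshift" if gene else "noncoding",
                 "protein_change": f"X{(hit[1] // 3) + 1}fs" if gene else ""}
            )

    gene_coords = genome.gene_table.set_index("gene")
    for dev in config.driver_events:
        gene = dev["gene"]
        if gene not in gene_coords.index:
            continue
        row = gene_coords.loc[gene]
        chrom, pos = pool.take_in_interval(row["chrom"], int(row["start"]), int(row["end"]))
        seq = genome.chroms[chrom]
        kind = dev.get("kind", "snv")
        if kind == "snv":
            ref = seq[pos - 1]
            alt = alt_bases(ref)[int(rng.integers(0, 3))]
        else:
            ref, alt = seq[pos - 1], seq[pos - 1] + "A"
        muts.append(
            {"clone": int(dev["clone"]) % n_clones, "chrom": chrom, "pos": pos,
             "ref": ref, "alt": alt, "kind": kind, "gene": gene,
             "consequence": dev.get("consequence", "missense"),
             "protein_change": dev.get("protein_change", "")}
        )

    sites = pd.DataFrame(muts)
    sites.insert(0, "mut_id", [f"M{i + 1:06d}" for i in range(len(sites))])
    sites = sites.set_index("mut_id", drop=False)

    # --- allele assignment and per-region multiplicity ---------------------
    n_mut = len(sites)
    mult = np.zeros((n_mut, len(region_ids)), dtype=int)
    exp_vaf = np.zeros((n_mut, len(region_ids)))
    lost: set[tuple[str, str]] = set()

    clone_arr = sites["clone"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    pos_arr = sites["pos"].to_numpy()

    # birth-state events: ancestors' events + own 'before_mutations' events
    alleles = np.empty(n_mut, dtype="<U1")
    for j in range(n_mut):
        c = clone_arr[j]
        birth_applicable = {
            i
            for i, e in enumerate(events)
            if (anc_matrix[e.clone, c] and e.clone != c)
            or (e.clone == c and e.timing == "before_mutations")
        }
        bmaj, bmin = _allele_state(events, ev_order, birth_applicable, chrom_arr[j], pos_arr[j])
        if bmaj + bmin <= 0:
            alleles[j] = "A"
        else:
            alleles[j] = "A" if rng.random() < bmaj / (bmaj + bmin) else "B"

    cn_total_at = {}
    for rid in region_ids:
        seg = segments[rid].segments
        cn_total_at[rid] = _locus_lookup(seg, chrom_arr, pos_arr, "cn_total")

    for r_i, rid in enumerate(region_ids):
        dom = dominant[rid]
        for j in range(n_mut):
            c = clone_arr[j]
            c_ccf = ccf[r_i, c]
            if c_ccf <= 0:
                continue
            m = 1
            for i in ev_order:
                e = events[i]
                if not (e.chrom == chrom_arr[j] and e.start <= pos_arr[j] <= e.end):
                    continue
                postdates = (
                    (anc_matrix[c, e.clone] and e.clone != c and i in dom)
                    or (e.clone == c and e.timing == "after_mutations")
                )
                if postdates:
                    m = e.major if alleles[j] == "A" else e.minor
            mult[j, r_i] = m
            if m == 0:
                lost.add((sites.index[j], rid))
                continue
            p = purity[r_i]
            cnt = cn_total_at[rid][j]
            exp_vaf[j, r_i] = p * m * c_ccf / (p * cnt + 2.0 * (1.0 - p))

    # --- observed read counts ----------------------------------------------
    e_rate = config.error_rate
    obs_vaf = exp_vaf * (1 - e_rate) + (1 - exp_vaf) * e_rate / 3.0
    if config.noiseless:
        depth = np.full(exp_vaf.shape, config.mean_depth, dtype=int)
        alt_reads = np.rint(exp_vaf * depth).astype(int)
    else:
        depth = rng.poisson(config.mean_depth, size=exp_vaf.shape)
        alt_reads = rng.binomial(depth, obs_vaf)

    mean_vaf = exp_vaf.mean(axis=1)
    norm_vaf = config.normal_contamination * mean_vaf + (0 if config.noiseless else e_rate / 3.0)
    if config.noiseless:
        n_depth = np.full(n_mut, config.normal_depth, dtype=int)
        n_alt = np.rint(norm_vaf * n_depth).astype(int)
    else:
        n_depth = rng.poisson(config.normal_depth, size=n_mut)
        n_alt = rng.binomial(n_depth, norm_vaf)

    for r_i, rid in enumerate(region_ids):
        sites[f"REGION_{rid}_DEPTH"] = depth[:, r_i]
        sites[f"REGION_{rid}_ALT"] = alt_reads[:, r_i]
    sites["NORMAL_DEPTH"] = n_depth
    sites["NORMAL_ALT"] = n_alt

    truth = replace(
        gt_stub,
        mutation_clone=pd.Series(clone_arr, index=sites.index),
        mutation_multiplicity=pd.DataFrame(mult, index=sites.index, columns=region_ids),
        expected_vaf=pd.DataFrame(exp_vaf, index=sites.index, columns=region_ids),
        gain_timing={
            i: ("early" if e.timing == "before_mutations" else "late")
            for i, e in enumerate(events)
            if e.kind == "gain"
        },
        lost_mutations=lost,
    )
    return sites.drop(columns=["clone"]), segments, truth, genome


def _locus_lookup(seg: pd.DataFrame, chroms: np.ndarray, pos: np.ndarray, col: str) -> np.ndarray:
    out = np.full(len(chroms), 2.0 if col == "cn_total" else 1.0)
    for chrom, grp in seg.groupby("chrom"):
        grp = grp.sort_values("start")
        mask = chroms == chrom
        if not mask.any():
            continue
        idx = np.searchsorted(grp["start"].to_numpy(), pos[mask], side="right") - 1
        idx = np.clip(idx, 0, len(grp) - 1)
        out[mask] = grp[col].to_numpy()[idx]
    return out


def simulate_normal_panel(
    config: SimulationConfig,
    sites: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Panel of ``panel_size`` normals with recurrent artifact sites.

    Returns (per-site VAF table, list of artifact site ids).  A fraction
    ``artifact_rate`` of sites is designated artifact; each artifact site
    is carried (VAF >= 2%) by each normal with probability
    ``artifact_prevalence``.
    """
    if not 0 <= config.artifact_rate <= 1:
        raise ValueError("artifact_rate must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed + 10_007)
    if sites is None:
        sites, _, _, _ = simulate_tumour(config)
    ids = list(sites["mut_id"] if "mut_id" in sites else sites.index)
    n_art = int(round(config.artifact_rate * len(ids)))
    artifact_ids = [ids[i] for i in sorted(rng.choice(len(ids), size=n_art, replace=False))]
    panel_depth = 100
    vaf = rng.binomial(panel_depth, config.error_rate / 3.0, size=(len(ids), config.panel_size)) / panel_depth
    art_pos = {a: i for i, a in enumerate(ids)}
    for a in artifact_ids:
        carriers = rng.random(config.panel_size) < config.artifact_prevalence
        v = rng.uniform(0.03, 0.12, size=config.panel_size)
        row = vaf[art_pos[a]]
        row[carriers] = v[carriers]
    panel = pd.DataFrame(
        vaf, index=pd.Index(ids, name="mut_id"),
        columns=[f"N{i + 1}" for i in range(config.panel_size)],
    )
    return panel, artifact_ids
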