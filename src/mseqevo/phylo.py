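"""Clone-tree reconstruction from regional CCF profiles.

Mutations are grouped into clusters by their regional presence pattern
and CCF centroid; clusters become candidate clones of a rooted tree
(root = germline).  A parent assignment is valid when (a) a child's
presence regions are contained in its parent's, and (b) the lineage sum
rule holds within a slack epsilon per region: a parent's centroid CCF
must be at least the sum of its children's.  The tree error score sums,
over nodes and regions, the positive part of (sum of children - parent).
Trees are ranked by a noise-tolerant version of that error, then by
parent-child tightness (parsimony: prefer the closest dominating
ancestor), then by the exact error and a lexicographic edge-list
tie-break.  Search is exhaustive for small cluster counts and
greedy-plus-local-search beyond.

This is a constraint-network re-implementation in the spirit of
multi-sample lineage tools (LICHeE-like), not a port.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

log = logging.getLogger(__name__)

GERMLINE = "germline"


@dataclass
class CloneCluster:
    cluster_id: str
    members: list[str]
    centroid: pd.Series  # region -> CCF in [0, 1]
    presence: pd.Series  # region -> bool
    has_driver: bool = False

    @property
    def n_members(self) -> int:
        return len(self.members)

    def regions(self) -> frozenset:
        return frozenset(self.presence.index[self.presence])


@dataclass
class CloneTree:
    """Rooted clone tree; branch length of a node = its member count."""

    clusters: dict[str, CloneCluster]
    parent: dict[str, str | None]  # node -> parent (germline -> None)
    error_score: float
    valid: bool = True
    unassigned: list[str] = field(default_factory=list)

    def children(self, node: str) -> list[str]:
        return sorted(k for k, p in self.parent.items() if p == node)

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c, p in self.parent.items() if p is not None)

    def is_ancestor(self, a: str, b: str) -> bool:
        p = self.parent.get(b)
        while p is not None:
            if p == a:
                return True
            p = self.parent.get(p)
        return False

    def newick(self) -> str:
        def rec(node: str) -> str:
            kids = self.children(node)
            length = self.clusters[node].n_members if node in self.clusters else 0
            inner = f"({','.join(rec(k) for k in kids)})" if kids else ""
            return f"{inner}{node}:{length}"

        return rec(GERMLINE) + ";"

    def to_json(self) -> str:
        payload = {
            "error_score": self.error_score,
            "valid": self.valid,
            "edges": self.edges(),
            "unassigned": list(self.unassigned),
            "clusters": {
                cid: {
                    "n_members": c.n_members,
                    "members": list(c.members),
                    "centroid": {r: float(v) for r, v in c.centroid.items()},
                    "presence": {r: bool(v) for r, v in c.presence.items()},
                    "has_driver": c.has_driver,
                }
                for cid, c in self.clusters.items()
            },
        }
        return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------


def cluster_ccfs(
    ccf_wide: pd.DataFrame,
    min_cluster: int = 8,
    absent_max: float = 0.0,
    present_min: float = 1e-4,
    merge_distance: float = 0.10,
    dropout_ccf: float = 0.25,
    driver_flags: pd.Series | None = None,
    retain_driver_clusters: bool = True,
) -> tuple[list[CloneCluster], list[str]]:
    """Group mutations by presence pattern, then by CCF centroid.

    Because per-region presence is a thresholded VAF call, a clone whose
    CCF sits near the detection limit sheds mutations into spurious
    sub-patterns.  After within-pattern centroid clustering, a cluster is
    therefore absorbed into a larger one when its pattern is a subset of
    the larger cluster's, their centroids agree (within
    ``merge_distance``, Chebyshev) on its present regions, and every
    missing region is one where the larger cluster's centroid CCF is at
    most ``dropout_ccf`` (i.e. detection dropout is plausible).

    Clusters smaller than ``min_cluster`` are then dissolved into the
    unassigned list unless they contain a driver-flagged mutation and
    ``retain_driver_clusters`` is set.
    Returns (clusters, unassigned mutation ids).
    """
    if ccf_wide.empty:
        raise ValueError("empty CCF matrix")
    regions = list(ccf_wide.columns)
    present = ccf_wide > present_min
    if absent_max > 0:
        ambiguous = (~present) & (ccf_wide > absent_max)
        present |= ambiguous  # values above absent_max count as present
    drivers = (
        driver_flags.reindex(ccf_wide.index, fill_value=False)
        if driver_flags is not None
        else pd.Series(False, index=ccf_wide.index)
    )

    raw: list[tuple[list[str], np.ndarray, tuple]] = []
    for pattern, grp in ccf_wide.groupby([present[r] for r in regions]):
        if not isinstance(pattern, tuple):
            pattern = (pattern,)
        if not any(pattern):
            continue
        values = grp.to_numpy()
        labels = _split_pattern_group(values, min_cluster, merge_distance)
        for lab in np.unique(labels):
            members = list(grp.index[labels == lab])
            centroid = values[labels == lab].mean(axis=0)
            raw.append((members, centroid, pattern))

    raw = _absorb_dropout_clusters(
        raw, ccf_wide, present_min, merge_distance, dropout_ccf
    )

    clusters: list[CloneCluster] = []
    unassigned: list[str] = []
    for members, centroid, pattern in raw:
        has_driver = bool(drivers.loc[members].any())
        if len(members) < min_cluster and not (retain_driver_clusters and has_driver):
            unassigned.extend(members)
            continue
        clusters.append(
            CloneCluster(
                cluster_id="",
                members=sorted(members),
                centroid=pd.Series(np.clip(centroid, 0.0, 1.0), index=regions),
                presence=pd.Series(pattern, index=regions),
                has_driver=has_driver,
            )
        )
    clusters.sort(
        key=lambda c: (-int(c.presence.sum()), -float(c.centroid.sum()), c.members[0])
    )
    for i, c in enumerate(clusters):
        c.cluster_id = f"C{i + 1}"
    return clusters, sorted(unassigned)


def _split_pattern_group(
    values: np.ndarray, min_cluster: int, sep_min: float, k_max: int = 5
) -> np.ndarray:
    """Split one presence-pattern group into CCF-centroid clusters.

    Model selection over 1..k_max Gaussian mixture components by BIC,
    rejecting solutions whose component centroids come closer than
    ``sep_min`` (Chebyshev) — clusters within measurement tolerance of
    each other are one clone.  Deterministic.
    """
    import warnings

    n = len(values)
    k_cap = min(k_max, max(1, n // max(min_cluster, 2)))
    if n < 2 or k_cap == 1 or (values == values[0]).all():
        return np.zeros(n, dtype=int)
    best_labels = np.zeros(n, dtype=int)
    best_bic = np.inf
    for k in range(1, k_cap + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="diag", reg_covar=1e-4,
            n_init=2, random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate rows at k-means init
            labels = gm.fit_predict(values)
        if k > 1:
            cents = gm.means_
            sep = min(
                np.abs(cents[a] - cents[b]).max()
                for a in range(k)
                for b in range(a + 1, k)
            )
            if sep < sep_min:
                continue
        bic = gm.bic(values)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best_labels = labels
    return best_labels


def _absorb_dropout_clusters(raw, ccf_wide, present_min, merge_distance, dropout_ccf):
    """Iteratively merge detection-dropout fragments into larger clusters."""

    def centroid_of(members, pattern):
        vals = ccf_wide.loc[members].to_numpy(dtype=float)
        cent = np.zeros(vals.shape[1])
        for j in range(vals.shape[1]):
            col = vals[:, j]
            nz = col > present_min
            cent[j] = col[nz].mean() if (pattern[j] and nz.any()) else 0.0
        return cent

    items = [
        {"members": list(m), "centroid": np.asarray(c, dtype=float), "pattern": tuple(p)}
        for m, c, p in raw
    ]
    changed = True
    while changed:
        changed = False
        items.sort(key=lambda it: (-len(it["members"]), it["members"][0]))
        for i, big in enumerate(items):
            bp = np.asarray(big["pattern"], dtype=bool)
            for j in range(len(items) - 1, i, -1):
                small = items[j]
                sp = np.asarray(small["pattern"], dtype=bool)
                if (sp & ~bp).any() or not sp.any():
                    continue
                dist = np.abs(big["centroid"][sp] - small["centroid"][sp]).max()
                missing = bp & ~sp
                # a dropout fragment is a minority of the merged cluster;
                # a similarly sized group is a distinct clone
                minority = len(small["members"]) <= (
                    len(small["members"]) + len(big["members"])
                ) / 3
                if (
                    minority
                    and dist <= merge_distance
                    and (big["centroid"][missing] <= dropout_ccf).all()
                ):
                    big["members"] += small["members"]
                    big["centroid"] = centroid_of(big["members"], bp)
                    del items[j]
                    changed = True
            if changed:
                break
    return [(it["members"], it["centroid"], it["pattern"]) for it in items]


# ---------------------------------------------------------------------------
# Tree building
# ---------------------------------------------------------------------------


def _tree_error(
    parent: dict[str, str],
    centroids: dict[str, np.ndarray],
    n_regions: int,
    rank_epsilon: float = 0.0,
) -> tuple[float, float, float]:
    """(total error, max per-(node, region) violation, soft error).

    The soft error discounts violations up to ``rank_epsilon`` per
    (node, region) — centroid noise at the sum-rule boundary — and is
    used for ranking only; the reported error score is the plain sum of
    positive violations.
    """
    sums: dict[str, np.ndarray] = {}
    for child, par in parent.items():
        sums.setdefault(par, np.zeros(n_regions))
        sums[par] = sums[par] + centroids[child]
    err = 0.0
    worst = 0.0
    soft = 0.0
    for node, s in sums.items():
        viol = np.maximum(0.0, s - centroids[node])
        err += float(viol.sum())
        worst = max(worst, float(viol.max()))
        soft += float(np.maximum(0.0, viol - rank_epsilon).sum())
    return err, worst, soft


def _tightness(parent: dict[str, str], centroids: dict[str, np.ndarray]) -> float:
    """Total L1 slack between parents and children; among equal-error
    trees, the tightest (most parsimonious) parent assignment wins."""
    return float(
        sum(np.abs(centroids[p] - centroids[c]).sum() for c, p in parent.items())
    )


def _is_tree(parent: dict[str, str], nodes: list[str]) -> bool:
    for n in nodes:
        seen = set()
        cur = n
        while cur != GERMLINE:
            if cur in seen:
                return False
            seen.add(cur)
            cur = parent[cur]
    return True


def build_tree(
    clusters: list[CloneCluster],
    epsilon: float = 0.10,
    max_exhaustive: int = 12,
    max_candidates: int = 500_000,
    top_k: int = 10,
    unassigned: list[str] | None = None,
    rank_epsilon: float = 0.05,
) -> list[CloneTree]:
    """Ranked clone trees (ascending error score).

    Ranking is by (noise-tolerant soft error, exact error, parent-child
    tightness, lexicographic edge list); the reported ``error_score`` is
    the plain sum of positive sum-rule violations.  If no assignment
    satisfies the sum rule within ``epsilon``, the best-effort
    minimum-error tree is returned flagged invalid.
    """
    if not clusters:
        raise ValueError("no clusters to build a tree from")
    regions = list(clusters[0].centroid.index)
    n_regions = len(regions)
    ids = [c.cluster_id for c in clusters]
    by_id = {c.cluster_id: c for c in clusters}
    centroids = {cid: by_id[cid].centroid.to_numpy(dtype=float) for cid in ids}
    centroids[GERMLINE] = np.ones(n_regions)
    regsets = {cid: by_id[cid].regions() for cid in ids}
    regsets[GERMLINE] = frozenset(regions)

    candidates: dict[str, list[str]] = {}
    for cid in ids:
        cand = [
            other
            for other in ids
            if other != cid
            and regsets[cid] <= regsets[other]
            and (centroids[other] >= centroids[cid] - epsilon).all()
        ]
        candidates[cid] = sorted(cand) + [GERMLINE]

    n_combo = float(np.prod([float(len(candidates[c])) for c in ids])) if ids else 0
    solutions: list[tuple[float, list, dict]] = []
    if len(ids) <= max_exhaustive and 0 < n_combo <= max_candidates:
        for combo in itertools.product(*(candidates[c] for c in ids)):
            parent = dict(zip(ids, combo))
            if not _is_tree(parent, ids):
                continue
            err, worst, soft = _tree_error(parent, centroids, n_regions, rank_epsilon)
            tight = _tightness(parent, centroids)
            solutions.append(
                ((round(soft, 10), round(tight, 10), round(err, 10), sorted(parent.items())),
                 err, {"worst": worst, "parent": parent})
            )
            if len(solutions) > 5000:
                solutions.sort(key=lambda t: t[0])
                del solutions[max(top_k, 1):]
        solutions.sort(key=lambda t: t[0])
    else:
        parent = _greedy_tree(ids, candidates, centroids, n_regions, rank_epsilon)
        err, worst, soft = _tree_error(parent, centroids, n_regions, rank_epsilon)
        solutions = [
            ((round(soft, 10), 0.0, round(err, 10), sorted(parent.items())), err,
             {"worst": worst, "parent": parent})
        ]

    trees: list[CloneTree] = []
    for _key, err, info in solutions[: max(top_k, 1)]:
        tree_parent: dict[str, str | None] = {GERMLINE: None}
        tree_parent.update(info["parent"])
        trees.append(
            CloneTree(
                clusters=dict(by_id),
                parent=tree_parent,
                error_score=err,
                valid=info["worst"] <= epsilon + 1e-12,
                unassigned=list(unassigned or []),
            )
        )
    valid = [t for t in trees if t.valid]
    if valid:
        return valid + [t for t in trees if not t.valid]
    log.warning("no tree satisfies the sum rule within epsilon=%.3g; "
                "returning best-effort tree flagged invalid", epsilon)
    return trees[:1]


def _greedy_tree(ids, candidates, centroids, n_regions, rank_epsilon):
    """Attach nodes in decreasing-extent order to the locally best parent,
    then hill-climb single-parent reassignments."""
    order = sorted(
        ids, key=lambda c: (-float((centroids[c] > 0).sum()), -float(centroids[c].sum()), c)
    )
    parent: dict[str, str] = {}
    placed = [GERMLINE]

    def cost(p: dict[str, str]) -> tuple[float, float, float]:
        err, _, soft = _tree_error(p, centroids, n_regions, rank_epsilon)
        return (round(soft, 10), round(_tightness(p, centroids), 10), round(err, 10))

    for cid in order:
        opts = [p for p in candidates[cid] if p in placed] or [GERMLINE]
        best, best_cost = None, (np.inf, np.inf, np.inf)
        for p in opts:
            trial = dict(parent)
            trial[cid] = p
            c = cost(trial)
            if c < best_cost:
                best, best_cost = p, c
        parent[cid] = best
        placed.append(cid)
    improved = True
    while improved:
        improved = False
        for cid in order:
            cur = cost(parent)
            for p in candidates[cid]:
                if p == parent[cid]:
                    continue
                trial = dict(parent)
                trial[cid] = p
                if not _is_tree(trial, list(ids)):
                    continue
                if cost(trial) < cur:
                    parent = trial
                    cur = cost(parent)
                    improved = True
    return parent


# ---------------------------------------------------------------------------
# Conflicts and parallel evolution
# ---------------------------------------------------------------------------


def _locus_cn_total(segments, region: str, chrom: str, pos: int) -> float | None:
    state = segments[region].state_at(chrom, pos)
    return None if state is None else float(state["cn_total"])


def assign_clades(
    tree: CloneTree,
    presence: pd.DataFrame,
    ccf_wide: pd.DataFrame,
    segments: dict | None = None,
    loci: pd.DataFrame | None = None,
    match_tol: float = 0.15,
    dropout_ccf: float = 0.25,
) -> pd.Series:
    """Map each mutation to its most plausible clade (tree node).

    Candidates are nodes whose presence covers the mutation's presence
    regions and whose centroid, restricted to those regions, lies within
    ``match_tol`` (Chebyshev) of the mutation's CCFs.  A candidate with
    extra regions stays in the running only when every absence there is
    plausible — the locus total CN in the absent region is lower than in
    the regions carrying the mutation (copy loss), or the candidate's
    centroid CCF is at most ``dropout_ccf`` (detection dropout).  Among
    plausible candidates the largest (by member count) wins, which lets
    mutations deleted by a regional copy loss rejoin their parental
    clone; otherwise the mutation keeps its own membership node.
    """
    member_of: dict[str, str] = {}
    for cid, cluster in tree.clusters.items():
        for m in cluster.members:
            member_of[m] = cid
    nodes = sorted(tree.clusters.values(), key=lambda c: (-c.n_members, c.cluster_id))
    out = {}
    for mut in presence.index:
        pat = presence.loc[mut]
        pres_regions = list(pat.index[pat])
        if not pres_regions:
            out[mut] = member_of.get(mut, pd.NA)
            continue
        vals = ccf_wide.loc[mut, pres_regions].to_numpy(dtype=float)
        ref_cn = None
        chrom = pos = None
        if segments is not None and loci is not None:
            chrom = str(loci.loc[mut, "chrom"])
            pos = int(loci.loc[mut, "pos"])
            cns = [
                cn
                for r in pres_regions
                if (cn := _locus_cn_total(segments, r, chrom, pos)) is not None
            ]
            ref_cn = min(cns) if cns else None
        chosen = None
        for node in nodes:
            if not set(pres_regions) <= node.regions():
                continue
            cent = node.centroid[pres_regions].to_numpy(dtype=float)
            if np.abs(cent - vals).max() > match_tol:
                continue
            plausible = True
            for r in node.regions() - set(pres_regions):
                loss = False
                if ref_cn is not None:
                    cn_r = _locus_cn_total(segments, r, chrom, pos)
                    loss = cn_r is not None and cn_r < ref_cn
                if not loss and node.centroid[r] > dropout_ccf:
                    plausible = False
                    break
            if plausible:
                chosen = node.cluster_id
                break
        out[mut] = chosen if chosen is not None else member_of.get(mut, pd.NA)
    return pd.Series(out, name="clade")


def explain_conflicts(
    presence: pd.DataFrame,
    tree: CloneTree,
    segments: dict[str, "SegmentProfile"],
    loci: pd.DataFrame,
    ccf_wide: pd.DataFrame,
    match_tol: float = 0.15,
) -> pd.DataFrame:
    """Explain presence-matrix conflicts against the tree by copy losses.

    A conflict is a (mutation, region) pair where the mutation's clade is
    present but the mutation is not; it is ``explained_by_loss`` iff the
    locus total CN in that region is strictly lower than the minimum CN
    across the regions where the mutation IS present.  Returns a long
    report (mut_id, region, clade, status).
    """
    clades = assign_clades(tree, presence, ccf_wide, segments, loci, match_tol)
    rows = []
    for mut, clade in clades.items():
        if pd.isna(clade):
            continue
        node = tree.clusters[clade]
        pat = presence.loc[mut]
        missing = [r for r in pat.index if node.presence.get(r, False) and not pat[r]]
        if not missing:
            continue
        chrom = str(loci.loc[mut, "chrom"])
        pos = int(loci.loc[mut, "pos"])
        present_cn = []
        for r in pat.index[pat]:
            st = segments[r].state_at(chrom, pos)
            if st is not None:
                present_cn.append(float(st["cn_total"]))
        ref_cn = min(present_cn) if present_cn else None
        for r in missing:
            st = segments[r].state_at(chrom, pos)
            if st is None or ref_cn is None:
                log.info("locus %s:%d not covered by segments in %s", chrom, pos, r)
                status = "unexplained"
            else:
                status = (
                    "explained_by_loss"
                    if float(st["cn_total"]) < ref_cn
                    else "unexplained"
                )
            rows.append({"mut_id": mut, "region": r, "clade": clade, "status": status})
    return pd.DataFrame(rows, columns=["mut_id", "region", "clade", "status"])


def detect_parallel_evolution(
    tree: CloneTree,
    sites: pd.DataFrame,
    driver_flags: pd.Series,
    clades: pd.Series | None = None,
) -> pd.DataFrame:
    """Genes with driver mutations on two or more distinct tree branches.

    An event is 'parallel' when at least two carrying branches are
    mutually non-ancestral, and 'trunk_and_branch' when the branches
    form an ancestral chain (progressive inactivation).  ``same_residue``
    marks identical protein changes (or identical altered positions) on
    distinct branches.
    """
    if clades is None:
        member_of = {}
        for cid, cluster in tree.clusters.items():
            for m in cluster.members:
                member_of[m] = cid
        clades = pd.Series(member_of)
    drv = sites.loc[driver_flags.reindex(sites.index, fill_value=False)]
    rows = []
    for gene, grp in drv.groupby("gene"):
        if not gene:
            continue
        node_of = {m: clades.get(m) for m in grp.index}
        nodes = sorted({n for n in node_of.values() if not pd.isna(n)})
        if len(nodes) < 2:
            continue
        parallel = any(
            not tree.is_ancestor(a, b) and not tree.is_ancestor(b, a)
            for a, b in itertools.combinations(nodes, 2)
        )
        changes = {}
        for m in grp.index:
            n = node_of[m]
            if pd.isna(n):
                continue
            pc = grp.loc[m, "protein_change"]
            if pc:
                changes.setdefault(_residue(pc), set()).add(n)
        same_residue = any(len(v) > 1 for v in changes.values())
        rows.append(
            {
                "gene": gene,
                "branches": ",".join(nodes),
                "n_mutations": len(grp),
                "kind": "parallel" if parallel else "trunk_and_branch",
                "same_residue": same_residue,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "branches", "n_mutations", "kind", "same_residue"])


def _residue(protein_change: str) -> str:
    digits = "".join(ch for ch in protein_change if ch.isdigit())
    return digits or protein_change
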