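"""Clustering, sum-rule tree search (vs a brute-force oracle), conflicts
and parallel evolution."""

import itertools

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo
from io import StringIO

from mseqevo.cna import SegmentProfile
from mseqevo.phylo import (
    CloneCluster,
    build_tree,
    cluster_ccfs,
    detect_parallel_evolution,
    explain_conflicts,
)

REGIONS = ["R1", "R2", "R3"]


def cluster(cid, centroid, n_members=20, has_driver=False, members=None):
    cent = pd.Series(centroid, index=REGIONS[: len(centroid)], dtype=float)
    members = members or [f"{cid}_m{i}" for i in range(n_members)]
    return CloneCluster(
        cluster_id=cid,
        members=members,
        centroid=cent,
        presence=cent > 0,
        has_driver=has_driver,
    )


# ---------------------------------------------------------------------------
# Independent brute-force oracle for the tree search
# ---------------------------------------------------------------------------


def oracle_best_tree(clusters, epsilon=0.10, rank_epsilon=0.05):
    """Exhaustive enumeration of parent maps, re-implemented from scratch:
    candidates by region containment + CCF dominance, ranked by
    (soft error, tightness, error, edge list)."""
    ids = [c.cluster_id for c in clusters]
    cent = {c.cluster_id: c.centroid.to_numpy(dtype=float) for c in clusters}
    regs = {c.cluster_id: frozenset(c.centroid.index[c.centroid > 0]) for c in clusters}
    all_regions = frozenset(clusters[0].centroid.index)
    cent["germline"] = np.ones(len(all_regions))
    regs["germline"] = all_regions

    def ok_parent(p, c):
        return regs[c] <= regs[p] and (cent[p] >= cent[c] - epsilon).all()

    options = {c: [p for p in ids + ["germline"] if p != c and ok_parent(p, c)] for c in ids}
    best = None
    for combo in itertools.product(*(options[c] for c in ids)):
        parent = dict(zip(ids, combo))
        # connectivity to germline without cycles
        good = True
        for node in ids:
            seen, cur = set(), node
            while cur != "germline":
                if cur in seen:
                    good = False
                    break
                seen.add(cur)
                cur = parent[cur]
            if not good:
                break
        if not good:
            continue
        err = soft = tight = 0.0
        for node in ids + ["germline"]:
            kids = [c for c in ids if parent[c] == node]
            if kids:
                s = sum(cent[c] for c in kids)
                v = np.maximum(0.0, s - cent[node])
                err += v.sum()
                soft += np.maximum(0.0, v - rank_epsilon).sum()
        for c in ids:
            tight += np.abs(cent[parent[c]] - cent[c]).sum()
        key = (round(soft, 10), round(tight, 10), round(err, 10), sorted(parent.items()))
        if best is None or key < best[0]:
            best = (key, parent, err)
    return best


class TestBuildTree:
    def test_two_branch_tree_with_disjoint_children(self):
        clusters = [
            cluster("T", [1.0, 1.0, 1.0]),
            cluster("A", [0.6, 0.0, 0.0]),
            cluster("B", [0.0, 0.7, 0.0]),
        ]
        tree = build_tree(clusters)[0]
        assert tree.edges() == [("T", "A"), ("T", "B"), ("germline", "T")]
        assert tree.error_score == pytest.approx(0.0, abs=1e-12)
        assert tree.valid

    def test_sum_rule_violation_scored_for_forced_siblings(self):
        """Two crossing-presence children exceeding the trunk accumulate
        per-region positive violations."""
        clusters = [
            cluster("T", [1.0, 1.0, 1.0]),
            cluster("A", [0.6, 0.6, 0.0]),
            cluster("B", [0.5, 0.0, 0.5]),
        ]
        tree = build_tree(clusters)[0]
        assert tree.edges() == [("T", "A"), ("T", "B"), ("germline", "T")]
        # region R1: 0.6 + 0.5 - 1.0 = 0.1 violation
        assert tree.error_score == pytest.approx(0.1, abs=1e-9)

    def test_single_truncal_cluster_gives_star_tree(self):
        tree = build_tree([cluster("T", [1.0, 1.0, 1.0])])[0]
        assert tree.edges() == [("germline", "T")]
        assert tree.error_score == 0.0

    def test_nested_chain_prefers_tightest_dominating_parent(self):
        clusters = [
            cluster("T", [1.0, 1.0, 1.0]),
            cluster("A", [0.8, 0.6, 0.0]),
            cluster("B", [0.5, 0.4, 0.0]),
        ]
        tree = build_tree(clusters)[0]
        assert ("A", "B") in tree.edges()

    def test_no_clusters_is_an_error(self):
        with pytest.raises(ValueError, match="no clusters"):
            build_tree([])

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_bruteforce_oracle_on_random_instances(self, seed):
        """On <= 6-cluster random instances the search returns exactly the
        oracle's best tree (same edges, same error)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 7))
        clusters = [cluster("T", [1.0, 1.0, 1.0])]
        for i in range(n - 1):
            cent = np.round(rng.uniform(0, 0.8, size=3) * (rng.random(3) < 0.7), 2)
            if cent.max() == 0:
                cent[int(rng.integers(0, 3))] = 0.4
            clusters.append(cluster(f"C{i}", cent))
        tree = build_tree(clusters)[0]
        best = oracle_best_tree(clusters)
        assert best is not None
        oracle_edges = sorted((p, c) for c, p in best[1].items())
        assert tree.edges() == oracle_edges
        assert tree.error_score == pytest.approx(best[2], abs=1e-9)


class TestClusterCcfs:
    def _wide(self, rows):
        return pd.DataFrame(rows, columns=REGIONS)

    def test_two_noiseless_patterns_give_two_clusters(self):
        wide = self._wide(
            [[1.0, 1.0, 1.0]] * 20 + [[0.5, 0.5, 0.0]] * 20
        )
        wide.index = [f"M{i}" for i in range(len(wide))]
        clusters, unassigned = cluster_ccfs(wide)
        assert len(clusters) == 2 and not unassigned

    def test_small_cluster_without_driver_dissolved(self):
        wide = self._wide([[1.0, 1.0, 1.0]] * 20 + [[0.0, 0.6, 0.0]] * 5)
        wide.index = [f"M{i}" for i in range(len(wide))]
        clusters, unassigned = cluster_ccfs(wide)
        assert len(clusters) == 1 and len(unassigned) == 5

    def test_small_cluster_with_driver_retained(self):
        wide = self._wide([[1.0, 1.0, 1.0]] * 20 + [[0.0, 0.6, 0.0]] * 5)
        wide.index = [f"M{i}" for i in range(len(wide))]
        drivers = pd.Series(False, index=wide.index)
        drivers["M22"] = True
        clusters, unassigned = cluster_ccfs(wide, driver_flags=drivers)
        assert len(clusters) == 2 and not unassigned
        assert any(c.has_driver for c in clusters)

    def test_same_pattern_distinct_centroids_split(self):
        wide = self._wide([[1.0, 1.0, 0.0]] * 20 + [[0.4, 0.4, 0.0]] * 20)
        wide.index = [f"M{i}" for i in range(len(wide))]
        clusters, _ = cluster_ccfs(wide)
        assert len(clusters) == 2

    def test_empty_matrix_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_ccfs(pd.DataFrame())


def test_branch_lengths_conserve_assigned_mutation_count():
    wide = pd.DataFrame(
        [[1.0, 1.0, 1.0]] * 30 + [[0.5, 0.0, 0.0]] * 12 + [[0.0, 0.5, 0.0]] * 5,
        columns=REGIONS, index=[f"M{i}" for i in range(47)],
    )
    clusters, unassigned = cluster_ccfs(wide)
    tree = build_tree(clusters, unassigned=unassigned)[0]
    assigned = sum(c.n_members for c in tree.clusters.values())
    assert assigned + len(tree.unassigned) == 47


def test_newick_output_is_parseable_with_branch_lengths():
    clusters = [
        cluster("T", [1.0, 1.0, 1.0], n_members=30),
        cluster("A", [0.6, 0.0, 0.0], n_members=12),
    ]
    tree = build_tree(clusters)[0]
    parsed = Phylo.read(StringIO(tree.newick()), "newick")
    terminals = {t.name: t.branch_length for t in parsed.get_terminals()}
    assert terminals == {"A": 12.0}
    assert parsed.root.name == "germline"


class TestConflicts:
    def _segments(self, cn_by_region):
        return {
            rid: SegmentProfile(
                region_id=rid,
                purity=0.7,
                segments=pd.DataFrame(
                    [("1", 1, 10_000, float(cn), max(int(cn) - 1, 1), min(int(cn) - 1, 1))],
                    columns=["chrom", "start", "end", "cn_total", "cn_major", "cn_minor"],
                ),
            )
            for rid, cn in cn_by_region.items()
        }

    def _fixture(self):
        members = [f"T_m{i}" for i in range(20)] + ["Mx"]
        trunk = cluster("T", [1.0, 1.0, 1.0], members=members)
        presence = pd.DataFrame(
            True, index=members, columns=REGIONS
        )
        presence.loc["Mx", "R2"] = False
        wide = presence.astype(float)
        tree = build_tree([trunk])[0]
        loci = pd.DataFrame(
            {"chrom": "1", "pos": 5000}, index=members
        )
        return tree, presence, wide, loci

    def test_copy_loss_in_absent_region_explains_conflict(self):
        tree, presence, wide, loci = self._fixture()
        segments = self._segments({"R1": 2, "R2": 1, "R3": 2})
        out = explain_conflicts(presence, tree, segments, loci, wide)
        assert out["status"].tolist() == ["explained_by_loss"]
        assert out["mut_id"].tolist() == ["Mx"] and out["region"].tolist() == ["R2"]

    def test_flat_copy_number_leaves_conflict_unexplained(self):
        tree, presence, wide, loci = self._fixture()
        segments = self._segments({"R1": 2, "R2": 2, "R3": 2})
        out = explain_conflicts(presence, tree, segments, loci, wide)
        assert out["status"].tolist() == ["unexplained"]


class TestParallelEvolution:
    def _sites(self, rows):
        return pd.DataFrame(rows).set_index("mut_id")

    def _tree(self):
        clusters = [
            cluster("T", [1.0, 1.0, 1.0], members=["m1"]),
            cluster("A", [0.6, 0.0, 0.0], members=["m2"]),
            cluster("B", [0.0, 0.7, 0.0], members=["m3"]),
        ]
        return build_tree(clusters)[0]

    def test_same_gene_on_sibling_branches_is_parallel(self):
        tree = self._tree()
        sites = self._sites(
            [
                {"mut_id": "m2", "gene": "KRAS", "protein_change": "G13D"},
                {"mut_id": "m3", "gene": "KRAS", "protein_change": "G13D"},
            ]
        )
        flags = pd.Series(True, index=sites.index)
        out = detect_parallel_evolution(tree, sites, flags)
        assert out["kind"].tolist() == ["parallel"]
        assert out["same_residue"].tolist() == [True]

    def test_trunk_plus_branch_is_progressive_inactivation(self):
        tree = self._tree()
        sites = self._sites(
            [
                {"mut_id": "m1", "gene": "ARID1A", "protein_change": "M274fs"},
                {"mut_id": "m2", "gene": "ARID1A", "protein_change": "Q100fs"},
            ]
        )
        flags = pd.Series(True, index=sites.index)
        out = detect_parallel_evolution(tree, sites, flags)
        assert out["kind"].tolist() == ["trunk_and_branch"]
        assert out["same_residue"].tolist() == [False]

    def test_gene_only_on_trunk_is_no_event(self):
        tree = self._tree()
        sites = self._sites(
            [{"mut_id": "m1", "gene": "TP53", "protein_change": "R175H"}]
        )
        out = detect_parallel_evolution(tree, sites, pd.Series(True, index=sites.index))
        assert out.empty
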