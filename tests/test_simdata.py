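"""Simulator contracts: VAF model limits, determinism, truth structure."""

import numpy as np
import pandas as pd
import pytest

from mseqevo.catalogs import orthogonal_catalog, synthetic_signature_catalog
from mseqevo.contexts import CONTEXT_LABELS
from mseqevo.simdata import (
    SimulationConfig,
    parse_clone_tree,
    sample_contexts,
    simulate_normal_panel,
    simulate_tumour,
)
from mseqevo.variants import vaf_frame

SMALL_TREE = [(None, 60), (0, 40), (0, 30)]


def small_config(**kw):
    base = dict(
        seed=7,
        clone_tree_spec=SMALL_TREE,
        truncal_mutations=None,
        n_regions=3,
        cna_events=[],
        loss_events=[],
        driver_events=[],
        genome=[("1", 12000), ("2", 12000)],
    )
    base.update(kw)
    return SimulationConfig(**base)


def test_vaf_is_half_for_pure_diploid_clonal_heterozygous():
    """p=1, diploid, CCF=1, multiplicity 1 gives VAF exactly 0.5 without noise."""
    cfg = small_config(
        clone_tree_spec=[(None, 50)], purity_range=(1.0, 1.0),
        noiseless=True, error_rate=0.0,
    )
    sites, _, truth, _ = simulate_tumour(cfg)
    vaf = vaf_frame(sites)
    assert np.allclose(vaf.to_numpy(), 0.5)
    assert np.allclose(truth.expected_vaf.to_numpy(), 0.5)


def test_same_seed_gives_byte_identical_outputs():
    cfg = small_config()
    a_sites, a_segs, a_truth, _ = simulate_tumour(cfg)
    b_sites, b_segs, b_truth, _ = simulate_tumour(cfg)
    pd.testing.assert_frame_equal(a_sites, b_sites)
    for rid in a_segs:
        pd.testing.assert_frame_equal(a_segs[rid].segments, b_segs[rid].segments)
    pd.testing.assert_frame_equal(a_truth.expected_vaf, b_truth.expected_vaf)
    assert a_truth.lost_mutations == b_truth.lost_mutations


def test_truncal_mutations_are_ubiquitous_in_truth():
    """A 700-truncal / 1200-branch tumour has exactly 700 ubiquitous
    mutations before loss events are applied."""
    cfg = SimulationConfig(
        seed=5,
        clone_tree_spec=[(None, 700), (0, 400), (0, 400), (1, 400)],
        n_regions=7,
        driver_events=[],
    )
    _, _, truth, _ = simulate_tumour(cfg)
    cats = truth.categories(ignore_losses=True)
    assert (cats == "ubiquitous").sum() == 700
    assert (cats != "ubiquitous").sum() == 1200


def test_lineage_sum_rule_holds_in_every_region():
    """Parent subtree CCF >= sum of child subtree CCFs, per region."""
    for seed in (1, 2, 3):
        cfg = SimulationConfig(seed=seed, driver_events=[])
        _, _, truth, _ = simulate_tumour(cfg)
        kids = {}
        for c, p in truth.parent.items():
            if p is not None:
                kids.setdefault(p, []).append(c)
        for parent, children in kids.items():
            child_sum = truth.clone_ccf[children].sum(axis=1)
            assert (truth.clone_ccf[parent] + 1e-9 >= child_sum).all()


def test_mean_observed_vaf_converges_to_expected_vaf():
    """Across replicate draws the empirical VAF tracks the formula within
    three standard errors."""
    cfg = small_config(purity_range=(0.6, 0.6), error_rate=0.0, mean_depth=200)
    sites, _, truth, _ = simulate_tumour(cfg)
    vaf = vaf_frame(sites)
    exp = truth.expected_vaf
    mask = exp > 0.05
    resid = (vaf.to_numpy() - exp.to_numpy())[mask.to_numpy()]
    se = np.sqrt((exp.to_numpy() * (1 - exp.to_numpy()) / 200)[mask.to_numpy()])
    assert np.abs(resid.mean()) < 3 * se.mean() / np.sqrt(len(resid))


def test_noiseless_vafs_recover_truth_categories_exactly():
    cfg = small_config(noiseless=True, error_rate=0.0, purity_range=(0.6, 0.6))
    sites, _, truth, _ = simulate_tumour(cfg)
    vaf = vaf_frame(sites)
    presence = vaf > 0
    n = presence.sum(axis=1)
    cats = pd.Series("shared", index=presence.index)
    cats[n == presence.shape[1]] = "ubiquitous"
    cats[n == 1] = "private"
    truth_cats = truth.categories()
    keep = truth_cats != "absent"
    assert (cats[keep] == truth_cats[keep]).all()


def test_multiplicity_never_exceeds_major_copy_number():
    cfg = SimulationConfig(seed=9, driver_events=[])
    sites, segs, truth, _ = simulate_tumour(cfg)
    for rid, prof in segs.items():
        seg = prof.segments
        for row in sites.itertuples():
            m = truth.mutation_multiplicity.loc[row.mut_id, rid]
            state = prof.state_at(row.chrom, row.pos)
            assert m <= state["cn_major"]


class TestNormalPanel:
    def test_zero_artifact_rate_means_no_panel_hits(self):
        cfg = small_config(artifact_rate=0.0, error_rate=0.0)
        sites, _, _, _ = simulate_tumour(cfg)
        panel, artifacts = simulate_normal_panel(cfg, sites)
        assert artifacts == []
        assert (panel < 0.02).all().all()

    def test_artifact_prevalence_matches_binomial_expectation(self):
        """Prevalence 0.3 in a panel of 14 gives ~4.2 carriers per artifact."""
        cfg = small_config(
            clone_tree_spec=[(None, 400)], artifact_rate=0.5,
            artifact_prevalence=0.3, panel_size=14,
        )
        sites, _, _, _ = simulate_tumour(cfg)
        panel, artifacts = simulate_normal_panel(cfg, sites)
        carriers = (panel.loc[artifacts] >= 0.02).sum(axis=1)
        assert abs(carriers.mean() - 4.2) < 3 * np.sqrt(14 * 0.3 * 0.7 / len(artifacts))

    def test_full_prevalence_hits_every_normal(self):
        cfg = small_config(artifact_rate=0.1, artifact_prevalence=1.0)
        sites, _, _, _ = simulate_tumour(cfg)
        panel, artifacts = simulate_normal_panel(cfg, sites)
        assert (panel.loc[artifacts] >= 0.02).all().all()


class TestSampleContexts:
    def test_empirical_spectrum_converges_to_catalog_column(self):
        cat = synthetic_signature_catalog()
        draws = sample_contexts({"S6": 1.0}, cat, 100_000, seed=1)
        emp = pd.Series(draws).value_counts().reindex(CONTEXT_LABELS, fill_value=0)
        l1 = np.abs(emp / emp.sum() - cat["S6"]).sum()
        assert l1 < 0.02

    def test_two_signature_mixture_spectrum(self):
        cat = orthogonal_catalog(4)
        draws = sample_contexts({"O1": 0.6, "O2": 0.4}, cat, 100_000, seed=2)
        emp = pd.Series(draws).value_counts().reindex(CONTEXT_LABELS, fill_value=0)
        target = 0.6 * cat["O1"] + 0.4 * cat["O2"]
        assert np.abs(emp / emp.sum() - target).sum() < 0.02

    def test_zero_draws_gives_empty_list(self):
        assert sample_contexts({"S1": 1.0}, synthetic_signature_catalog(), 0) == []

    def test_unknown_signature_id_rejected(self):
        with pytest.raises(ValueError, match="unknown signature"):
            sample_contexts({"nope": 1.0}, synthetic_signature_catalog(), 10)


class TestConfigValidation:
    def test_multiple_roots_rejected(self):
        with pytest.raises(ValueError, match="exactly one root"):
            parse_clone_tree([(None, 5), (None, 5)], np.random.default_rng(0))

    def test_forward_reference_parent_rejected(self):
        with pytest.raises(ValueError, match="invalid parent"):
            parse_clone_tree([(None, 5), (2, 5), (1, 5)], np.random.default_rng(0))

    def test_random_tree_spec_parses(self):
        parents, counts = parse_clone_tree("random(5, 10-20)", np.random.default_rng(0))
        assert len(parents) == 5 and parents[0] is None
        assert all(10 <= c <= 20 for c in counts)

    def test_bad_purity_range_rejected(self):
        with pytest.raises(ValueError, match="purity_range"):
            simulate_tumour(small_config(purity_range=(0.0, 0.5)))

    def test_event_minor_above_major_rejected(self):
        cfg = small_config(
            cna_events=[{"clone": 0, "chrom": "1", "major": 1, "minor": 2,
                         "timing": "before_mutations"}]
        )
        with pytest.raises(ValueError, match="major >= minor"):
            simulate_tumour(cfg)
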