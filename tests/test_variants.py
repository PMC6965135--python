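"""Filtering thresholds, rejection reasons and categorisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mseqevo.catalogs import default_driver_catalog
from mseqevo.variants import (
    categorize_counts,
    classify_driver,
    cross_germline_filter,
    quality_filter,
    two_tier_call,
)

from conftest import make_sites


class TestQualityFilter:
    def test_tumour_depth_boundary_69_rejected_70_kept(self):
        sites = make_sites(
            [
                {"vafs": [0.3, 0.3, 0.3], "depths": [69, 200, 200]},
                {"vafs": [0.3, 0.3, 0.3], "depths": [70, 200, 200]},
            ]
        )
        kept, rejected = quality_filter(sites)
        assert list(kept["mut_id"]) == ["M0002"]
        assert rejected["reason"].tolist() == ["tumour_depth"]

    def test_germline_depth_boundary(self):
        sites = make_sites(
            [
                {"vafs": [0.3] * 3, "normal_depth": 19},
                {"vafs": [0.3] * 3, "normal_depth": 20},
            ]
        )
        kept, rejected = quality_filter(sites)
        assert list(kept["mut_id"]) == ["M0002"]
        assert rejected["reason"].tolist() == ["germline_depth"]

    def test_germline_evidence_requires_both_vaf_and_count(self):
        """Rejection needs germline VAF > 2% AND alt count > 2; either
        condition alone is not enough."""
        sites = make_sites(
            [
                {"vafs": [0.3] * 3, "normal_depth": 100, "normal_alt": 3},  # both
                {"vafs": [0.3] * 3, "normal_depth": 66, "normal_alt": 2},  # vaf only
                {"vafs": [0.3] * 3, "normal_depth": 200, "normal_alt": 3},  # count only
            ]
        )
        kept, rejected = quality_filter(sites)
        assert list(kept["mut_id"]) == ["M0002", "M0003"]
        assert rejected["reason"].tolist() == ["germline_evidence"]

    def test_sex_chromosomes_dropped_first(self):
        sites = make_sites(
            [{"chrom": "X", "vafs": [0.3] * 3, "depths": [10, 10, 10], "normal_depth": 5}]
        )
        _, rejected = quality_filter(sites)
        assert rejected["reason"].tolist() == ["sex_chromosome"]


class TestCrossGermlineFilter:
    def _panel(self, n_carriers, n_normals=14):
        vaf = np.zeros((1, n_normals))
        vaf[0, :n_carriers] = 0.05
        return pd.DataFrame(vaf, index=["M0001"], columns=[f"N{i}" for i in range(n_normals)])

    def test_three_of_fourteen_rejected(self):
        sites = make_sites([{"vafs": [0.3] * 3}])
        kept, rejected = cross_germline_filter(sites, self._panel(3))
        assert kept.empty and len(rejected) == 1

    def test_two_of_fourteen_retained(self):
        sites = make_sites([{"vafs": [0.3] * 3}])
        kept, _ = cross_germline_filter(sites, self._panel(2))
        assert len(kept) == 1

    def test_clean_panel_removes_nothing(self):
        sites = make_sites([{"vafs": [0.3] * 3}, {"vafs": [0.2] * 3}])
        kept, rejected = cross_germline_filter(sites, pd.DataFrame(
            np.zeros((2, 14)), index=sites.index, columns=[f"N{i}" for i in range(14)]
        ))
        assert len(kept) == 2 and rejected.empty

    def test_empty_panel_is_an_error(self):
        sites = make_sites([{"vafs": [0.3] * 3}])
        with pytest.raises(ValueError, match="panel is empty"):
            cross_germline_filter(sites, pd.DataFrame(index=sites.index))


class TestTwoTier:
    def test_shared_call_with_mixed_regional_vafs(self):
        pm = two_tier_call(make_sites([{"vafs": [0.06, 0.01, 0.03]}]))
        assert pm.presence.loc["M0001"].tolist() == [True, False, True]
        assert pm.category["M0001"] == "shared"

    def test_tier1_boundary_is_inclusive_at_5pct(self):
        pm = two_tier_call(make_sites([{"vafs": [0.05, 0.0, 0.0]}]))
        assert len(pm.sites) == 1

    def test_all_regions_below_tier1_rejected(self):
        pm = two_tier_call(make_sites([{"vafs": [0.04, 0.04, 0.04]}]))
        assert pm.sites.empty
        assert pm.rejected["reason"].tolist() == ["tier1_max_vaf"]

    def test_tier2_boundary_is_strict(self):
        """Presence requires VAF strictly above 2.5%."""
        pm = two_tier_call(
            make_sites([{"vafs": [0.30, 0.025, 0.026], "depths": [200, 1000, 1000]}])
        )
        assert pm.presence.loc["M0001"].tolist() == [True, False, True]

    def test_high_vaf_everywhere_is_ubiquitous(self):
        pm = two_tier_call(make_sites([{"vafs": [0.30, 0.28, 0.26]}]))
        assert pm.category["M0001"] == "ubiquitous"

    def test_single_region_call_is_private(self):
        pm = two_tier_call(make_sites([{"vafs": [0.30, 0.0, 0.0]}]))
        assert pm.category["M0001"] == "private"


def test_categorize_counts_matches_hand_count():
    pm = two_tier_call(
        make_sites(
            [
                {"vafs": [0.3, 0.3, 0.3]},
                {"vafs": [0.3, 0.3, 0.0]},
                {"vafs": [0.3, 0.0, 0.0]},
                {"vafs": [0.3, 0.3, 0.3], "consequence": "synonymous"},
            ]
        )
    )
    summary = categorize_counts(pm)
    assert summary["non_silent_total"] == 3
    assert summary["ubiquitous"] == 1
    assert summary["heterogeneous"] == 2
    assert summary["pct_heterogeneous"] == pytest.approx(200 / 3)


def test_categorize_counts_all_ubiquitous_has_no_heterogeneous():
    pm = two_tier_call(make_sites([{"vafs": [0.3] * 3}, {"vafs": [0.2] * 3}]))
    summary = categorize_counts(pm)
    assert summary["heterogeneous"] == 0


def test_categorize_counts_empty_matrix_is_all_zero():
    pm = two_tier_call(make_sites([{"vafs": [0.01] * 3}]))
    summary = categorize_counts(pm)
    assert summary["non_silent_total"] == 0 and summary["ubiquitous"] == 0


class TestDriverClassification:
    CATALOG = default_driver_catalog()

    def test_known_alteration_rule(self):
        sites = make_sites(
            [{"vafs": [0.3] * 3, "gene": "KRAS", "consequence": "missense",
              "protein_change": "G13D"}]
        )
        out = classify_driver(sites, self.CATALOG)
        assert out["likely_driver"].all()
        assert out["driver_rule"].tolist() == ["known_alteration"]

    def test_disrupting_mutation_in_tsg_rule(self):
        sites = make_sites(
            [{"vafs": [0.3] * 3, "gene": "B2M", "consequence": "frameshift",
              "protein_change": "L15fs"}]
        )
        out = classify_driver(sites, self.CATALOG)
        assert out["driver_rule"].tolist() == ["disrupting_in_tsg"]

    def test_known_position_with_novel_change_rule(self):
        sites = make_sites(
            [{"vafs": [0.3] * 3, "gene": "PIK3CA", "consequence": "missense",
              "protein_change": "H1047L"}]
        )
        out = classify_driver(sites, self.CATALOG)
        assert out["driver_rule"].tolist() == ["known_position"]

    def test_gene_absent_from_catalog_not_flagged(self):
        sites = make_sites(
            [{"vafs": [0.3] * 3, "gene": "G1_4", "consequence": "missense",
              "protein_change": "A5T"}]
        )
        assert not classify_driver(sites, self.CATALOG)["likely_driver"].any()

    def test_disrupting_in_oncogene_not_flagged_by_rule2(self):
        sites = make_sites(
            [{"vafs": [0.3] * 3, "gene": "KRAS", "consequence": "frameshift",
              "protein_change": "A77fs"}]
        )
        assert not classify_driver(sites, self.CATALOG)["likely_driver"].any()

    def test_unknown_consequence_vocabulary_rejected(self):
        sites = make_sites([{"vafs": [0.3] * 3, "consequence": "weird_term"}])
        with pytest.raises(ValueError, match="unknown consequence"):
            classify_driver(sites, self.CATALOG)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    tier2=st.floats(min_value=0.0, max_value=0.2),
    bump=st.floats(min_value=0.001, max_value=0.2),
)
def test_raising_tier2_never_increases_presence(tier2, bump):
    sites = make_sites(
        [{"vafs": [v1, v2, v3]} for v1 in (0.0, 0.03, 0.2) for v2 in (0.01, 0.26)
         for v3 in (0.0, 0.06)]
    )
    low = two_tier_call(sites, tier2_vaf=tier2).presence.to_numpy().sum()
    high = two_tier_call(sites, tier2_vaf=tier2 + bump).presence.to_numpy().sum()
    assert high <= low
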