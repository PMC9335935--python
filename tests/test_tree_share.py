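"""Gametolog calls, polarisation, and the 10-tree classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sdrkit.errors import ConfigurationError
from sdrkit.tree_share import (
    CHROMOSOMES,
    TREE_OF_PATTERN,
    TreeClassification,
    classify_tree,
    infer_gametolog_alleles,
    informative_filter,
    polarize,
    run_treeshare,
    summarize_hypotheses,
    GametologCall,
)
from sdrkit.variant_io import HET, HOM_ALT, HOM_REF, MISSING, GenotypeTable, SampleSheet

from conftest import treeshare_on_sex_chrom


class TestClassifierBijection:
    def test_ten_informative_subsets_six_rejections(self):
        """Brute-force enumeration of all 16 derived-allele subsets of
        {Xp, Yp, Xw, Yw}: exactly the 10 subsets of size 2–3 map to distinct
        trees; sizes 0, 1 and 4 are uninformative."""
        assigned = []
        uninformative = 0
        for r in range(5):
            for combo in itertools.combinations(CHROMOSOMES, r):
                pattern = frozenset(combo)
                if len(pattern) in (2, 3):
                    assigned.append(classify_tree(pattern))
                else:
                    uninformative += 1
                    with pytest.raises(ValueError):
                        classify_tree(pattern)
        assert sorted(assigned) == list(range(1, 11))
        assert uninformative == 6

    @pytest.mark.parametrize(
        "pattern, tree",
        [
            ({"Yp", "Yw"}, 1),
            ({"Xp", "Xw"}, 2),
            ({"Xp", "Yp"}, 3),
            ({"Xw", "Yw"}, 4),
            ({"Xp", "Xw", "Yw"}, 5),
            ({"Yp", "Xw", "Yw"}, 7),
        ],
    )
    def test_documented_assignments(self, pattern, tree):
        assert classify_tree(frozenset(pattern)) == tree


class TestGametologCalls:
    def test_females_hom_males_het(self):
        call = infer_gametolog_alleles([HET, HET, HET], [HOM_REF, HOM_REF])
        assert (call.x_allele, call.y_allele) == ("ref", "alt")

    def test_males_share_female_homozygote(self):
        call = infer_gametolog_alleles([HOM_REF, HOM_REF], [HOM_REF, HOM_REF])
        assert (call.x_allele, call.y_allele) == ("ref", "ref")

    def test_polymorphic_females_rejected(self):
        call = infer_gametolog_alleles([HET, HET], [HOM_REF, HET])
        assert call.rejected and call.reason == "female_polymorphic"

    def test_males_opposite_homozygote_rejected(self):
        call = infer_gametolog_alleles([HOM_ALT, HOM_ALT], [HOM_REF, HOM_REF])
        assert call.rejected and call.reason == "males_opposite_homozygote"

    def test_mixed_males_rejected(self):
        call = infer_gametolog_alleles([HET, HOM_REF], [HOM_REF, HOM_REF])
        assert call.rejected and call.reason == "males_mixed"

    def test_insufficient_samples(self):
        call = infer_gametolog_alleles([HET, MISSING], [HOM_REF, HOM_REF])
        assert call.rejected and call.reason == "insufficient_samples"


class TestPolarize:
    def test_agreeing_outgroups(self):
        anc, reason = polarize({"latipinna": [HOM_REF], "holbrooki": [HOM_REF]})
        assert anc == "ref" and reason is None

    def test_disagreeing_outgroups_rejected(self):
        anc, reason = polarize({"latipinna": [HOM_REF], "holbrooki": [HOM_ALT]})
        assert anc is None and reason == "outgroup_disagree"

    def test_heterozygous_outgroup_rejected(self):
        anc, reason = polarize({"latipinna": [HET], "holbrooki": [HOM_REF]})
        assert anc is None and reason == "outgroup_het"

    def test_uncalled_outgroup_species_rejected(self):
        anc, reason = polarize({"latipinna": [MISSING], "holbrooki": [HOM_ALT]})
        assert anc is None and reason == "insufficient_outgroup"


class TestInformativeFilter:
    def _call(self, sp, x, y):
        return GametologCall(sp, x, y)

    def test_picta_private_derived_pair(self):
        pattern, reason = informative_filter(
            self._call("picta", "alt", "alt"), self._call("wingei", "ref", "ref"), "ref"
        )
        assert pattern == frozenset({"Xp", "Yp"}) and reason is None
        assert classify_tree(pattern) == 3

    def test_derived_on_all_four_uninformative(self):
        pattern, reason = informative_filter(
            self._call("picta", "alt", "alt"), self._call("wingei", "alt", "alt"), "ref"
        )
        assert pattern is None and reason == "derived_on_all"

    def test_single_chromosome_uninformative(self):
        pattern, reason = informative_filter(
            self._call("picta", "ref", "ref"), self._call("wingei", "ref", "alt"), "ref"
        )
        assert pattern is None and reason == "derived_singleton"

    def test_upstream_rejection_propagates(self):
        rejected = GametologCall("picta", None, None, True, "female_polymorphic")
        pattern, reason = informative_filter(rejected, self._call("wingei", "ref", "alt"), "ref")
        assert pattern is None and reason == "picta:female_polymorphic"


def _cohort_table(rows):
    """Table with 2 picta M/F, 2 wingei M/F, 1 latipinna, 1 holbrooki.

    ``rows`` is a list of 10-genotype lists in that sample order.
    """
    ids = ["p_M1", "p_M2", "p_F1", "p_F2", "w_M1", "w_M2", "w_F1", "w_F2", "lat_1", "hol_1"]
    sheet = SampleSheet.from_records(
        [
            ("p_M1", "picta", "M"),
            ("p_M2", "picta", "M"),
            ("p_F1", "picta", "F"),
            ("p_F2", "picta", "F"),
            ("w_M1", "wingei", "M"),
            ("w_M2", "wingei", "M"),
            ("w_F1", "wingei", "F"),
            ("w_F2", "wingei", "F"),
            ("lat_1", "latipinna", "unknown"),
            ("hol_1", "holbrooki", "unknown"),
        ]
    )
    g = np.array(rows, dtype=np.int8)
    sites = pd.DataFrame(
        {
            "chrom": ["chr12"] * len(rows),
            "pos": np.arange(1, len(rows) + 1) * 10,
            "ref": ["A"] * len(rows),
            "alt": ["T"] * len(rows),
            "qual": 60.0,
            "is_snp": True,
            "is_biallelic": True,
            "is_indel": False,
        }
    )
    return GenotypeTable(ids, sites, g, np.full_like(g, 30, dtype=np.int32)), sheet


class TestRunTreeshare:
    def test_hand_built_rejection_reasons(self):
        R, H, A, M = HOM_REF, HET, HOM_ALT, MISSING
        rows = [
            #  pM1 pM2 pF1 pF2 wM1 wM2 wF1 wF2 lat hol
            [H, H, R, R, R, R, R, R, R, R],      # derived alt on Yp only -> singleton pattern
            [A, A, A, A, R, R, R, R, R, R],      # derived fixed on Xp,Yp -> tree 3
            [R, R, R, R, A, A, A, A, R, R],      # derived fixed on Xw,Yw -> tree 4
            [H, R, R, R, R, R, R, R, R, R],      # mixed picta males
            [H, H, H, R, R, R, R, R, R, R],      # polymorphic picta females
            [A, A, A, A, A, A, A, A, H, R],      # outgroup heterozygote
            [A, A, A, A, A, A, A, A, R, R],      # derived fixed on all four chromosomes
            [M, M, R, R, R, R, R, R, R, R],      # insufficient picta males
        ]
        gt, sheet = _cohort_table(rows)
        tc = run_treeshare(gt, sheet, focal=("picta", "wingei"))
        assert tc.counts == {3: 1, 4: 1}
        assert tc.uninformative["derived_singleton"] == 1
        assert tc.uninformative["picta:males_mixed"] == 1
        assert tc.uninformative["picta:female_polymorphic"] == 1
        assert tc.uninformative["outgroup:outgroup_het"] == 1
        assert tc.uninformative["derived_on_all"] == 1
        assert tc.uninformative["picta:insufficient_samples"] == 1
        assert tc.n_informative == 2 and tc.n_sites == 8

    def test_sample_minima_enforced(self):
        gt, sheet = _cohort_table([[HOM_REF] * 10])
        small = sheet.table[sheet.table["sample_id"] != "p_M2"]
        with pytest.raises(ConfigurationError):
            run_treeshare(gt.subset_samples(small["sample_id"].tolist()), SampleSheet(small))

    def test_homologous_recovery_only_trees_1_2(self, homologous_sim):
        tc = treeshare_on_sex_chrom(homologous_sim)
        assert set(tc.counts) <= {1, 2}
        truth = homologous_sim.truth
        expected = truth[truth["expected"].isin(["1", "2"])]["expected"].astype(int)
        assert tc.counts == expected.value_counts().to_dict()

    def test_independent_recovery_only_trees_3_4(self, independent_sim):
        tc = treeshare_on_sex_chrom(independent_sim)
        assert set(tc.counts) <= {3, 4}

    def test_y_stem_vs_x_stem_split_is_binomial(self, homologous_sim):
        """Equal Y-stem and X-stem lengths put trees 1 and 2 at 50:50 within
        3 binomial σ."""
        tc = treeshare_on_sex_chrom(homologous_sim)
        n = tc.n_informative
        assert n >= 2000
        assert abs(tc.counts[1] / n - 0.5) <= 3 * np.sqrt(0.25 / n)


class TestSummarize:
    def _tc(self, counts, n_sites=1000):
        per_site = pd.DataFrame(columns=["chrom", "pos", "pattern", "tree_id", "reason"])
        from collections import Counter

        return TreeClassification(per_site, counts, Counter(), n_sites)

    def test_independent_verdict(self):
        s = summarize_hypotheses(self._tc({3: 270, 4: 100}))
        assert s.verdict == "independent"

    def test_homologous_boundary(self):
        s = summarize_hypotheses(self._tc({1: 50, 2: 50}))
        assert s.verdict == "homologous"

    def test_sparse_counts_ambiguous(self):
        s = summarize_hypotheses(self._tc({9: 5}))
        assert s.verdict == "ambiguous"

    def test_turnover_flagged_when_tree5_exceeds_homoplasy(self):
        s = summarize_hypotheses(self._tc({4: 300, 5: 200, 9: 2, 10: 1}))
        assert s.verdict == "turnover_wingei"

    def test_zero_informative_warns(self):
        with pytest.warns(UserWarning):
            s = summarize_hypotheses(self._tc({}))
        assert s.verdict == "ambiguous"
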