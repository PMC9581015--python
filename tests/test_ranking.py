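"""Physicochemical features, reference statistics, scoring and ranking."""

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from centerscan.ranking import (
    FEATURE_NAMES,
    FeatureVector,
    classify_score,
    compute_features,
    hydropathy_scale,
    rank_hits,
    reference_stats,
    residue_masses,
    score_hit,
)
from centerscan.scanner import HitReport


class TestComputeFeatures:
    def test_glycine_mass_from_table(self):
        assert compute_features("G").molecular_weight == pytest.approx(
            residue_masses()["G"]
        )

    def test_isoleucine_tops_hydropathy_scale(self):
        scale = hydropathy_scale()
        assert compute_features("I").gravy == pytest.approx(max(scale.values()))
        assert compute_features("I").gravy == pytest.approx(scale["I"])

    def test_pi_ordering_acidic_vs_basic(self):
        assert compute_features("DD").isoelectric_point < 7
        assert compute_features("KK").isoelectric_point > 7

    def test_ambiguity_codes_excluded_from_averages(self):
        assert compute_features("AXA") == compute_features("AA")

    @pytest.mark.parametrize("bad", ["", "XXX", "A1C"])
    def test_degenerate_fragments_rejected(self, bad):
        with pytest.raises(ValueError):
            compute_features(bad)

    @pytest.mark.parametrize(
        "frag",
        ["KACAAAAAAAAAAK", "GAVLIWY", "DDEEKKRRHH", "MSTNPKPQRKTKRNT"],
    )
    def test_against_protparam_oracle(self, frag):
        """Independent cross-check against Biopython's ProtParam."""
        f = compute_features(frag)
        pa = ProteinAnalysis(frag)
        assert f.molecular_weight == pytest.approx(pa.molecular_weight(), abs=0.01)
        assert f.gravy == pytest.approx(pa.gravy(), abs=1e-6)
        # different pKa sets; agreement is loose by nature
        assert f.isoelectric_point == pytest.approx(pa.isoelectric_point(), abs=1.2)

    def test_net_charge_sign_at_ph7(self):
        assert compute_features("KKKK").net_charge_ph7 > 0
        assert compute_features("DDDD").net_charge_ph7 < 0


class TestReferenceStats:
    def test_single_fragment_floored_sd(self):
        ref = reference_stats(["KACAAAAAAAAAAK"])
        f = compute_features("KACAAAAAAAAAAK")
        for name in FEATURE_NAMES:
            assert ref.means[name] == pytest.approx(f.get(name))
            assert 0 < ref.sds[name] <= 1e-6 * abs(ref.means[name]) + 1e-9

    def test_identical_fragments_floored_sd(self):
        ref = reference_stats(["GAVLIWY", "GAVLIWY"])
        assert all(ref.sds[n] < 1e-3 for n in FEATURE_NAMES)

    def test_means_match_independent_recomputation(self):
        frags = [
            "KACAAAAAAAAAAK", "SGSAAAAAAAAAAR", "KTGAAAAAAAAAAK",
            "SACDEFGHIKLMNK", "KPCAAAAAGGGGGR",
        ]
        ref = reference_stats(frags)
        table = np.array(
            [[compute_features(f).get(n) for n in FEATURE_NAMES] for f in frags]
        )
        for j, name in enumerate(FEATURE_NAMES):
            assert ref.means[name] == pytest.approx(table[:, j].mean())
            assert ref.sds[name] == pytest.approx(
                max(table[:, j].std(), 1e-6 * abs(table[:, j].mean()) + 1e-9)
            )

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            reference_stats([])


def make_ref():
    return reference_stats(
        ["KACAAAAAAAAAAK", "SGSAAAAAAAAAAR", "KTGAAAAAAAAAAK",
         "SACDEFGHIKLMNK", "KPCAAAAAGGGGGR"]
    )


class TestScoreHit:
    def test_features_at_mean_score_one_and_select(self):
        ref = make_ref()
        f = FeatureVector(
            molecular_weight=ref.means["molecular_weight"],
            isoelectric_point=ref.means["isoelectric_point"],
            gravy=ref.means["gravy"],
            net_charge_ph7=0.0,
        )
        sc = score_hit(f, ref)
        assert sc.overall == pytest.approx(1.0)
        assert all(v == pytest.approx(1.0) for v in sc.feature_scores.values())
        assert sc.selected

    def test_three_sigma_deviation_scores_zero_red(self):
        ref = make_ref()
        f = FeatureVector(
            molecular_weight=ref.means["molecular_weight"]
            + 3 * ref.sds["molecular_weight"],
            isoelectric_point=ref.means["isoelectric_point"],
            gravy=ref.means["gravy"],
            net_charge_ph7=0.0,
        )
        sc = score_hit(f, ref, c=3.0)
        assert sc.feature_scores["molecular_weight"] == pytest.approx(0.0)
        assert sc.feature_classes["molecular_weight"] == "red"
        assert not sc.selected

    def test_symmetric_deviations_score_equally(self):
        ref = make_ref()
        delta = 1.7 * ref.sds["gravy"]
        up = FeatureVector(
            ref.means["molecular_weight"], ref.means["isoelectric_point"],
            ref.means["gravy"] + delta, 0.0,
        )
        down = FeatureVector(
            ref.means["molecular_weight"], ref.means["isoelectric_point"],
            ref.means["gravy"] - delta, 0.0,
        )
        assert score_hit(up, ref).feature_scores == pytest.approx(
            score_hit(down, ref).feature_scores
        )

    def test_invalid_spread_rejected(self):
        with pytest.raises(ValueError):
            score_hit(compute_features("AAA"), make_ref(), c=0)

    @given(
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=-10, max_value=10),
        st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_scores_bounded_and_monotone(self, z_mw, z_pi, z_gr):
        """Every score lies in [0,1] and shrinks as |x - mean| grows."""
        ref = make_ref()
        f = FeatureVector(
            ref.means["molecular_weight"] + z_mw * ref.sds["molecular_weight"],
            ref.means["isoelectric_point"] + z_pi * ref.sds["isoelectric_point"],
            ref.means["gravy"] + z_gr * ref.sds["gravy"],
            0.0,
        )
        sc = score_hit(f, ref)
        assert all(0.0 <= v <= 1.0 for v in sc.feature_scores.values())
        assert 0.0 <= sc.overall <= 1.0
        further = FeatureVector(
            ref.means["molecular_weight"] + 2 * z_mw * ref.sds["molecular_weight"],
            f.isoelectric_point,
            f.gravy,
            0.0,
        )
        sc2 = score_hit(further, ref)
        assert (
            sc2.feature_scores["molecular_weight"]
            <= sc.feature_scores["molecular_weight"] + 1e-12
        )

    def test_selection_rule_enforced_verbatim(self):
        """Selected iff green overall AND >=2 green features AND no red."""
        ref = make_ref()
        mu = ref.means
        sd = ref.sds

        def fv(z_mw, z_pi, z_gr):
            return FeatureVector(
                mu["molecular_weight"] + z_mw * sd["molecular_weight"],
                mu["isoelectric_point"] + z_pi * sd["isoelectric_point"],
                mu["gravy"] + z_gr * sd["gravy"],
                0.0,
            )

        for zs in [
            (0, 0, 0), (0, 0, 1.5), (0, 0, 3.5), (0, 1.5, 1.5),
            (1.5, 1.5, 1.5), (0, 0, 2.5), (2.5, 2.5, 0), (3.5, 0, 0),
        ]:
            sc = score_hit(fv(*zs), ref)
            greens = sum(1 for v in sc.feature_classes.values() if v == "green")
            reds = sum(1 for v in sc.feature_classes.values() if v == "red")
            expected = sc.overall_class == "green" and greens >= 2 and reds == 0
            assert sc.selected == expected

    def test_reference_pool_outscores_shifted_fragments(self):
        """In-pool fragments rank above composition-shifted ones."""
        ref = make_ref()
        in_pool = score_hit(compute_features("KACAAAAAAAAAAK"), ref).overall
        shifted = score_hit(compute_features("WWWWWWWWWWWWWW"), ref).overall
        assert in_pool > shifted


class TestRankHits:
    def hit(self, seq_id, start, overall=None, greens=3, selected=None):
        scores = None
        if overall is not None:
            classes = {
                n: ("green" if i < greens else "amber")
                for i, n in enumerate(FEATURE_NAMES)
            }
            n_red = sum(1 for v in classes.values() if v == "red")
            sel = (
                selected
                if selected is not None
                else (overall >= 0.6 and greens >= 2 and n_red == 0)
            )
            from centerscan.ranking import ScoreCard

            scores = ScoreCard(
                feature_scores={n: overall for n in FEATURE_NAMES},
                feature_classes=classes,
                overall=overall,
                overall_class=classify_score(overall),
                selected=sel,
            )
        return HitReport(
            seq_id=seq_id, motif_id="GC", center_class="GC",
            start=start, end=start + 13, matched_text="A" * 14, scores=scores,
        )

    def test_higher_overall_first(self):
        lo, hi = self.hit("a", 1, 0.4), self.hit("b", 1, 0.9)
        assert rank_hits([lo, hi]) == [hi, lo]

    def test_green_count_breaks_ties(self):
        two = self.hit("a", 1, 0.7, greens=2)
        three = self.hit("b", 1, 0.7, greens=3)
        assert rank_hits([two, three]) == [three, two]

    def test_full_tie_falls_back_to_seq_id(self):
        b = self.hit("b", 1, 0.7)
        a = self.hit("a", 1, 0.7)
        assert rank_hits([b, a]) == [a, b]

    def test_unscored_hits_sort_last(self):
        scored = self.hit("z", 1, 0.2)
        bare = self.hit("a", 1, None)
        assert rank_hits([bare, scored]) == [scored, bare]
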