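"""Interpretation layer: filtering, copy-number arithmetic, CIN, concordance."""

import itertools

import pandas as pd
import pytest

import cfcna as cf
from cfcna.calls import (FLAG_AMPLIFICATION, FLAG_CANCER_ASSOCIATED,
                         FLAG_LIKELY_GERMLINE, FLAG_TISSUE_VERIFIED, CnaCall)
from cfcna.hmm import TumourFractionEstimate
from cfcna.interpret import (concordance_group, flag_likely_germline,
                             summarize_patient)


def call(chrom="1", start=0, end=10_000_000, direction="gain", es=0.05,
         n_bins=20, caller="wc", score=6.0):
    return CnaCall(chrom=chrom, start=start, end=end, direction=direction,
                   score=score, effect_size=es, n_bins=n_bins, caller=caller)


class TestFilterCalls:
    def test_chromosome_19_removed(self):
        kept = cf.filter_calls([call(chrom="19"), call(chrom="5")])
        assert [c.chrom for c in kept] == ["5"]
        assert FLAG_CANCER_ASSOCIATED in kept[0].flags

    def test_subthreshold_effect_removed(self):
        assert cf.filter_calls([call(es=0.014)]) == []
        assert len(cf.filter_calls([call(es=0.015)])) == 1

    def test_blacklisted_call_removed(self):
        bl = pd.DataFrame([("1", 0, 50_000_000)],
                          columns=["chrom", "start", "end"])
        assert cf.filter_calls([call()], blacklist=bl) == []
        far = call(chrom="2")
        assert cf.filter_calls([far], blacklist=bl) == [far]

    def test_filter_order_independent(self):
        bl = pd.DataFrame([("3", 0, 20_000_000)],
                          columns=["chrom", "start", "end"])
        calls = [call(chrom="19"), call(chrom="3"), call(chrom="4", es=0.01),
                 call(chrom="5", es=0.3), call(chrom="X")]
        filters = {
            "chrom": dict(blacklist=None, es_min=0.0),
            "es": dict(blacklist=None, excluded_chromosomes=set(),
                       es_min=0.015),
            "bl": dict(blacklist=bl, excluded_chromosomes=set(), es_min=0.0),
        }
        reference = None
        for order in itertools.permutations(filters):
            out = [call(chrom="19"), call(chrom="3"), call(chrom="4", es=0.01),
                   call(chrom="5", es=0.3), call(chrom="X")]
            for name in order:
                out = cf.filter_calls(out, **filters[name])
            key = sorted((c.chrom, c.start) for c in out)
            reference = key if reference is None else reference
            assert key == reference


class TestCopyNumberArithmetic:
    def test_printed_calibration_point(self):
        assert cf.estimate_copy_number(0.045, 0.03) == pytest.approx(5.0)

    def test_extreme_amplification_magnitude(self):
        c = cf.estimate_copy_number(0.88, 0.035)
        assert c >= 50
        assert c == pytest.approx(2 + 2 * 0.88 / 0.035)

    def test_zero_effect_is_diploid(self):
        assert cf.estimate_copy_number(0.0, 0.05) == pytest.approx(2.0)

    def test_undefined_fraction_not_evaluable(self):
        undefined = TumourFractionEstimate(0.0, False)
        assert cf.estimate_copy_number(0.1, undefined) is None


class TestClassifyAmplification:
    def test_high_ratio_is_amplification(self):
        # effect 21% at fraction 8.4% -> ratio 2.5
        assert cf.classify_amplification(0.21, 0.084) == "amplification"

    def test_low_ratio_is_gain(self):
        assert cf.classify_amplification(0.02, 0.05) == "gain"

    def test_fallback_effect_size_rule(self):
        undefined = TumourFractionEstimate(0.0, False)
        assert cf.classify_amplification(0.05, undefined) == "amplification"
        assert cf.classify_amplification(0.045, undefined) == "gain"

    def test_negative_effect_is_loss(self):
        assert cf.classify_amplification(-0.08, 0.05) == "loss"

    def test_boundary_coherent_with_copy_number_five(self):
        # ratio exactly 1.5 <=> copy number exactly 5: amplification
        # (0.375 and 0.25 are float-exact, so the ratio is exactly 1.5)
        assert cf.classify_amplification(0.375, 0.25) == "amplification"
        assert cf.estimate_copy_number(0.375, 0.25) == 5.0


class TestCin:
    def test_ten_chromosomes_is_cin(self):
        calls = [call(chrom=str(i)) for i in range(1, 11)]
        assert cf.classify_cin(calls) is True

    def test_nine_chromosomes_is_not(self):
        calls = [call(chrom=str(i)) for i in range(1, 10)]
        assert cf.classify_cin(calls) is False

    def test_multiple_calls_same_chromosome_count_once(self):
        calls = [call(chrom="1", start=s, end=s + 10) for s in range(0, 120, 10)]
        assert cf.classify_cin(calls) is False

    def test_no_calls_not_cin(self):
        assert cf.classify_cin([]) is False


class TestConfidence:
    @pytest.mark.parametrize("caller,length,es,expected", [
        ("wc", 40e6, 0.04, "high"),
        ("wc", 10e6, 0.06, "high"),
        ("wc", 10e6, 0.02, "low"),
        ("wc", 3e6, 0.06, "low"),    # below the 5 Mb small-call floor
        ("hmm", 10e6, 0.06, "high"),
        ("hmm", 3e6, 0.06, "high"),  # hmm small-call floor is 2 Mb
        ("hmm", 40e6, 0.02, "low"),
    ])
    def test_empirical_tiers(self, caller, length, es, expected):
        c = call(end=int(length), es=es, caller=caller)
        assert cf.classify_confidence(c) == expected


class TestTissueConcordance:
    def _tissue(self, rows):
        df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                         "direction", "amplification"])
        return cf.TissueCallSet(patient_id="P", intervals=df)

    def test_plasma_gain_inside_tissue_gain_verified(self):
        plasma = [call(chrom="8", start=1_000_000, end=2_000_000)]
        tissue = self._tissue([("8", 0, 5_000_000, "gain", False)])
        verified, group = cf.verify_against_tissue(plasma, tissue)
        assert FLAG_TISSUE_VERIFIED in verified[0].flags
        assert group == "TP"

    def test_direction_mismatch_not_verified(self):
        plasma = [call(chrom="8", direction="loss", es=-0.05)]
        tissue = self._tissue([("8", 0, 50_000_000, "gain", False)])
        verified, group = cf.verify_against_tissue(plasma, tissue)
        assert FLAG_TISSUE_VERIFIED not in verified[0].flags
        assert group == "TP"  # both compartments have calls

    def test_plasma_only_is_group_p(self):
        plasma = [call()]
        tissue = self._tissue([])
        _, group = cf.verify_against_tissue(plasma, tissue)
        assert group == "P"

    def test_both_empty_is_group_n(self):
        _, group = cf.verify_against_tissue([], self._tissue([]))
        assert group == "N"

    def test_groups_partition_all_flag_combinations(self):
        seen = {concordance_group(t, p)
                for t in (True, False) for p in (True, False)}
        assert seen == {"TP", "T", "P", "N"}


class TestActionableAnnotation:
    def test_amplification_over_vegfa_annotated(self):
        genes = cf.interpret.load_actionable_genes()
        amp = call(chrom="6", start=43_000_000, end=44_500_000)
        amp.flags.add(FLAG_AMPLIFICATION)
        out = cf.annotate_actionable([amp], genes)
        assert out[0].genes == ("VEGFA",)

    def test_plain_gain_not_annotated(self):
        genes = cf.interpret.load_actionable_genes()
        gain = call(chrom="6", start=43_000_000, end=44_500_000)
        out = cf.annotate_actionable([gain], genes)
        assert out[0].genes == ()

    def test_empty_gene_list_is_noop(self):
        amp = call()
        amp.flags.add(FLAG_AMPLIFICATION)
        assert cf.annotate_actionable([amp], pd.DataFrame()) == [amp]


class TestGermlineFlag:
    def test_short_strong_call_flagged_never_deleted(self):
        short_strong = call(end=300_000, n_bins=3, es=0.30)
        long_strong = call(end=50_000_000, n_bins=100, es=0.30)
        out = flag_likely_germline([short_strong, long_strong])
        assert FLAG_LIKELY_GERMLINE in out[0].flags
        assert FLAG_LIKELY_GERMLINE not in out[1].flags
        assert len(out) == 2


class TestSummaries:
    def test_single_patient_no_calls(self):
        s = summarize_patient("P99", [], [],
                              TumourFractionEstimate(0.0, False))
        report = cf.summarize_cohort([s])
        assert report["n_patients"] == 1
        assert report["plasma_positive"] == 0
        assert report["cin"] == 0
        assert report["groups"]["N"] == 1

    def test_amplification_flag_set_from_fraction(self):
        amp = call(chrom="6", es=0.21)
        s = summarize_patient("P01", [amp], [],
                              TumourFractionEstimate(0.084, True))
        assert FLAG_AMPLIFICATION in amp.flags
        assert s.wc and not s.hmm
        assert s.group == "P"
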