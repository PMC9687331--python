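"""Case definitions: blood-contamination rule, composite reference standard
and the Ig response-pattern taxonomy."""

import pytest
from hypothesis import given, settings, strategies as st

from csfscreen import (
    Analyte,
    OCBStatus,
    ResponsePattern,
    SerumReferenceRange,
    build_profile,
    classify_response_pattern,
    classify_sample,
    detect_blood_contamination,
)
from csfscreen.errors import IndeterminateReferenceStandardError
from conftest import make_sample, sample_with_ifs


def classify(sample):
    return classify_sample(sample, build_profile(sample))


class TestBloodContaminationRule:
    def test_full_pattern_fires(self):
        sample = sample_with_ifs(
            {Analyte.IGM: 40.0, Analyte.IGA: 20.0, Analyte.IGG: 5.0},
            erythrocytes_csf=600,
        )
        assert detect_blood_contamination(sample, build_profile(sample))

    def test_erythrocytes_below_threshold_blocks(self):
        sample = sample_with_ifs(
            {Analyte.IGM: 40.0, Analyte.IGA: 20.0, Analyte.IGG: 5.0},
            erythrocytes_csf=100,
        )
        assert not detect_blood_contamination(sample, build_profile(sample))

    def test_erythrocytes_exactly_at_threshold_blocks(self):
        sample = sample_with_ifs(
            {Analyte.IGM: 40.0, Analyte.IGA: 20.0, Analyte.IGG: 5.0},
            erythrocytes_csf=500,
        )
        assert not detect_blood_contamination(sample, build_profile(sample))

    def test_ordering_violation_blocks(self):
        sample = sample_with_ifs(
            {Analyte.IGM: 10.0, Analyte.IGA: 25.0, Analyte.IGG: 5.0},
            erythrocytes_csf=600,
        )
        assert not detect_blood_contamination(sample, build_profile(sample))

    def test_unmeasured_iga_does_not_block(self):
        # the ordering chain is evaluated over the participating analytes only
        sample = sample_with_ifs(
            {Analyte.IGM: 40.0, Analyte.IGG: 5.0}, erythrocytes_csf=600
        )
        assert detect_blood_contamination(sample, build_profile(sample))

    def test_if_negative_iga_does_not_block(self):
        sample = sample_with_ifs(
            {Analyte.IGM: 40.0, Analyte.IGA: -20.0, Analyte.IGG: 5.0},
            erythrocytes_csf=600,
        )
        assert detect_blood_contamination(sample, build_profile(sample))

    def test_igm_negative_blocks(self):
        sample = sample_with_ifs(
            {Analyte.IGM: -10.0, Analyte.IGA: 20.0, Analyte.IGG: 5.0},
            erythrocytes_csf=600,
        )
        assert not detect_blood_contamination(sample, build_profile(sample))

    def test_missing_igm_returns_false_with_note_not_exception(self):
        sample = sample_with_ifs({Analyte.IGG: 30.0}, erythrocytes_csf=600)
        profile = build_profile(sample)
        assert detect_blood_contamination(sample, profile) is False
        result = classify_sample(sample, profile)
        assert any("not evaluable" in note for note in result.rationale)

    @settings(derandomize=True, max_examples=100)
    @given(
        ec=st.integers(min_value=0, max_value=500),
        if_igm=st.floats(min_value=-90, max_value=90),
        if_iga=st.floats(min_value=-90, max_value=90),
        if_igg=st.floats(min_value=-90, max_value=90),
    )
    def test_never_fires_at_or_below_threshold(self, ec, if_igm, if_iga, if_igg):
        sample = sample_with_ifs(
            {Analyte.IGM: if_igm, Analyte.IGA: if_iga, Analyte.IGG: if_igg},
            erythrocytes_csf=ec,
        )
        assert not detect_blood_contamination(sample, build_profile(sample))


class TestClassifySample:
    def test_quantitative_igg_synthesis_is_a_response(self):
        result = classify(sample_with_ifs({Analyte.IGG: 12.0}, erythrocytes_csf=2))
        assert result.immune_response
        assert result.synthesis_flags[Analyte.IGG]
        assert not result.ocb_positive

    def test_all_negative_is_no_response(self):
        result = classify(
            sample_with_ifs(
                {Analyte.IGG: -20.0, Analyte.IGA: -30.0, Analyte.IGM: -10.0}
            )
        )
        assert not result.immune_response

    def test_if_exactly_zero_is_no_synthesis(self):
        # positivity is strict: a quotient exactly on the line is negative
        import dataclasses

        from csfscreen import classify_sample as _classify

        sample = sample_with_ifs({Analyte.IGG: -5.0})
        profile = build_profile(sample)
        on_line = dataclasses.replace(
            profile,
            intrathecal_fraction={**profile.intrathecal_fraction, Analyte.IGG: 0.0},
        )
        result = _classify(sample, on_line)
        assert not result.synthesis_flags[Analyte.IGG]
        assert not result.immune_response

    def test_contamination_discounts_quantitative_synthesis(self):
        result = classify(
            sample_with_ifs(
                {Analyte.IGM: 30.0, Analyte.IGA: 15.0, Analyte.IGG: 4.0},
                erythrocytes_csf=800,
            )
        )
        assert result.blood_contamination
        assert not result.immune_response

    def test_ocb_still_counts_under_contamination(self):
        result = classify(
            sample_with_ifs(
                {Analyte.IGM: 30.0, Analyte.IGA: 15.0, Analyte.IGG: 4.0},
                erythrocytes_csf=800,
                ocb_status=OCBStatus.CSF_SPECIFIC_POSITIVE,
            )
        )
        assert result.blood_contamination
        assert result.immune_response

    def test_ocb_alone_is_a_response(self):
        result = classify(
            sample_with_ifs(
                {Analyte.IGG: -20.0, Analyte.IGA: -30.0, Analyte.IGM: -10.0},
                ocb_status=OCBStatus.CSF_SPECIFIC_POSITIVE,
            )
        )
        assert result.immune_response

    def test_flck_synthesis_alone_is_not_a_response(self):
        # FLCkappa is the index test, not part of the reference standard
        result = classify(
            sample_with_ifs(
                {Analyte.IGG: -20.0, Analyte.IGA: -30.0, Analyte.IGM: -10.0,
                 Analyte.FLCK: 40.0}
            )
        )
        assert result.flck_synthesis
        assert not result.immune_response

    def test_indeterminate_reference_standard(self):
        sample = make_sample(
            igg_csf=None, igg_serum=None, iga_csf=None, iga_serum=None,
            igm_csf=None, igm_serum=None, ocb_status=OCBStatus.NOT_DONE,
        )
        with pytest.raises(IndeterminateReferenceStandardError):
            classify(sample)

    def test_ocb_not_done_with_igs_measured_is_determinate(self):
        result = classify(
            sample_with_ifs({Analyte.IGG: 12.0}, ocb_status=OCBStatus.NOT_DONE)
        )
        assert result.immune_response

    def test_serum_flck_elevation_flag(self):
        elevated = classify(sample_with_ifs({}, flck_serum=30.0))
        normal = classify(sample_with_ifs({}))
        boundary = classify_sample(
            sample_with_ifs({}, flck_serum=22.4),
            build_profile(sample_with_ifs({}, flck_serum=22.4)),
            SerumReferenceRange(),
        )
        assert elevated.serum_flck_elevated
        assert not normal.serum_flck_elevated
        assert not boundary.serum_flck_elevated  # strictly above the bound

    def test_determinism(self):
        sample = sample_with_ifs({Analyte.IGG: 12.0, Analyte.IGM: 3.0})
        profile = build_profile(sample)
        assert classify_sample(sample, profile) == classify_sample(sample, profile)


class TestResponsePattern:
    @pytest.mark.parametrize(
        "ifs, expected",
        [
            ({Analyte.IGG: -1.0, Analyte.IGA: -1.0, Analyte.IGM: -1.0}, ResponsePattern.NONE),
            ({Analyte.IGG: 5.0, Analyte.IGA: -1.0, Analyte.IGM: -1.0}, ResponsePattern.IGG),
            ({Analyte.IGG: -1.0, Analyte.IGA: 5.0, Analyte.IGM: -1.0}, ResponsePattern.IGA),
            ({Analyte.IGG: -1.0, Analyte.IGA: -1.0, Analyte.IGM: 5.0}, ResponsePattern.IGM),
            ({Analyte.IGG: 5.0, Analyte.IGA: -1.0, Analyte.IGM: 5.0}, ResponsePattern.IGG_M),
            ({Analyte.IGG: -1.0, Analyte.IGA: 5.0, Analyte.IGM: 5.0}, ResponsePattern.IGA_M),
            ({Analyte.IGG: 5.0, Analyte.IGA: 5.0, Analyte.IGM: -1.0}, ResponsePattern.IGG_A),
            ({Analyte.IGG: 5.0, Analyte.IGA: 5.0, Analyte.IGM: 5.0}, ResponsePattern.IGG_A_M),
        ],
    )
    def test_taxonomy(self, ifs, expected):
        assert classify_response_pattern(classify(sample_with_ifs(ifs))) is expected

    def test_measured_subset(self):
        # with IgA unmeasured the pattern is computed over IgG/IgM only
        result = classify(sample_with_ifs({Analyte.IGG: 5.0, Analyte.IGM: 5.0}))
        assert classify_response_pattern(result) is ResponsePattern.IGG_M


class TestReferenceStandardDecomposition:
    def test_hand_enumerated_cohort(self):
        # 2 OCB-only + 1 quantitative-only + 1 both + 1 contamination-discounted
        # + 2 negatives -> 4 responders
        cohort = [
            sample_with_ifs({Analyte.IGG: -10.0}, sample_id="ocb1",
                            ocb_status=OCBStatus.CSF_SPECIFIC_POSITIVE),
            sample_with_ifs({Analyte.IGG: -10.0}, sample_id="ocb2",
                            ocb_status=OCBStatus.CSF_SPECIFIC_POSITIVE),
            sample_with_ifs({Analyte.IGG: 15.0}, sample_id="quant"),
            sample_with_ifs({Analyte.IGM: 25.0}, sample_id="both",
                            ocb_status=OCBStatus.CSF_SPECIFIC_POSITIVE),
            sample_with_ifs({Analyte.IGM: 30.0, Analyte.IGA: 15.0, Analyte.IGG: 4.0},
                            sample_id="contam", erythrocytes_csf=900),
            sample_with_ifs({Analyte.IGG: -5.0}, sample_id="neg1"),
            sample_with_ifs({Analyte.IGM: -50.0}, sample_id="neg2"),
        ]
        results = [classify(s) for s in cohort]
        assert sum(r.immune_response for r in results) == 4
        assert sum(r.blood_contamination for r in results) == 1
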