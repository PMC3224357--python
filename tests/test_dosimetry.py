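"""Machine-side dose chain, tissue weighting, and reporting conventions."""

import numpy as np
import pytest

from ctcap import (CTDIMeasurements, OrganDoseTable, ctdi_vol, ctdi_w, dlp,
                   effective_dose_dlp_cc, effective_dose_from_organ_doses,
                   energy_response_correction, load_anthropomorphic_doses,
                   percent_difference, percent_difference_printed)
from ctcap.dosimetry import DEFAULT_SCHEME, TissueWeightingScheme, canonical_organ
from ctcap.errors import (IncompleteTableError, InvalidMeasurementError,
                          InvalidPitchError, UndefinedComparisonError)


class TestCtdiChain:
    @pytest.mark.parametrize("p, c, expected", [(10, 10, 10), (12, 6, 10), (0, 9, 3)])
    def test_ctdi_w(self, p, c, expected):
        assert ctdi_w(CTDIMeasurements(ctdi_p=p, ctdi_c=c)) == pytest.approx(expected)

    def test_negative_measurements_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            CTDIMeasurements(ctdi_p=-1.0, ctdi_c=5.0)

    @pytest.mark.parametrize("w, pitch, expected", [(10, 1, 10), (11, 1.375, 8.0)])
    def test_ctdi_vol(self, w, pitch, expected):
        assert ctdi_vol(w, pitch) == pytest.approx(expected)

    def test_zero_pitch_rejected(self):
        with pytest.raises(InvalidPitchError):
            ctdi_vol(10, 0)

    @pytest.mark.parametrize("v, L, expected", [(10, 0, 0), (14.3, 66.9, 956.67), (1, 1, 1)])
    def test_dlp(self, v, L, expected):
        assert dlp(v, L) == pytest.approx(expected)

    @pytest.mark.parametrize("d, expected", [(0, 0), (956.19, 14.34285), (1000, 15.0)])
    def test_effective_dose_dlp_cc(self, d, expected):
        assert effective_dose_dlp_cc(d) == pytest.approx(expected, abs=1e-9)

    def test_chain_is_multilinear(self, rng):
        """E(p,c,pitch,L) scales linearly in each scalar argument."""
        p, c, pitch, L = 12.0, 6.0, 1.375, 66.9
        base = effective_dose_dlp_cc(dlp(ctdi_vol(ctdi_w(CTDIMeasurements(p, c)), pitch), L))
        twice = effective_dose_dlp_cc(dlp(ctdi_vol(ctdi_w(CTDIMeasurements(2 * p, 2 * c)), pitch), L))
        assert twice == pytest.approx(2 * base, rel=1e-12)
        half_pitch = effective_dose_dlp_cc(
            dlp(ctdi_vol(ctdi_w(CTDIMeasurements(p, c)), pitch / 2), L))
        assert half_pitch == pytest.approx(2 * base, rel=1e-12)


class TestEffectiveDoseAssembly:
    def test_zero_doses_give_zero(self):
        organs = list(DEFAULT_SCHEME.individually_weighted) + list(DEFAULT_SCHEME.remainder_members)
        table = OrganDoseTable(rows={o: (0.0, 0.0) for o in organs})
        result = effective_dose_from_organ_doses(table)
        assert result.effective_dose == 0.0
        assert all(v == 0.0 for v in result.contributions.values())

    def test_uniform_dose_scales_by_weight_sum(self):
        """With every organ at dose D the result is (sum of weights) x D = 0.53 D."""
        organs = list(DEFAULT_SCHEME.individually_weighted) + list(DEFAULT_SCHEME.remainder_members)
        table = OrganDoseTable(rows={o: (10.0, 0.0) for o in organs})
        result = effective_dose_from_organ_doses(table)
        assert result.effective_dose == pytest.approx(0.53 * 10.0, rel=1e-12)

    def test_missing_organ_is_named(self):
        organs = list(DEFAULT_SCHEME.individually_weighted) + list(DEFAULT_SCHEME.remainder_members)
        organs.remove("pancreas")
        table = OrganDoseTable(rows={o: (1.0, 0.0) for o in organs})
        with pytest.raises(IncompleteTableError, match="pancreas"):
            effective_dose_from_organ_doses(table)

    def test_agrees_with_bruteforce_weighted_sum(self, rng):
        """Independent explicit-loop summation matches to 1e-12 relative."""
        scheme = DEFAULT_SCHEME
        for _ in range(100):
            rows = {o: (float(rng.uniform(0, 40)), float(rng.uniform(0, 2)))
                    for o in list(scheme.individually_weighted) + list(scheme.remainder_members)}
            result = effective_dose_from_organ_doses(OrganDoseTable(rows=rows))
            # brute force, sharing no code with the implementation
            expected = 0.0
            for organ, w in scheme.weights.items():
                if organ == "remainder":
                    acc, cnt = 0.0, 0
                    for member in scheme.remainder_members:
                        acc += rows[member][0]
                        cnt += 1
                    expected += w * acc / cnt
                else:
                    expected += w * rows[organ][0]
            assert result.effective_dose == pytest.approx(expected, rel=1e-12)

    def test_remainder_overlap_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            TissueWeightingScheme(weights={"lung": 0.12, "remainder": 0.12},
                                  remainder_members=("lung",))


#: printed per-organ equivalent-dose cells (organ -> value) for each
#: anthropomorphic phantom and dose source, with the printed decimal places
PRINTED_CONTRIBUTIONS = {
    ("female", "measured"): {
        "brain": (0.0029, 4), "colon": (2.68, 2), "esophagus": (1.00, 2),
        "liver": (1.040, 3), "lung": (3.24, 2), "thymus": (0.94, 2),
        "thyroid": (0.49, 2), "remainder": (3.08, 2),
    },
    ("female", "calculated"): {
        "brain": (0.004, 3), "colon": (2.5, 1), "esophagus": (0.92, 2),
        "liver": (1.18, 2), "lung": (4.07, 2), "thymus": (1.0, 1),
        "thyroid": (1.0, 1), "remainder": (3.1, 1),
    },
    ("male", "measured"): {
        "brain": (0.007, 3), "colon": (3.4, 1), "esophagus": (0.88, 2),
        "liver": (1.05, 2), "lung": (2.9, 1), "thymus": (1.08, 2),
        "thyroid": (1.21, 2), "remainder": (2.7, 1),
    },
    ("male", "calculated"): {
        "brain": (0.004, 3), "colon": (2.4, 1), "esophagus": (0.84, 2),
        "liver": (1.12, 2), "lung": (3.89, 2), "thymus": (1.0, 1),
        "thyroid": (1.0, 1), "remainder": (2.3, 1),
    },
}

PRINTED_EFFECTIVE_DOSE = {
    ("female", "measured"): 12.5, ("female", "calculated"): 13.7,
    ("male", "measured"): 13.1, ("male", "calculated"): 12.5,
}


class TestAnthropomorphicTables:
    @pytest.mark.parametrize("key", sorted(PRINTED_EFFECTIVE_DOSE))
    def test_effective_dose_reproduces_printed_value(self, key):
        table = load_anthropomorphic_doses()[key]
        result = effective_dose_from_organ_doses(table)
        assert result.effective_dose == pytest.approx(PRINTED_EFFECTIVE_DOSE[key], abs=0.1)

    @pytest.mark.parametrize("key", sorted(PRINTED_CONTRIBUTIONS))
    def test_every_contribution_matches_its_printed_cell(self, key):
        table = load_anthropomorphic_doses()[key]
        result = effective_dose_from_organ_doses(table)
        for organ, (printed, decimals) in PRINTED_CONTRIBUTIONS[key].items():
            rounded = round(result.contributions[organ], decimals)
            assert abs(rounded - printed) <= 0.01 + 1e-12, (organ, rounded, printed)

    def test_contributions_sum_to_effective_dose(self):
        for table in load_anthropomorphic_doses().values():
            result = effective_dose_from_organ_doses(table)
            assert result.effective_dose == pytest.approx(
                sum(result.contributions.values()), rel=1e-12)


class TestReportingConventions:
    @pytest.mark.parametrize(
        "a, b, raw, printed",
        [(13.7, 12.5, 9.16, 9), (13.1, 12.5, 4.69, 5), (21, 15, 33.33, 33)])
    def test_percent_difference_matches_printed_values(self, a, b, raw, printed):
        assert percent_difference(a, b) == pytest.approx(raw, abs=0.005)
        assert percent_difference_printed(a, b) == printed

    def test_percent_difference_symmetric_and_zero_on_equal(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.1, 50, size=2)
            assert percent_difference(a, b) == pytest.approx(percent_difference(b, a), rel=1e-12)
        assert percent_difference(7.3, 7.3) == 0.0

    def test_percent_difference_undefined_for_nonpositive_mean(self):
        with pytest.raises(UndefinedComparisonError):
            percent_difference(0.0, 0.0)

    @pytest.mark.parametrize("reading, factor, expected",
                             [(10.0, 1.15, 11.5), (7.0, 1.0, 7.0), (0.0, 1.15, 0.0)])
    def test_energy_response_correction(self, reading, factor, expected):
        assert energy_response_correction(reading, factor) == pytest.approx(expected)

    def test_nonpositive_correction_factor_rejected(self):
        with pytest.raises(InvalidMeasurementError):
            energy_response_correction(10.0, 0.0)


def test_canonical_organ_aliases():
    assert canonical_organ("Uterus/Testes") == "uterus_testes"
    assert canonical_organ("uterus") == "uterus_testes"
    assert canonical_organ("Adrenals/Gall Bladder") == "adrenals_gall_bladder"
    assert canonical_organ("Lung") == "lung"
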