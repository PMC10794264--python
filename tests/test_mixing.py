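"""Two-end-member apportionment: fractions, CIs, dose-response report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palmtrace.derivatization import species
from palmtrace.isotope import DeltaValue, VPDB_SCALE
from palmtrace.mixing import (
    AbsentEndMemberError,
    DegenerateMixingError,
    MixingEstimate,
    dose_response_profile,
    mixing_fraction,
    substitute_fat_endmember,
)
from palmtrace.signatures import (
    AbsentEndMember,
    SourceSignature,
    diet_fat_signature,
    sugar_signature,
)


def sig(label, value, sd=None):
    return SourceSignature(label, DeltaValue(value, sd=sd, scale=VPDB_SCALE))


SUGAR = sig("dietary sugars", -11.15, 0.65)
FAT = sig("dietary PAM", -29.70, 0.19)


def tissue(value, sd=None):
    return DeltaValue(value, sd=sd, scale=VPDB_SCALE)


class TestFraction:
    def test_endmember_identities(self):
        assert mixing_fraction(tissue(-29.70), SUGAR, FAT).fraction_sugar == 0.0
        assert mixing_fraction(tissue(-11.15), SUGAR, FAT).fraction_sugar == 1.0

    def test_enriched_brain_value(self):
        est = mixing_fraction(tissue(-16.47), SUGAR, FAT)
        assert est.fraction_sugar == pytest.approx(13.23 / 18.55, abs=1e-9)
        assert est.fraction_sugar == pytest.approx(0.713, abs=5e-4)

    def test_all_four_extreme_combinations_exceed_seventy_percent(self, diets):
        """Both brain extremes against both fat sources: f >= 0.70."""
        sugar = sugar_signature(diets["MP"])
        fats = [diet_fat_signature(diets[d], species("16:0")) for d in ("MP", "HP")]
        fractions = [
            mixing_fraction(tissue(t), sugar, f).fraction_sugar
            for t in (-14.79, -16.47)
            for f in fats
        ]
        assert len(fractions) == 4
        assert all(f >= 0.70 for f in fractions)

    def test_affine_and_increasing_in_tissue_delta(self):
        ds = np.linspace(-29.0, -12.0, 9)
        fs = [mixing_fraction(tissue(d), SUGAR, FAT).raw_fraction for d in ds]
        assert all(a < b for a, b in zip(fs, fs[1:]))
        slopes = np.diff(fs) / np.diff(ds)
        assert np.allclose(slopes, slopes[0], rtol=1e-9)

    def test_out_of_range_clamped_and_flagged(self):
        est = mixing_fraction(tissue(-31.0), SUGAR, FAT)
        assert est.clamped
        assert est.fraction_sugar == 0.0
        assert est.raw_fraction < 0.0

    def test_degenerate_separation_rejected(self):
        with pytest.raises(DegenerateMixingError):
            mixing_fraction(tissue(-20.0), sig("s", -20.0), sig("f", -20.5))

    def test_absent_endmember_directs_to_substitute(self):
        absent = AbsentEndMember(diet_id="LP", species="16:0")
        with pytest.raises(AbsentEndMemberError, match="substitute"):
            mixing_fraction(tissue(-16.0), SUGAR, absent)

    def test_atom_fraction_space_nearly_identical_at_natural_abundance(self):
        a = mixing_fraction(tissue(-16.47), SUGAR, FAT, space="delta")
        b = mixing_fraction(tissue(-16.47), SUGAR, FAT, space="atom_fraction")
        assert b.fraction_sugar == pytest.approx(a.fraction_sugar, rel=1e-3)

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=100, derandomize=True)
    def test_fraction_inverts_the_forward_mixture(self, f_true):
        d = f_true * SUGAR.delta.value + (1 - f_true) * FAT.delta.value
        est = mixing_fraction(tissue(d), SUGAR, FAT)
        assert est.raw_fraction == pytest.approx(f_true, abs=1e-12)


class TestUncertainty:
    def test_montecarlo_reproducible_and_close_to_analytic(self):
        kwargs = dict(delta_tissue=tissue(-16.47, sd=0.3), sugar=SUGAR, fat=FAT)
        ana = mixing_fraction(method="analytic", **kwargs)
        mc1 = mixing_fraction(method="montecarlo", **kwargs)
        mc2 = mixing_fraction(method="montecarlo", **kwargs)
        assert (mc1.ci_low, mc1.ci_high) == (mc2.ci_low, mc2.ci_high)
        width_a = ana.ci_high - ana.ci_low
        width_m = mc1.ci_high - mc1.ci_low
        assert abs(width_a - width_m) < 0.15 * width_a

    def test_analytic_ci_widens_with_input_sd(self):
        narrow = mixing_fraction(tissue(-16.47, sd=0.1), SUGAR, FAT)
        wide = mixing_fraction(tissue(-16.47, sd=0.6), SUGAR, FAT)
        assert (wide.ci_high - wide.ci_low) > (narrow.ci_high - narrow.ci_low)

    def test_montecarlo_ci_respects_physical_bounds(self):
        est = mixing_fraction(tissue(-11.5, sd=1.0), SUGAR, FAT,
                              method="montecarlo")
        assert 0.0 <= est.ci_low <= est.ci_high <= 1.0

    def test_parameter_recovery_at_study_noise(self):
        """Mean estimated fraction within 0.03 of truth, n = 6 per group."""
        rng = np.random.default_rng(20240117)
        sep_sugar, sep_fat = -11.15, -29.70
        for f_true in (0.3, 0.5, 0.7, 0.9):
            d_true = f_true * sep_sugar + (1 - f_true) * sep_fat
            means = []
            for _ in range(200):
                obs = rng.normal(d_true, 0.3, size=6)
                fs = [
                    mixing_fraction(tissue(v), SUGAR, FAT).fraction_sugar
                    for v in obs
                ]
                means.append(np.mean(fs))
            assert abs(np.mean(means) - f_true) < 0.03


class TestDoseResponse:
    @staticmethod
    def estimates(fracs):
        return {
            g: MixingEstimate(
                fraction_sugar=f, raw_fraction=f,
                ci_low=max(f - 0.05, 0.0), ci_high=min(f + 0.05, 1.0),
                method="analytic",
            )
            for g, f in fracs.items()
        }

    def test_monotone_decreasing_verdict(self):
        rep = dose_response_profile(self.estimates({"LP": 0.9, "MP": 0.8, "HP": 0.7}))
        assert rep.monotone_decreasing
        assert rep.violations == ()
        assert rep.pairwise_differences["LP-MP"] == pytest.approx(0.1)

    def test_reversed_ordering_lists_violations(self):
        rep = dose_response_profile(self.estimates({"LP": 0.7, "MP": 0.8, "HP": 0.9}))
        assert not rep.monotone_decreasing
        assert set(rep.violations) == {("LP", "MP"), ("MP", "HP")}

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            dose_response_profile(self.estimates({"LP": 0.9}))

    def test_dose_response_detected_on_simulated_cohorts(self):
        """Generator ordering f(LP)>f(MP)>f(HP) is recovered in >=95%."""
        rng = np.random.default_rng(20240117)
        truths = {"LP": 0.88, "MP": 0.80, "HP": 0.72}
        hits = 0
        reps = 200
        for _ in range(reps):
            ests = {}
            for g, f in truths.items():
                d = f * SUGAR.delta.value + (1 - f) * FAT.delta.value
                obs = rng.normal(d, np.hypot(0.5, 0.3), size=6)
                fbar = np.mean(
                    [mixing_fraction(tissue(v), SUGAR, FAT).fraction_sugar
                     for v in obs]
                )
                ests[g] = MixingEstimate(
                    fraction_sugar=min(max(fbar, 0.0), 1.0),
                    raw_fraction=fbar, ci_low=0.0, ci_high=1.0,
                    method="analytic",
                )
            hits += dose_response_profile(ests).monotone_decreasing
        assert hits / reps >= 0.95


def test_substitute_endmember_pools_available_fats(diets):
    pam = species("16:0")
    real = [diet_fat_signature(diets[d], pam) for d in ("MP", "HP")]
    sub = substitute_fat_endmember(real)
    assert sub.delta.value == pytest.approx((-29.44 - 29.70) / 2)
    assert sub.delta.sd > 0
    with pytest.raises(AbsentEndMemberError):
        substitute_fat_endmember([])
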