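import numpy as np
import pytest

from radiomics_repro.cohort import CohortSpec, generate_cohort, perturb_mask
from radiomics_repro.core import READINGS
from radiomics_repro.preprocess import compute_adc


def _ellipse(r=10, shape=(40, 40)):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - shape[0] / 2) / r) ** 2 + ((cc - shape[1] / 2) / (r * 0.8)) ** 2 <= 1


def _dice(a, b):
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


class TestPerturbMask:
    def test_zero_magnitude_is_identity(self, rng):
        mask = _ellipse()
        out = perturb_mask(mask, 0.0, rng)
        np.testing.assert_array_equal(out, mask)

    def test_dice_stays_high_but_below_one(self):
        mask = _ellipse(r=11)
        assert mask.sum() > 250
        dices = []
        for seed in range(100):
            out = perturb_mask(mask, 2.0, np.random.default_rng(seed))
            dices.append(_dice(mask, out))
        dices = np.array(dices)
        assert np.all(dices < 1.0)
        assert dices.mean() > 0.6

    def test_area_change_monotone_in_magnitude(self):
        mask = _ellipse()
        mean_changes = []
        for magnitude in (0.5, 1.0, 2.0, 4.0):
            deltas = [
                abs(
                    int(perturb_mask(mask, magnitude, np.random.default_rng(s)).sum())
                    - int(mask.sum())
                )
                for s in range(100)
            ]
            mean_changes.append(np.mean(deltas))
        assert all(a < b for a, b in zip(mean_changes, mean_changes[1:]))

    def test_output_single_component_nonempty(self, rng):
        mask = _ellipse(r=5)
        from scipy import ndimage

        for _ in range(50):
            out = perturb_mask(mask, 3.0, rng)
            assert out.sum() >= 1
            _, n = ndimage.label(out, structure=np.ones((3, 3), bool))
            assert n == 1

    def test_negative_magnitude_rejected(self, rng):
        with pytest.raises(ValueError):
            perturb_mask(_ellipse(), -1.0, rng)


class TestCohortDesign:
    def test_default_design_counts(self):
        spec = CohortSpec()
        assert spec.n_patients * spec.glands_per_patient == 74
        # one reading over the full cohort = 444 mask instances
        assert 74 * len(spec.sequence_labels) == 444

    def test_single_case_structure(self):
        spec = CohortSpec(n_patients=1, glands_per_patient=1, rng_seed=5)
        cases = generate_cohort(spec)
        assert len(cases) == 1
        case = cases[0]
        assert len(case.images) == 6
        n_delineations = sum(len(v) for v in case.delineations.values())
        assert n_delineations == 18
        for label, dels in case.delineations.items():
            assert [d.reading for d in dels] == list(READINGS)

    def test_same_seed_bit_reproducible(self):
        spec = CohortSpec(n_patients=2, rng_seed=99)
        a = generate_cohort(spec)
        b = generate_cohort(CohortSpec(n_patients=2, rng_seed=99))
        for ca, cb in zip(a, b):
            for label in ca.images:
                np.testing.assert_array_equal(
                    ca.images[label].pixels, cb.images[label].pixels
                )
                for da, db in zip(ca.delineations[label], cb.delineations[label]):
                    np.testing.assert_array_equal(da.mask, db.mask)

    def test_delineations_overlap_truth(self, small_cohort):
        for case in small_cohort:
            for dels in case.delineations.values():
                for d in dels:
                    assert _dice(d.mask, case.truth_mask) > 0

    def test_intra_reader_displacement_smaller_than_inter(self, small_cohort):
        intra, inter = [], []
        for case in small_cohort:
            for dels in case.delineations.values():
                by = {d.reading: d.mask for d in dels}
                inter.append(1 - _dice(by["L1"], by["L2.1"]))
                intra.append(1 - _dice(by["L2.1"], by["L2.2"]))
        assert np.mean(intra) < np.mean(inter)

    def test_dixon_pairs_share_delineations_others_do_not(self, small_cohort):
        n_diff_t2 = 0
        n_diff_indep = 0
        for case in small_cohort:
            for a, b in (("ipDIXON_T2", "wDIXON_T2"), ("PC_ipDIXON_T1", "PC_wDIXON_T1")):
                for da, db in zip(case.delineations[a], case.delineations[b]):
                    np.testing.assert_array_equal(da.mask, db.mask)
            if not np.array_equal(
                case.delineations["T1"][0].mask, case.delineations["ADC"][0].mask
            ):
                n_diff_indep += 1
        assert n_diff_indep > len(small_cohort) // 2

    def test_intra_equals_inter_zero_gives_identical_readings(self):
        spec = CohortSpec(
            n_patients=1, inter_reader_perturb=0.0, intra_reader_perturb=0.0, rng_seed=1
        )
        case = generate_cohort(spec)[0]
        for dels in case.delineations.values():
            for d in dels[1:]:
                np.testing.assert_array_equal(d.mask, dels[0].mask)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="intra"):
            CohortSpec(inter_reader_perturb=0.5, intra_reader_perturb=1.0)
        with pytest.raises(ValueError, match="n_patients"):
            CohortSpec(n_patients=0)
        with pytest.raises(ValueError, match="fit"):
            generate_cohort(CohortSpec(n_patients=1, image_size=(24, 24)))


class TestDWIConsistency:
    def test_adc_map_recovers_true_field_inside_gland(self, small_cohort):
        """The emitted ADC image approximates the generating field."""
        errs = []
        for case in small_cohort:
            adc = case.images["ADC"].pixels
            inside = case.truth_mask
            errs.append(np.nanmedian(np.abs(adc[inside] - case.adc_true[inside])))
        # noisy signals: median error well below the field's dynamic range
        assert np.median(errs) < 0.25

    def test_noise_free_signals_invert_exactly(self):
        spec = CohortSpec(n_patients=1, rng_seed=3)
        contrasts = dict(spec.contrasts)
        contrasts["ADC"] = (400.0, 60.0, 0.0)  # no signal noise
        spec = CohortSpec(n_patients=1, rng_seed=3, contrasts=contrasts)
        case = generate_cohort(spec)[0]
        adc = case.images["ADC"].pixels
        inside = case.truth_mask
        np.testing.assert_allclose(
            adc[inside], case.adc_true[inside], rtol=1e-10
        )
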