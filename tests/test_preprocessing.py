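"""Wavelength subsampling, MSC, outlier removal and cut comparison."""

import numpy as np
import pytest
from scipy import stats

from phenospec import (
    Spectrum,
    SyntheticConfig,
    compare_cuts,
    generate_cohort,
    msc_correct,
    remove_outliers,
    subsample_wavelengths,
)
from phenospec.errors import ValidationError


def _spec(sid, wl, refl, cut=2):
    return Spectrum(sample_id=sid, cultivar="X", cut=cut, wavelengths_nm=wl, reflectance=refl)


class TestSubsample:
    def test_1nm_grid_to_2nm_gives_673_bands(self):
        wl = 355.0 + np.arange(1346)  # 1 nm native grid, 355-1700
        s = _spec("a", wl, np.linspace(0.1, 0.9, len(wl)))
        out = subsample_wavelengths(s, 2.0)
        assert out.n_bands == 673
        assert out.wavelengths_nm[0] == 355.0
        assert np.all(np.diff(out.wavelengths_nm) == 2.0)

    def test_native_step_is_identity(self):
        wl = np.array([355.0, 357.0, 359.0])
        s = _spec("a", wl, np.array([0.1, 0.2, 0.3]))
        out = subsample_wavelengths(s, 2.0)
        assert np.array_equal(out.wavelengths_nm, wl)
        assert np.array_equal(out.reflectance, s.reflectance)

    def test_non_multiple_step_rejected_naming_both(self):
        wl = np.array([355.0, 357.0, 359.0, 361.0])
        s = _spec("a", wl, np.full(4, 0.5))
        with pytest.raises(ValidationError, match="3.*2|2.*3"):
            subsample_wavelengths(s, 3.0)

    def test_step_below_native_rejected(self):
        wl = np.array([355.0, 357.0, 359.0])
        with pytest.raises(ValidationError):
            subsample_wavelengths(_spec("a", wl, np.full(3, 0.5)), 1.0)


class TestMSC:
    def test_exact_inversion_of_linear_scatter(self, reference):
        ref = reference
        s1 = _spec("s1", ref.wavelengths_nm, 2.0 * ref.reflectance + 1.0)
        s2 = _spec("s2", ref.wavelengths_nm, 0.5 * ref.reflectance - 0.01)
        corrected, report = msc_correct([s1, s2], reference=ref)
        for c in corrected:
            assert np.allclose(c.reflectance, ref.reflectance, atol=1e-10)
        a1, b1 = report.per_sample_fit["s1"]
        assert a1 == pytest.approx(2.0) and b1 == pytest.approx(1.0)

    def test_reference_input_unchanged_with_unit_fit(self, reference):
        ref = reference
        s = _spec("same", ref.wavelengths_nm, ref.reflectance.copy())
        other = _spec("other", ref.wavelengths_nm, 1.5 * ref.reflectance + 0.1)
        corrected, report = msc_correct([s, other], reference=ref)
        a, b = report.per_sample_fit["same"]
        assert a == pytest.approx(1.0, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(corrected[0].reflectance, ref.reflectance, atol=1e-12)

    def test_variance_shrinks_on_scattered_cohort(self):
        cfg = SyntheticConfig(n_cultivars=10, n_replicates=2, scatter_slope_sd=0.2,
                              scatter_offset_sd=0.05, seed=9)
        spectra, _ = generate_cohort(cfg)
        before = np.vstack([s.reflectance for s in spectra]).var(axis=0)
        corrected, _ = msc_correct(spectra)
        after = np.vstack([s.reflectance for s in corrected]).var(axis=0)
        assert after.mean() < before.mean()
        assert np.mean(after < before) > 0.95

    def test_idempotent_under_fixed_reference(self, reference):
        ref = reference
        rng = np.random.default_rng(4)
        spectra = [
            _spec(f"s{i}", ref.wavelengths_nm,
                  np.exp(rng.normal(0, 0.2)) * ref.reflectance + rng.normal(0, 0.05))
            for i in range(6)
        ]
        once, _ = msc_correct(spectra, reference=ref)
        twice, _ = msc_correct(once, reference=ref)
        for a, b in zip(once, twice):
            assert np.allclose(a.reflectance, b.reflectance, atol=1e-10)

    def test_zero_variance_reference_rejected(self, reference):
        flat = _spec("flat", reference.wavelengths_nm, np.full(reference.n_bands, 0.5))
        spectra = [_spec(f"s{i}", reference.wavelengths_nm, reference.reflectance) for i in range(3)]
        with pytest.raises(ValidationError, match="variance"):
            msc_correct(spectra, reference=flat)

    def test_fewer_than_two_spectra_rejected(self, reference):
        with pytest.raises(ValidationError):
            msc_correct([_spec("only", reference.wavelengths_nm, reference.reflectance)])


class TestRemoveOutliers:
    def test_identical_spectra_none_removed(self):
        wl = np.arange(355.0, 400.0, 2.0)
        spectra = [_spec(f"s{i}", wl, np.full(len(wl), 0.4)) for i in range(5)]
        retained, report = remove_outliers(spectra)
        assert len(retained) == 5 and not report.removed_ids

    def test_single_shifted_record_removed(self, rng):
        wl = np.arange(355.0, 455.0, 2.0)
        base = rng.normal(0.5, 0.01, size=(50, len(wl)))
        spectra = [_spec(f"s{i}", wl, base[i]) for i in range(50)]
        spectra.append(_spec("shifted", wl, np.full(len(wl), 10.0)))
        retained, report = remove_outliers(spectra)
        assert [sid for sid, _ in report.removed_ids] == ["shifted"]
        assert report.retained_count == 50

    def test_removal_matches_direct_z_computation(self, small_cohort):
        spectra, _ = small_cohort
        means = np.array([s.reflectance.mean() for s in spectra])
        z = (means - means.mean()) / means.std(ddof=1)
        expected = {s.sample_id for s, zi in zip(spectra, z) if abs(zi) > 2.0}
        _, report = remove_outliers(spectra, z_limit=2.0)
        assert {sid for sid, _ in report.removed_ids} == expected

    def test_order_independent(self, small_cohort):
        spectra, _ = small_cohort
        _, fwd = remove_outliers(spectra, z_limit=2.0)
        _, rev = remove_outliers(spectra[::-1], z_limit=2.0)
        assert {s for s, _ in fwd.removed_ids} == {s for s, _ in rev.removed_ids}

    def test_retained_plus_removed_is_input_count(self, small_cohort):
        spectra, _ = small_cohort
        retained, report = remove_outliers(spectra, z_limit=1.5)
        assert report.retained_count + len(report.removed_ids) == len(spectra)
        assert len(retained) == report.retained_count

    def test_fewer_than_three_rejected(self):
        wl = np.arange(355.0, 400.0, 2.0)
        spectra = [_spec(f"s{i}", wl, np.full(len(wl), 0.4)) for i in range(2)]
        with pytest.raises(ValidationError):
            remove_outliers(spectra)


class TestCompareCuts:
    def _cohort(self, rng, offsets, n=30):
        wl = np.arange(355.0, 455.0, 2.0)
        spectra = []
        for cut, off in offsets.items():
            for i in range(n):
                refl = rng.normal(0.5 + off, 0.05, size=len(wl))
                spectra.append(_spec(f"c{cut}s{i}", wl, np.clip(refl, 0, None), cut=cut))
        return spectra

    def test_separated_groups_tiny_p(self, rng):
        table = compare_cuts(self._cohort(rng, {1: 0.5, 2: 0.0}))
        assert table.loc[0, "p"] < 1e-10

    def test_identical_groups_zero_t(self):
        wl = np.arange(355.0, 400.0, 2.0)
        spectra = [_spec(f"a{i}", wl, np.full(len(wl), 0.4 + 0.01 * i), cut=1) for i in range(4)]
        spectra += [_spec(f"b{i}", wl, np.full(len(wl), 0.4 + 0.01 * i), cut=2) for i in range(4)]
        table = compare_cuts(spectra)
        assert table.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)

    def test_type_one_error_rate_calibrated(self):
        """Same-distribution groups reject at ~alpha over 1000 seeded replicates."""
        rng = np.random.default_rng(77)
        n_rep, n = 1000, 25
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        rate = np.mean(p < 0.05)
        assert 0.03 <= rate <= 0.07

    def test_symmetric_in_pair_order(self, rng):
        spectra = self._cohort(rng, {1: 0.1, 2: 0.0, 3: 0.05}, n=10)
        table = compare_cuts(spectra)
        rev = compare_cuts(spectra[::-1])
        merged = table.merge(rev, on=["cut_i", "cut_j"], suffixes=("_f", "_r"))
        assert np.allclose(merged["p_f"], merged["p_r"])

    def test_all_pairs_present(self, small_cohort):
        spectra, _ = small_cohort
        table = compare_cuts(spectra)
        assert set(map(tuple, table[["cut_i", "cut_j"]].values.tolist())) == {
            (1, 2), (1, 3), (2, 3),
        }

    def test_single_cut_rejected(self, rng):
        with pytest.raises(ValidationError):
            compare_cuts(self._cohort(rng, {2: 0.0}, n=5))
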