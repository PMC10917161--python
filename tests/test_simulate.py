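import numpy as np
import pytest

from netpyramid.errors import ConfigurationError, DegenerateInputError
from netpyramid.simulate import (CohortDesign, band_limited_latent,
                                 band_power_fraction, generate_cohort,
                                 read_cohort_tsv, simulate_subject,
                                 write_cohort_tsv)


def small_design(h, **kwargs):
    defaults = dict(hierarchy=h, n_patients=2, n_controls=2,
                    voxels_per_parcel=2, seed=11)
    defaults.update(kwargs)
    return CohortDesign(**defaults)


class TestDesignValidation:
    def test_band_beyond_nyquist_rejected(self, toy_hierarchy):
        with pytest.raises(ConfigurationError):
            small_design(toy_hierarchy, band=(0.01, 0.3), tr_seconds=2.0)

    def test_reduction_out_of_range_rejected(self, toy_hierarchy):
        with pytest.raises(ConfigurationError):
            small_design(toy_hierarchy, coupling_reduction=1.5)

    def test_unknown_effect_node_rejected(self, toy_hierarchy):
        with pytest.raises(ConfigurationError):
            small_design(toy_hierarchy, effect_nodes={999})

    def test_coupling_length_checked(self, toy_hierarchy):
        with pytest.raises(ConfigurationError):
            small_design(toy_hierarchy, module_coupling=(0.5,))


class TestDeterminism:
    def test_fixed_seed_bit_identical(self, toy_hierarchy):
        a = generate_cohort(small_design(toy_hierarchy))
        b = generate_cohort(small_design(toy_hierarchy))
        for ta, tb in zip(a, b):
            assert ta.subject_id == tb.subject_id
            assert np.array_equal(ta.data, tb.data)

    def test_subject_stream_independent_of_order(self, toy_hierarchy):
        d = small_design(toy_hierarchy)
        direct = simulate_subject(d, "patient_002", "patient")
        via_cohort = generate_cohort(d)[1]
        assert np.array_equal(direct.data, via_cohort.data)

    def test_different_seeds_differ(self, toy_hierarchy):
        a = generate_cohort(small_design(toy_hierarchy, seed=1))[0]
        b = generate_cohort(small_design(toy_hierarchy, seed=2))[0]
        assert not np.array_equal(a.data, b.data)


class TestCovarianceStructure:
    def test_within_parcel_correlation_matches_model(self, toy_hierarchy):
        """Weights with sum-of-squares 1.5 and unit noise imply rho = 0.6."""
        d = small_design(toy_hierarchy, n_patients=1, n_controls=1,
                         n_timepoints=2000, voxels_per_parcel=4,
                         module_coupling=(0.5, 0.5), noise_sd=1.0)
        assert d.within_parcel_correlation == pytest.approx(0.6)
        ts = generate_cohort(d)[0]
        rs = []
        for pid in toy_hierarchy.node_ids(1):
            cols = ts.data[:, ts.unit_labels == pid]
            r = np.corrcoef(cols, rowvar=False)
            rs.extend(r[np.triu_indices_from(r, k=1)])
        assert abs(np.mean(rs) - 0.6) < 0.05

    def test_correlation_decreases_with_lca_scale(self, toy_hierarchy):
        """Voxel correlation falls as the lowest common ancestor coarsens."""
        d = small_design(toy_hierarchy, n_patients=1, n_controls=1,
                         n_timepoints=4000, voxels_per_parcel=1,
                         module_coupling=(0.6, 0.4), noise_sd=0.5)
        ts = generate_cohort(d)[0]
        r = np.corrcoef(ts.data, rowvar=False)
        h = toy_hierarchy
        lca_corr = {2: [], 3: []}
        ids = ts.unit_labels
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = int(ids[i]), int(ids[j])
                if h.ancestor(a, 2) == h.ancestor(b, 2):
                    lca_corr[2].append(r[i, j])
                elif h.ancestor(a, 3) == h.ancestor(b, 3):
                    lca_corr[3].append(r[i, j])
        assert np.mean(lca_corr[2]) > np.mean(lca_corr[3]) > 0

    def test_null_design_groups_exchangeable_in_distribution(self, toy_hierarchy):
        """With no injected effect the group field never enters generation."""
        d = small_design(toy_hierarchy)
        pat = simulate_subject(d, "s1", "patient")
        con = simulate_subject(d, "s1", "control")
        assert np.array_equal(pat.data, con.data)

    def test_coupling_reduction_lowers_cross_parcel_correlation(self, toy_hierarchy):
        base = small_design(toy_hierarchy, n_timepoints=2000,
                            module_coupling=(0.6, 0.4), noise_sd=0.5)
        eff = small_design(toy_hierarchy, n_timepoints=2000,
                           module_coupling=(0.6, 0.4), noise_sd=0.5,
                           effect_nodes={1}, coupling_reduction=0.6)
        ts_b = simulate_subject(base, "patient_001", "patient")
        ts_e = simulate_subject(eff, "patient_001", "patient")

        def mean_cross(ts):
            cols1 = ts.data[:, ts.unit_labels == 1].mean(axis=1)
            cols2 = ts.data[:, ts.unit_labels == 2].mean(axis=1)
            return np.corrcoef(cols1, cols2)[0, 1]

        assert mean_cross(ts_e) < mean_cross(ts_b)

    def test_coupling_reduction_preserves_signal_variance(self, toy_hierarchy):
        """Amplitude rescaling keeps effect-node variance at baseline level."""
        kwargs = dict(n_timepoints=4000, module_coupling=(0.6, 0.4),
                      noise_sd=0.0)
        base = small_design(toy_hierarchy, **kwargs)
        eff = small_design(toy_hierarchy, effect_nodes={1},
                           coupling_reduction=0.7, **kwargs)
        v_base = simulate_subject(base, "patient_001", "patient")
        v_eff = simulate_subject(eff, "patient_001", "patient")
        var_b = v_base.data[:, v_base.unit_labels == 1].var()
        var_e = v_eff.data[:, v_eff.unit_labels == 1].var()
        assert var_e == pytest.approx(var_b, rel=0.05)


class TestBandPowerFraction:
    def test_in_band_sinusoid(self):
        t = np.arange(240) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        assert band_power_fraction(x, 2.0, (0.01, 0.1)) == pytest.approx(1.0)

    def test_out_of_band_sinusoid(self):
        t = np.arange(240) * 2.0
        x = np.sin(2 * np.pi * 0.2 * t)
        assert band_power_fraction(x, 2.0, (0.01, 0.1)) == pytest.approx(0.0, abs=1e-12)

    def test_latent_is_band_limited(self):
        x = band_limited_latent(np.random.default_rng(3), 240, 2.0, (0.01, 0.1))
        assert band_power_fraction(x, 2.0, (0.01, 0.1)) >= 0.99
        assert np.var(x) == pytest.approx(1.0, rel=1e-6)

    def test_constant_series_rejected(self):
        with pytest.raises(DegenerateInputError):
            band_power_fraction(np.ones(16), 2.0)


def test_cohort_tsv_roundtrip(tmp_path, toy_hierarchy):
    subjects = generate_cohort(small_design(toy_hierarchy, n_timepoints=20))
    manifest = write_cohort_tsv(subjects, tmp_path)
    back = read_cohort_tsv(manifest)
    assert [s.subject_id for s in back] == [s.subject_id for s in subjects]
    for a, b in zip(subjects, back):
        assert a.group == b.group
        np.testing.assert_allclose(a.data, b.data, rtol=1e-4)
        assert np.array_equal(a.unit_labels, b.unit_labels)


def test_nifti_roundtrip(tmp_path, toy_hierarchy):
    from netpyramid.simulate import subject_from_nifti, subject_to_nifti

    ts = generate_cohort(small_design(toy_hierarchy, n_timepoints=16))[0]
    bold = tmp_path / "bold.nii.gz"
    labels = tmp_path / "labels.nii.gz"
    subject_to_nifti(ts, bold, labels)
    back = subject_from_nifti(bold, labels, ts.subject_id, ts.group)
    np.testing.assert_allclose(back.data, ts.data, rtol=1e-5)
    assert np.array_equal(back.unit_labels, ts.unit_labels)
    assert back.tr_seconds == pytest.approx(2.0)
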