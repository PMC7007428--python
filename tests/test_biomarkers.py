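import numpy as np
import pytest
from scipy import stats

from specgrade import (
    ClassEffect,
    CohortDesign,
    build_marker_table,
    dbm,
    direction,
    fit_pls_da,
    generate_cohort,
    marker_anova,
    preprocess,
    subset,
    top_peaks,
)
from specgrade.biomarkers import significance_tag
from specgrade.synth import default_band_model
from conftest import make_dataset


def two_class_dataset(rng, n_per=6, p=12, shift=None):
    X = rng.normal(size=(2 * n_per, p))
    if shift is not None:
        X[n_per:] += shift
    return make_dataset(
        X,
        labels=["G1"] * n_per + ["G2"] * n_per,
        stage_tag="raw",
    )


class TestDbm:
    def test_identical_distributions_no_flags_when_zero(self):
        X = np.tile(np.arange(6.0), (4, 1))
        ds = make_dataset(X, labels=["G1", "G1", "G2", "G2"])
        d = dbm(ds, "G2", "G1")
        np.testing.assert_allclose(d.coefficients, 0.0)
        assert d.flagged == []

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        ds = two_class_dataset(rng)
        a = dbm(ds, "G2", "G1")
        b = dbm(ds, "G1", "G2")
        np.testing.assert_allclose(a.coefficients, -b.coefficients)

    def test_missing_class_rejected(self):
        ds = make_dataset(np.ones((2, 3)), labels=["G1", "G1"])
        with pytest.raises(ValueError, match="absent"):
            dbm(ds, "G2", "G1")

    def test_flag_count_monotone_in_threshold(self):
        rng = np.random.default_rng(1)
        ds = two_class_dataset(rng, shift=0.5)
        counts = [
            len(dbm(ds, "G2", "G1", threshold=t).flagged)
            for t in (0.0, 0.1, 0.3, 1.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_single_injected_band_flagged_exactly(self):
        """At low noise an isolated injected effect flags only wavenumbers in
        its own band's neighbourhood, and flags the marker itself."""
        design = CohortDesign(class_sizes={"G1": 20, "G2": 20})
        bands = default_band_model()
        bands.patient_sd, bands.noise_sd = 0.05, 0.002
        eff = ClassEffect(1122.0, "up", 0.2, "G2")
        ds = subset(
            preprocess(generate_cohort(design, bands, [eff], seed=0)),
            labels=["G1", "G2"],
        )
        d = dbm(ds, "G2", "G1")
        flagged_wn = np.array([w for w, _ in d.flagged])
        assert flagged_wn.size > 0
        assert np.abs(flagged_wn - 1122.0).max() <= 31.0  # inside band support
        assert np.abs(flagged_wn - 1122.0).min() <= 4.0  # marker itself hit


class TestTopPeaks:
    def test_eight_isolated_spikes_recovered_in_magnitude_order(self):
        wn = np.arange(1800.0, 899.0, -4.0)
        coefs = np.zeros_like(wn)
        spikes = {1700.0: 0.9, 1600.0: -0.8, 1500.0: 0.7, 1400.0: -0.6,
                  1300.0: 0.5, 1200.0: -0.4, 1100.0: 0.3, 1000.0: -0.2}
        for w, c in spikes.items():
            coefs[np.argmin(np.abs(wn - w))] = c
        table = top_peaks(coefs, wn, 8)
        assert list(table["wavenumber"]) == sorted(
            spikes, key=lambda w: -abs(spikes[w])
        )

    def test_monotone_vector_falls_back_to_endpoints(self):
        wn = np.arange(1800.0, 899.0, -4.0)
        coefs = np.linspace(0.0, 1.0, wn.size)
        with pytest.warns(UserWarning, match="endpoints"):
            table = top_peaks(coefs, wn, 2)
        assert set(table["wavenumber"]) == {wn[0], wn[-1]}

    def test_plateau_takes_leftmost_point(self):
        wn = np.arange(10.0, 0.0, -1.0)
        coefs = np.array([0, 1, 3, 3, 3, 1, 0, 2, 1, 0], dtype=float)
        table = top_peaks(coefs, wn, 2)
        assert list(table["wavenumber"]) == [wn[2], wn[7]]

    def test_constant_offset_changes_magnitude_extrema(self):
        # |c| extrema are not offset-invariant: signed coefficients carry the
        # physics, so this is intended behaviour, not a bug.
        wn = np.arange(20.0, 0.0, -1.0)
        coefs = np.sin(np.linspace(0, 4 * np.pi, wn.size))
        a = top_peaks(coefs, wn, 3)["wavenumber"].tolist()
        b = top_peaks(coefs + 0.5, wn, 3)["wavenumber"].tolist()
        assert a != b

    def test_short_axis_rejected(self):
        with pytest.raises(ValueError, match="3 points"):
            top_peaks(np.array([1.0, 2.0]), np.array([2.0, 1.0]), 1)


class TestMarkerAnova:
    def test_identical_groups_give_p_one(self):
        X = np.tile(np.arange(4.0), (6, 1))
        ds = make_dataset(X, labels=["G1"] * 3 + ["G2"] * 3)
        assert marker_anova(ds, ds.wavenumbers[1]) == 1.0

    def test_two_group_anova_equals_pooled_t_test(self):
        rng = np.random.default_rng(2)
        ds = two_class_dataset(rng, n_per=8, shift=0.7)
        wn = ds.wavenumbers[3]
        p_anova = marker_anova(ds, wn)
        g1 = ds.intensities[ds.labels == "G1", 3]
        g2 = ds.intensities[ds.labels == "G2", 3]
        _, p_t = stats.ttest_ind(g1, g2, equal_var=True)
        assert p_anova == pytest.approx(p_t, rel=1e-10)

    def test_large_injected_effect_highly_significant(self):
        design = CohortDesign(class_sizes={"G1": 15, "G2": 15})
        bands = default_band_model()
        bands.patient_sd = 0.05
        eff = ClassEffect(1454.0, "up", 0.3, "G2")
        ds = preprocess(generate_cohort(design, bands, [eff], seed=1))
        assert marker_anova(ds, 1454.0) < 0.001

    def test_off_axis_wavenumber_rejected(self):
        ds = make_dataset(np.random.default_rng(3).normal(size=(4, 5)),
                          labels=["G1", "G1", "G2", "G2"])
        with pytest.raises(KeyError):
            marker_anova(ds, ds.wavenumbers[0] + 100.0)


class TestDirection:
    def test_injected_up_effect_reads_up_on_raw_scale(self):
        design = CohortDesign(class_sizes={"G1": 10, "G2": 10})
        bands = default_band_model()
        bands.patient_sd = 0.02
        eff = ClassEffect(1454.0, "up", 0.3, "G2")
        ds = generate_cohort(design, bands, [eff], seed=2)
        assert direction(ds, 1454.0, "G2", "G1") == "up"
        assert direction(ds, 1454.0, "G1", "G2") == "down"

    def test_exact_tie_warns_down(self):
        X = np.tile(np.arange(4.0), (4, 1))
        ds = make_dataset(X, labels=["G1", "G1", "G2", "G2"])
        with pytest.warns(UserWarning, match="tie"):
            assert direction(ds, ds.wavenumbers[0], "G2", "G1") == "down"


class TestMarkerTable:
    def test_structure_sorting_and_significance(self, preprocessed):
        sub = subset(preprocessed, labels=["G1", "G2"])
        model = fit_pls_da(
            sub.intensities, sub.labels, 2,
            wavenumbers=sub.wavenumbers, positive_class="G2",
        )
        table = build_marker_table(model, sub, n_peaks=8)
        frame = table.frame
        assert len(frame) <= 8
        mags = frame["coefficient"].abs().to_numpy()
        assert (np.diff(mags) <= 1e-12).all()
        for p, tag in zip(frame["p_value"], frame["significance"]):
            assert tag == significance_tag(p)
        assert set(frame["direction"]) <= {"up", "down"}

    def test_injected_markers_recovered_at_high_effect(self):
        injected = [(1546.0, "up"), (1454.0, "down"), (1227.0, "down")]
        design = CohortDesign(class_sizes={"G1": 25, "G2": 25})
        bands = default_band_model()
        effects = [ClassEffect(w, d, 0.25, "G2") for w, d in injected]
        ds = preprocess(generate_cohort(design, bands, effects, seed=3))
        model = fit_pls_da(
            ds.intensities, ds.labels, 1,
            wavenumbers=ds.wavenumbers, positive_class="G2",
        )
        table = build_marker_table(model, ds, n_peaks=8)
        found = table.frame["wavenumber"].to_numpy()
        for w, _ in injected:
            assert np.min(np.abs(found - w)) <= 4.0
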