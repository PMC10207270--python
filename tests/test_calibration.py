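import numpy as np
import pytest
from scipy import stats

from tetrelscan import (
    CalibrationPoint,
    estimate_density_promolecular,
    estimate_ttb_energy,
    fit_calibration,
    fit_distance_density,
    load_peptide_records,
    load_reference_complexes,
)
from tetrelscan.calibration import (
    PROMOLECULAR_PARAMS,
    REGRESSION_COMPLEXES,
    round_half_away,
)
from tetrelscan.exceptions import (
    DegenerateFitError,
    ExtrapolationWarning,
    FitError,
    InsufficientDataError,
    UnsupportedElementError,
)


def closed_form_ols(x, y):
    """Textbook least squares, the independent check for the fitted line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    syy = np.sum((y - y.mean()) ** 2)
    slope = sxy / sxx
    return slope, y.mean() - slope * x.mean(), sxy / np.sqrt(sxx * syy)


def make_points(pairs):
    return [CalibrationPoint(label, rho, de) for label, rho, de in pairs]


class TestFitCalibration:
    def test_reference_complexes_match_closed_form(self, table1_points_2_to_6):
        model = fit_calibration(make_points(table1_points_2_to_6))
        slope, intercept, r = closed_form_ols(
            [p[1] for p in table1_points_2_to_6],
            [p[2] for p in table1_points_2_to_6],
        )
        assert model.slope == pytest.approx(slope)
        assert model.intercept == pytest.approx(intercept)
        assert model.pearson_r == pytest.approx(r)
        # frozen closed-form values: denser contact -> more negative energy
        assert model.slope == pytest.approx(-5.46512, abs=1e-5)
        assert model.intercept == pytest.approx(1.79186, abs=1e-5)
        assert model.pearson_r == pytest.approx(-0.96407, abs=1e-5)
        assert model.n_points == 5

    def test_two_points_give_exact_line(self):
        model = fit_calibration(make_points([("a", 0.5, -1.0), ("b", 1.0, -2.0)]))
        assert model.predict_full(0.5) == pytest.approx(-1.0)
        assert model.predict_full(1.0) == pytest.approx(-2.0)
        assert abs(model.pearson_r) == 1.0

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_calibration(make_points([("a", 0.5, -1.0)] * 5))

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_calibration(make_points([("a", 0.5, -1.0)]))

    def test_parameter_recovery_under_noise(self):
        """Simulated (ρ, ΔE) data recover the generating slope.

        20 points per replicate, Gaussian energy noise of sd 0.15 kcal/mol;
        over 200 replicates the true slope must lie within 3 standard errors
        of the estimate at least 95% of the time.
        """
        rng = np.random.default_rng(20230404)
        true_slope, true_intercept = -5.5, 1.8
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            rho = rng.uniform(0.4, 1.7, size=20)
            de = true_slope * rho + true_intercept + rng.normal(0, 0.15, size=20)
            res = stats.linregress(rho, de)
            if abs(res.slope - true_slope) <= 3 * res.stderr:
                hits += 1
        assert hits / n_rep >= 0.95


class TestEstimateEnergy:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            (0.77, -1.2),  # ATSP c0, TRP···ALA
            (0.51, -0.5),  # p53 c3, LEU···ASN
            (1.38, -2.9),  # ATSP c1, 2JH···MK8
        ],
    )
    def test_tabulated_densities_reproduce_printed_energies(
        self, default_model, rho, expected
    ):
        est = estimate_ttb_energy(rho, default_model)
        assert est.dE_ttb_rounded == pytest.approx(expected)

    def test_root_of_line_gives_zero(self, default_model):
        rho0 = -default_model.intercept / default_model.slope
        assert estimate_ttb_energy(rho0, default_model).dE_ttb_rounded == 0.0

    def test_strictly_decreasing_in_rho(self, default_model):
        rhos = np.linspace(0.2, 3.0, 50)
        energies = [estimate_ttb_energy(r, default_model).dE_ttb for r in rhos]
        assert all(a > b for a, b in zip(energies, energies[1:]))

    def test_extrapolation_warns_but_returns(self, default_model):
        with pytest.warns(ExtrapolationWarning):
            est = estimate_ttb_energy(5.0, default_model)
        assert est.dE_ttb < 0

    def test_nonpositive_rho_rejected(self, default_model):
        with pytest.raises(ValueError):
            estimate_ttb_energy(0.0, default_model)

    def test_rounding_half_away_from_zero(self):
        assert round_half_away(-1.25, 1) == -1.3
        assert round_half_away(1.25, 1) == 1.3
        assert round_half_away(-1.24, 1) == -1.2


class TestDistanceDensitySurrogate:
    def test_tabulated_pairs_rank_correlate(self):
        df = load_peptide_records()
        points = [
            CalibrationPoint(str(i), r.rho100, r.dE, d_OC=r.d)
            for i, r in df.iterrows()
        ]
        model = fit_distance_density(points)
        predicted = model.predict(df["d"].to_numpy())
        rho_s = stats.spearmanr(predicted, df["rho100"].to_numpy()).statistic
        assert rho_s >= 0.85
        assert model.spearman_check == pytest.approx(rho_s)
        assert model.fit_points == len(df)

    def test_noiseless_exponential_recovered_exactly(self):
        a_true, b_true = 50.0, 1.2
        d = np.linspace(2.5, 3.6, 8)
        points = [
            CalibrationPoint(str(i), a_true * np.exp(-b_true * di), -1.0, d_OC=di)
            for i, di in enumerate(d)
        ]
        model = fit_distance_density(points)
        assert model.amplitude == pytest.approx(a_true, abs=1e-6)
        assert model.decay == pytest.approx(b_true, abs=1e-6)

    def test_prediction_strictly_decreasing_in_distance(self):
        from tetrelscan.calibration import default_distance_density_model

        model = default_distance_density_model()
        d = np.linspace(2.0, 5.0, 30)
        rho = model.predict(d)
        assert np.all(np.diff(rho) < 0)

    def test_constant_distance_fails(self):
        points = [CalibrationPoint(str(i), 0.5 + 0.1 * i, -1.0, d_OC=3.0)
                  for i in range(6)]
        with pytest.raises(FitError):
            fit_distance_density(points)

    def test_too_few_points(self):
        points = [CalibrationPoint(str(i), 1.0, -1.0, d_OC=3.0 + i)
                  for i in range(4)]
        with pytest.raises(InsufficientDataError):
            fit_distance_density(points)


class TestPromolecularDensity:
    def _two_carbonyls(self, d):
        """Two antiparallel C=O units with O···C separation d along z."""
        o1 = np.array([0.0, 0.0, 0.0])
        c1 = np.array([0.0, 1.231, 0.0])
        c2 = np.array([0.0, 0.0, d])
        o2 = np.array([0.0, -1.231, d])
        atoms = [("O", o1), ("C", c1), ("C", c2), ("O", o2)]
        return o1, c2, atoms

    def test_density_decays_with_probe_distance(self):
        o = np.zeros(3)
        near = estimate_density_promolecular(o, o + [0, 0, 0.1], [("O", o)])
        far = estimate_density_promolecular(o, o + [0, 0, 5.0], [("O", o)])
        assert near > far > 0

    def test_rigid_translation_invariance(self):
        o1, c2, atoms = self._two_carbonyls(3.0)
        shift = np.array([7.0, -2.0, 4.0])
        moved = [(el, np.asarray(coord) + shift) for el, coord in atoms]
        a = estimate_density_promolecular(o1, c2, atoms)
        b = estimate_density_promolecular(o1 + shift, c2 + shift, moved)
        assert a == pytest.approx(b, rel=1e-12)

    def test_rank_correlation_with_tabulated_densities(self):
        """Promolecular minima at the six ATSP cluster O···C separations
        must rank like the tabulated densities (shorter contact = denser)."""
        df = load_peptide_records()
        atsp = df[df["source"] == "ATSP"]
        minima = []
        for d in atsp["d"]:
            o1, c2, atoms = self._two_carbonyls(d)
            minima.append(estimate_density_promolecular(o1, c2, atoms))
        rho_s = stats.spearmanr(minima, atsp["rho100"]).statistic
        assert rho_s > 0.8

    def test_unknown_element_rejected(self):
        with pytest.raises(UnsupportedElementError):
            estimate_density_promolecular(
                np.zeros(3), np.array([0, 0, 3.0]), [("XX", np.zeros(3))]
            )

    def test_all_supported_elements_have_positive_parameters(self):
        for el, (a, b) in PROMOLECULAR_PARAMS.items():
            assert a > 0 and b > 0, el


class TestReferenceData:
    def test_reference_table_shape_and_regression_subset(self):
        df = load_reference_complexes()
        assert set(df.columns) == {"complex", "dE", "d", "rho100",
                                   "rho100_ancillary"}
        assert len(df) == 10
        assert set(REGRESSION_COMPLEXES) < set(df["complex"])
        assert "12" not in REGRESSION_COMPLEXES

    def test_peptide_records_cover_all_sources(self):
        df = load_peptide_records()
        assert set(df["source"]) == {"ATSP", "p53", "pDIQ", "4N5T-xray"}
        assert len(df) == 30
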