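"""Cosolvency models: log-linear, Jouyban-Acree (fitted + published), Wilson."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cosolv.cosolvency import (
    ETHANOL_LOGLINEAR,
    JA_ABRAHAM_GENERAL,
    JA_ETHANOL_WATER_GENERAL,
    JouybanAcreeParams,
    ModifiedWilsonParams,
    ja_fit,
    ja_predict,
    ja_trained_predict,
    loglinear_predict,
    loglinear_sigma,
    loglinear_sigma_from_logP,
    wilson_fit,
    wilson_predict,
)
from cosolv.data_model import ETHANOL_WATER, SolubilityDataset, SolubilityRecord
from cosolv.datasets import ASPIRIN_ABRAHAM
from cosolv.exceptions import AnchorMissingError, DomainError, FitError, RankDeficiencyError


class TestLogLinear:
    def test_sigma_zero_for_equal_solubilities(self):
        assert loglinear_sigma(0.5, 0.5) == 0.0

    def test_sigma_from_neat_anchors(self):
        # direct log of the measured neat-solvent ratio at 25 C
        assert loglinear_sigma(0.826, 0.0246) == pytest.approx(3.514, abs=5e-4)

    def test_sigma_negative_when_cosolvent_weaker(self):
        assert loglinear_sigma(0.01, 0.1) < 0

    def test_sigma_nonpositive_inputs_raise(self):
        with pytest.raises(DomainError):
            loglinear_sigma(0.0, 0.1)

    def test_sigma_from_logP(self):
        assert loglinear_sigma_from_logP(1.18) == pytest.approx(3.4452)
        assert loglinear_sigma_from_logP(0.0) == ETHANOL_LOGLINEAR.N

    def test_predict_boundary_returns_water_solubility(self):
        assert loglinear_predict(0.0246, 3.4452, 0.0) == pytest.approx(0.0246)

    def test_predicted_log_solubility_curve(self):
        # sigma from logP constants over neat-water anchor, both temperatures
        sigma = loglinear_sigma_from_logP(1.18)
        assert np.log(loglinear_predict(0.0246, sigma, 0.5)) == pytest.approx(-1.98, abs=5e-3)
        assert np.log(loglinear_predict(0.0246, sigma, 1.0)) == pytest.approx(-0.26, abs=5e-3)
        assert np.log(loglinear_predict(0.0308, sigma, 1.0)) == pytest.approx(-0.04, abs=5e-3)


def _exact_ja_dataset(J=(1000.0, -200.0, 50.0), anchors=None):
    anchors = anchors or {298.15: (0.8, 0.02), 310.15: (1.0, 0.03)}
    params = JouybanAcreeParams(J=J)
    records = []
    for T, (C1, C2) in anchors.items():
        for f1 in np.round(np.arange(0, 1.01, 0.1), 2):
            records.append(SolubilityRecord(f1, T, float(ja_predict(params, C1, C2, f1, T))))
    return SolubilityDataset(system=ETHANOL_WATER, records=tuple(records))


class TestJouybanAcree:
    def test_noiseless_identifiability(self):
        ds = _exact_ja_dataset()
        fit = ja_fit(ds)
        assert np.allclose(fit.J, (1000.0, -200.0, 50.0), rtol=1e-8, atol=1e-8)

    def test_fit_on_packaged_dataset_matches_published_coefficients(self, aspirin):
        fit = ja_fit(aspirin)
        assert fit.J[0] == pytest.approx(1426.596, rel=5e-3)
        assert fit.J[1] == pytest.approx(515.373, rel=5e-3)
        assert fit.J[2] == pytest.approx(-1084.479, rel=5e-3)

    def test_anchors_reproduced_exactly(self):
        p = JouybanAcreeParams(J=(1426.596, 515.373, -1084.479))
        assert ja_predict(p, 0.826, 0.0246, 0.0, 298.15) == pytest.approx(0.0246, rel=1e-14)
        assert ja_predict(p, 0.826, 0.0246, 1.0, 298.15) == pytest.approx(0.826, rel=1e-14)

    def test_hand_evaluated_midpoint(self):
        # ln C = 0.5 ln C1 + 0.5 ln C2 + 0.25 * J0 / T at f1 = 0.5
        p = JouybanAcreeParams(J=(1426.596, 515.373, -1084.479))
        expected = np.exp(
            0.5 * np.log(0.826) + 0.5 * np.log(0.0246) + 0.25 * 1426.596 / 298.15
        )
        assert ja_predict(p, 0.826, 0.0246, 0.5, 298.15) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.4716, abs=2e-4)

    def test_zero_mixing_terms_reduce_to_loglinear_blend(self):
        p = JouybanAcreeParams(J=(0.0,))
        got = ja_predict(p, 0.8, 0.02, 0.3, 298.15)
        assert got == pytest.approx(np.exp(0.3 * np.log(0.8) + 0.7 * np.log(0.02)))

    def test_anchor_only_dataset_is_rank_deficient(self):
        records = tuple(
            SolubilityRecord(f1, 298.15, c) for f1, c in [(0.0, 0.02), (1.0, 0.8)]
        )
        ds = SolubilityDataset(system=ETHANOL_WATER, records=records)
        with pytest.raises(RankDeficiencyError):
            ja_fit(ds)

    def test_missing_anchor_raises(self):
        records = tuple(
            SolubilityRecord(f1, 298.15, 0.1) for f1 in (0.0, 0.3, 0.5)
        )
        ds = SolubilityDataset(system=ETHANOL_WATER, records=records)
        with pytest.raises(AnchorMissingError):
            ja_fit(ds)

    def test_fit_residuals_match_regression_residuals(self, aspirin):
        # no transform leakage: ln-space residuals of predictions equal the
        # least-squares residuals of the linear regression
        fit = ja_fit(aspirin)
        recs = aspirin.subset(analyte="primary_solute").records
        resid = []
        for r in recs:
            pred = ja_predict(
                fit, aspirin.cosolvent_solubility(r.T), aspirin.water_solubility(r.T), r.f1, r.T
            )
            resid.append(np.log(r.C) - np.log(pred))
        f1 = np.array([r.f1 for r in recs])
        T = np.array([r.T for r in recs])
        y = np.array(
            [
                np.log(r.C)
                - r.f1 * np.log(aspirin.cosolvent_solubility(r.T))
                - (1 - r.f1) * np.log(aspirin.water_solubility(r.T))
                for r in recs
            ]
        )
        X = np.column_stack([f1 * (1 - f1) * (f1 - (1 - f1)) ** i / T for i in range(3)])
        assert np.allclose(resid, y - X @ np.array(fit.J), atol=1e-12)


class TestTrainedCoefficients:
    def test_anchor_reproduced(self):
        got = ja_trained_predict(JA_ETHANOL_WATER_GENERAL, 0.8, 0.02, 0.0, 298.15)
        assert got == pytest.approx(0.02, rel=1e-14)

    def test_abraham_power0_coefficient_dot_product(self):
        J = JA_ABRAHAM_GENERAL.term_coefficients(ASPIRIN_ABRAHAM).J
        assert J[0] == pytest.approx(937.2, abs=0.05)

    def test_constant_set_equals_plain_params(self):
        got = ja_trained_predict(JA_ETHANOL_WATER_GENERAL, 0.8, 0.02, 0.45, 305.0)
        params = JouybanAcreeParams(J=(1667.856, 1117.347, 447.7262))
        assert got == pytest.approx(ja_predict(params, 0.8, 0.02, 0.45, 305.0), rel=1e-14)

    def test_missing_descriptors_raise(self):
        from cosolv.exceptions import ConfigurationError

        with pytest.raises(ConfigurationError):
            ja_trained_predict(JA_ABRAHAM_GENERAL, 0.8, 0.02, 0.5, 298.15)


class TestModifiedWilson:
    def test_anchors_for_any_lambda(self):
        p = ModifiedWilsonParams(0.7, 1.9, 298.15)
        assert wilson_predict(p, 0.988, 0.0308, 0.0) == pytest.approx(0.0308, rel=1e-12)
        assert wilson_predict(p, 0.988, 0.0308, 1.0) == pytest.approx(0.988, rel=1e-12)

    def test_hand_evaluated_midpoint_with_published_parameters(self):
        p = ModifiedWilsonParams(0.294, 3.405, 310.15)
        assert wilson_predict(p, 0.988, 0.0308, 0.5) == pytest.approx(0.4495, abs=2e-4)

    def test_unit_lambdas_reduce_to_loglinear_blend(self):
        p = ModifiedWilsonParams(1.0, 1.0, 298.15)
        for f1 in (0.2, 0.5, 0.8):
            expected = np.exp(f1 * np.log(0.8) + (1 - f1) * np.log(0.02))
            assert wilson_predict(p, 0.8, 0.02, f1) == pytest.approx(expected, rel=1e-12)

    def test_noiseless_recovery(self):
        truth = ModifiedWilsonParams(0.4, 2.5, 298.15)
        records = tuple(
            SolubilityRecord(f1, 298.15, float(wilson_predict(truth, 0.8, 0.02, f1)))
            for f1 in np.round(np.arange(0, 1.01, 0.1), 2)
        )
        ds = SolubilityDataset(system=ETHANOL_WATER, records=records)
        fit = wilson_fit(ds, 298.15)
        assert fit.lambda12 == pytest.approx(0.4, abs=1e-6)
        assert fit.lambda21 == pytest.approx(2.5, abs=1e-6)

    def test_fit_on_packaged_dataset_recovers_published_lambdas(self, aspirin):
        fit = wilson_fit(aspirin, 310.15)
        assert fit.lambda12 == pytest.approx(0.294, abs=5e-3)
        assert fit.lambda21 == pytest.approx(3.405, abs=5e-2)

    def test_underdetermined_fit_raises(self):
        records = tuple(
            SolubilityRecord(f1, 298.15, 0.1 + f1) for f1 in (0.0, 0.5, 1.0)
        )
        ds = SolubilityDataset(system=ETHANOL_WATER, records=records)
        with pytest.raises(FitError):
            wilson_fit(ds, 298.15)

    def test_invalid_lambda_rejected(self):
        with pytest.raises(DomainError):
            ModifiedWilsonParams(-0.1, 2.0, 298.15)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    f1=st.floats(min_value=0.0, max_value=1.0),
    C1=st.floats(min_value=1e-4, max_value=10.0),
    C2=st.floats(min_value=1e-4, max_value=10.0),
)
def test_all_models_positive_and_anchor_consistent(f1, C1, C2):
    """Exponentiated models stay positive; f1 in {0,1} returns the anchors."""
    ja = JouybanAcreeParams(J=(800.0, -120.0, 40.0))
    wl = ModifiedWilsonParams(0.5, 2.0, 298.15)
    vals = [
        ja_predict(ja, C1, C2, f1, 298.15),
        wilson_predict(wl, C1, C2, f1),
        loglinear_predict(C2, np.log(C1 / C2), f1),
    ]
    assert all(v > 0 for v in vals)
    if f1 == 0.0:
        assert all(v == pytest.approx(C2, rel=1e-9) for v in vals)
    if f1 == 1.0:
        assert all(v == pytest.approx(C1, rel=1e-9) for v in vals)
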