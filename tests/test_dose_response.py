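import math
import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bmscreen.dose_response import (
    DoseResponseSeries,
    FitResult,
    compute_auc,
    fit_4pl,
    logistic4_conc,
    normalize_series,
)
from bmscreen.screen_io import ValidationError

HALF_LOG = 10 ** 0.5
DOSES = [0.0] + sorted(10.0 / HALF_LOG ** i for i in range(8))


def _series(top, bottom, ic50, hill, doses=DOSES, noise=None):
    sig = [1e6 * logistic4_conc(c, top, bottom, ic50, hill) for c in doses]
    if noise is not None:
        sig = [s * f for s, f in zip(sig, noise)]
    return normalize_series(zip(doses, sig), compound_id="x", cell_model_id="T")


class TestNormalizeSeries:
    def test_direct_ratio(self):
        s = normalize_series([(0, 1000), (0.1, 900), (1, 500), (10, 100)])
        assert s.conc_um == (0, 0.1, 1, 10)
        assert s.viability == (1.0, 0.9, 0.5, 0.1)

    def test_all_equal_signals_give_unit_viability(self):
        s = normalize_series([(0, 5e5), (0.1, 5e5), (1, 5e5), (10, 5e5)])
        assert s.viability == (1.0, 1.0, 1.0, 1.0)

    def test_idempotent(self):
        s1 = normalize_series([(0, 1000), (0.1, 900), (1, 500), (10, 100)])
        s2 = normalize_series(zip(s1.conc_um, s1.viability))
        assert s2.viability == s1.viability

    def test_anchor_is_lowest_tested_dose_without_vehicle(self):
        s = normalize_series([(0.1, 800), (1, 400), (3, 200), (10, 100)])
        assert s.viability[0] == 1.0
        assert s.viability[1] == 0.5

    def test_duplicate_concentrations_averaged(self):
        s = normalize_series([(0, 1000), (0.1, 800), (0.1, 1000), (1, 500), (10, 100)])
        assert s.conc_um == (0, 0.1, 1, 10)
        assert s.viability[1] == pytest.approx(0.9)

    def test_nonpositive_anchor_rejected(self):
        with pytest.raises(ValidationError):
            normalize_series([(0, 0.0), (0.1, 900), (1, 500), (10, 100)])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            normalize_series([(0, 1000), (1, 500), (10, 100)])


class TestFit4PL:
    def test_noiseless_parameter_recovery_to_1e6(self):
        fit = _series(1.0, 0.0, 0.5, 1.2)
        f = fit_4pl(fit)
        assert f.converged
        assert f.top == pytest.approx(1.0, abs=1e-6)
        assert f.bottom == pytest.approx(0.0, abs=1e-6)
        assert 10 ** f.log10_ic50 == pytest.approx(0.5, abs=1e-6)
        assert f.hill == pytest.approx(1.2, abs=1e-6)
        assert f.r2 == pytest.approx(1.0, abs=1e-12)

    def test_flat_series_gets_nan_r2_sentinel(self):
        s = DoseResponseSeries("x", "T", tuple(DOSES), (1.0,) * len(DOSES))
        f = fit_4pl(s)
        assert math.isnan(f.r2)

    def test_r2_at_most_one_on_noisy_data(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            noise = np.exp(rng.normal(0, 0.1, len(DOSES)))
            f = fit_4pl(_series(1.0, 0.1, 0.3, 1.5, noise=noise))
            assert f.r2 <= 1.0

    def test_fit_invariant_to_input_order(self):
        pairs = [(c, 1e6 * logistic4_conc(c, 1.0, 0.1, 0.4, 1.3)) for c in DOSES]
        shuffled = pairs[:]
        random.Random(1).shuffle(shuffled)
        f1 = fit_4pl(normalize_series(pairs))
        f2 = fit_4pl(normalize_series(shuffled))
        assert f1 == f2

    def test_requires_four_positive_doses(self):
        s = DoseResponseSeries("x", "T", (0.0, 0.1, 1.0, 10.0), (1.0, 0.9, 0.5, 0.2))
        with pytest.raises(ValidationError):
            fit_4pl(s)

    def test_bottom_bias_shrinks_as_noise_vanishes(self):
        biases = []
        for cv in (10.0, 0.5):
            rng = np.random.default_rng(17)
            sigma = math.sqrt(math.log1p((cv / 100) ** 2))
            errs = []
            for _ in range(60):
                bottom = rng.uniform(0.0, 0.3)
                ic50 = 10 ** rng.uniform(-1.5, -0.5)
                hill = rng.uniform(0.8, 2.5)
                noise = np.exp(rng.normal(-sigma**2 / 2, sigma, len(DOSES)))
                f = fit_4pl(_series(1.0, bottom, ic50, hill, noise=noise))
                errs.append(f.bottom - bottom)
            biases.append(abs(float(np.mean(errs))))
        assert biases[1] < 0.01
        assert biases[1] <= biases[0] + 1e-6


class TestComputeAUC:
    WINDOW = (math.log10(DOSES[1]), 1.0)

    def test_no_effect_curve_gives_one(self):
        f = FitResult(1.0, 1.0, 0.0, 1.0, converged=True)
        assert compute_auc(f, *self.WINDOW) == pytest.approx(1.0)

    def test_complete_kill_curve_gives_zero(self):
        f = FitResult(0.0, 0.0, 0.0, 1.0, converged=True)
        assert compute_auc(f, *self.WINDOW) == pytest.approx(0.0)

    def test_step_at_window_midpoint_gives_half(self):
        x_min, x_max = self.WINDOW
        f = FitResult(1.0, 0.0, (x_min + x_max) / 2, 50.0, converged=True)
        assert compute_auc(f, x_min, x_max) == pytest.approx(0.5, abs=0.01)

    def test_clamped_into_unit_interval(self):
        f = FitResult(1.4, -0.1, 0.0, 0.5, converged=True)
        auc = compute_auc(f, *self.WINDOW)
        assert 0.0 <= auc <= 1.0

    @given(st.floats(0.0, 0.9), st.floats(-2.0, 1.0))
    def test_monotone_in_bottom_and_ic50(self, bottom, log_ic50):
        x_min, x_max = self.WINDOW
        base = compute_auc(FitResult(1.0, bottom, log_ic50, 1.5, True),
                           x_min, x_max, n_grid=2001)
        higher_bottom = compute_auc(FitResult(1.0, bottom + 0.1, log_ic50, 1.5, True),
                                    x_min, x_max, n_grid=2001)
        shifted_right = compute_auc(FitResult(1.0, bottom, log_ic50 + 0.5, 1.5, True),
                                    x_min, x_max, n_grid=2001)
        assert higher_bottom >= base - 1e-12
        assert shifted_right >= base - 1e-12

    def test_unconverged_fit_rejected(self):
        f = FitResult(float("nan"), float("nan"), float("nan"), float("nan"), False)
        with pytest.raises(ValidationError):
            compute_auc(f, *self.WINDOW)


def test_fit_attaches_auc_over_tested_window():
    f = fit_4pl(_series(1.0, 0.0, 0.5, 1.2))
    x_min, x_max = math.log10(DOSES[1]), math.log10(DOSES[-1])
    assert f.auc == pytest.approx(compute_auc(f, x_min, x_max), abs=1e-12)
    assert 0.0 <= f.auc <= 1.0
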