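import numpy as np
import pytest
from scipy.special import expit

import acebounds as ab
from acebounds.mechanistic import ParameterBox


@pytest.fixture
def logistic_model():
    return ab.logistic_example_model()


def h_constant_model():
    """Outcome law ignores treatment and mediator: psi_bar is identically 0."""
    return ab.MechanisticModel(
        mediator_law=lambda a, th: expit(th[0] + th[1] * a),
        outcome_law=lambda a, m, la: expit(la[0]),
        theta_space=ParameterBox.from_dict(
            {"theta0": (-np.inf, np.inf), "theta1": (-np.inf, np.inf)}
        ),
        lambda_space=ParameterBox.from_dict({"lambda0": (-np.inf, np.inf)}),
        name="h-constant",
    )


class TestParameterBox:
    def test_degenerate_entries_are_fixed(self):
        box = ParameterBox.from_dict({"x": 1.0, "y": (0.0, 2.0)})
        assert box.free.tolist() == [False, True]

    def test_rejects_inverted_interval(self):
        with pytest.raises(ValueError):
            ParameterBox.from_dict({"x": (1.0, 0.0)})

    def test_rejects_duplicate_names(self):
        with pytest.raises(ValueError):
            ParameterBox(("x", "x"), np.zeros(2), np.ones(2))

    def test_nesting_check(self):
        outer = ParameterBox.from_dict({"x": (0.0, 1.0)})
        ParameterBox.from_dict({"x": (0.2, 0.8)}).require_within(outer)
        with pytest.raises(ValueError):
            ParameterBox.from_dict({"x": (0.2, 1.5)}).require_within(outer)


class TestMuBarPsiBar:
    def test_all_half_probabilities(self, logistic_model):
        assert ab.mu_bar(logistic_model, 1, (0, 0), (0, 0, 0, 0)) == pytest.approx(0.5)

    def test_direct_evaluation(self, logistic_model):
        mu0 = ab.mu_bar(logistic_model, 0, (0, 10), (0, 0, 10, 0))
        assert mu0 == pytest.approx(expit(10) * 0.5 + 0.25, abs=1e-12)
        assert mu0 == pytest.approx(0.74998, abs=1e-4)

    def test_mediator_forced_on(self, logistic_model):
        lam = (0.3, 0.5, -0.2, 0.1)
        mu = ab.mu_bar(logistic_model, 1, (40, 40), lam)
        assert mu == pytest.approx(logistic_model.h(1, 1, lam), abs=1e-12)

    def test_psi_bar_null_model(self, logistic_model):
        assert ab.psi_bar(logistic_model, (0, 0), (0, 0, 0, 0)) == 0.0

    def test_psi_bar_example_value(self, logistic_model):
        assert ab.psi_bar(logistic_model, (0, 10), (0, 0, 10, 0)) == pytest.approx(
            0.2500, abs=1e-4
        )

    def test_outcome_without_mechanism_dependence_gives_null(self, logistic_model):
        """With no a or m dependence in the outcome law, psi_bar vanishes
        for any mediator parameters."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            theta = rng.normal(size=2) * 3
            lam = (rng.normal() * 3, 0.0, 0.0, 0.0)
            assert ab.psi_bar(logistic_model, theta, lam) == pytest.approx(0.0, abs=1e-15)

    def test_structure_encoded_by_parameters(self, logistic_model):
        """No direct effect (lambda1 = lambda3 = 0) plus no mediator shift
        (theta1 = 0) encodes the null: psi_bar = 0."""
        rng = np.random.default_rng(6)
        for _ in range(20):
            theta = (rng.normal() * 3, 0.0)
            lam = (rng.normal() * 3, 0.0, rng.normal() * 3, 0.0)
            assert ab.psi_bar(logistic_model, theta, lam) == pytest.approx(0.0, abs=1e-15)

    def test_invalid_component_rejected(self):
        bad = ab.MechanisticModel(
            mediator_law=lambda a, th: 1.5,
            outcome_law=lambda a, m, la: 0.5,
            theta_space=ParameterBox.from_dict({"t": (0, 1)}),
            lambda_space=ParameterBox.from_dict({"l": (0, 1)}),
        )
        with pytest.raises(ValueError):
            ab.mu_bar(bad, 1, [0.5], [0.5])

    def test_ranges(self, logistic_model):
        rng = np.random.default_rng(7)
        for _ in range(50):
            theta = rng.normal(size=2) * 5
            lam = rng.normal(size=4) * 5
            for a in (0, 1):
                assert 0.0 <= ab.mu_bar(logistic_model, a, theta, lam) <= 1.0
            assert -1.0 <= ab.psi_bar(logistic_model, theta, lam) <= 1.0

    def test_monte_carlo_oracle(self, logistic_model):
        """Simulating the two-stage Bernoulli mechanism reproduces mu_bar
        within 3 standard errors."""
        rng = np.random.default_rng(8)
        n = 1_000_000
        for _ in range(3):
            theta = rng.normal(size=2)
            lam = rng.normal(size=4)
            a = int(rng.integers(0, 2))
            g = logistic_model.g(a, theta)
            m = rng.uniform(size=n) < g
            py = np.where(
                m, logistic_model.h(a, 1, lam), logistic_model.h(a, 0, lam)
            )
            y = rng.uniform(size=n) < py
            est = y.mean()
            se = max(np.sqrt(est * (1 - est) / n), 1e-6)
            assert ab.mu_bar(logistic_model, a, theta, lam) == pytest.approx(
                est, abs=3 * se
            )


class TestBoundsOverBox:
    def test_point_box_collapses(self, logistic_model):
        tb = ParameterBox.from_dict({"theta0": 0.2, "theta1": 1.0})
        lb = ParameterBox.from_dict(
            {"lambda0": -0.5, "lambda1": 0.3, "lambda2": 0.7, "lambda3": 0.0}
        )
        b = ab.bounds_over_box(logistic_model, tb, lb)
        val = ab.psi_bar(logistic_model, (0.2, 1.0), (-0.5, 0.3, 0.7, 0.0))
        assert b.lower == b.upper == pytest.approx(val, abs=1e-12)

    def test_corner_matches_fine_grid_single_free(self, logistic_model):
        logistic_model.monotonicity["lambda1"] = "increasing"
        tb = ParameterBox.from_dict({"theta0": 0.0, "theta1": 0.0})
        lb = ParameterBox.from_dict(
            {"lambda0": 0.0, "lambda1": (0.0, 10.0), "lambda2": 0.0, "lambda3": 0.0}
        )
        fine = ab.bounds_over_box(logistic_model, tb, lb, "grid", 101)
        corners = ab.bounds_over_box(logistic_model, tb, lb, "corners")
        assert corners.lower == pytest.approx(fine.lower, abs=1e-9)
        assert corners.upper == pytest.approx(fine.upper, abs=1e-9)
        lo = ab.psi_bar(logistic_model, (0, 0), (0, 0, 0, 0))
        hi = ab.psi_bar(logistic_model, (0, 0), (0, 10, 0, 0))
        assert (corners.lower, corners.upper) == pytest.approx((lo, hi), abs=1e-12)

    def test_corners_require_monotonicity_declarations(self, logistic_model):
        tb = ParameterBox.from_dict({"theta0": 0.0, "theta1": (0.0, 1.0)})
        lb = ParameterBox.from_dict(
            {"lambda0": 0.0, "lambda1": 0.0, "lambda2": 0.0, "lambda3": 0.0}
        )
        with pytest.raises(ValueError, match="monotonicity"):
            ab.bounds_over_box(logistic_model, tb, lb, "corners")

    def test_corner_grid_agreement_random_monotone_boxes(self, logistic_model):
        """psi_bar is increasing in lambda1 and lambda3 for any fixed rest
        (they only enter the treated arm through expit), so corner search
        is exact over random boxes in those directions."""
        logistic_model.monotonicity.update(
            {"lambda1": "increasing", "lambda3": "increasing"}
        )
        rng = np.random.default_rng(9)
        for _ in range(10):
            t0, t1, l0, l2 = rng.normal(size=4) * 2
            lo1, hi1 = np.sort(rng.normal(size=2) * 3)
            lo3, hi3 = np.sort(rng.normal(size=2) * 3)
            tb = ParameterBox.from_dict({"theta0": t0, "theta1": t1})
            lb = ParameterBox.from_dict(
                {
                    "lambda0": l0,
                    "lambda1": (lo1, hi1),
                    "lambda2": l2,
                    "lambda3": (lo3, hi3),
                }
            )
            grid = ab.bounds_over_box(logistic_model, tb, lb, "grid", 9)
            corners = ab.bounds_over_box(logistic_model, tb, lb, "corners")
            assert corners.lower == pytest.approx(grid.lower, abs=1e-9)
            assert corners.upper == pytest.approx(grid.upper, abs=1e-9)

    def test_shrinking_box_never_widens(self, logistic_model):
        tb = ParameterBox.from_dict({"theta0": 0.0, "theta1": (0.0, 2.0)})
        lb_wide = ParameterBox.from_dict(
            {"lambda0": 0.0, "lambda1": (-2.0, 2.0), "lambda2": 1.0, "lambda3": 0.0}
        )
        lb_narrow = ParameterBox.from_dict(
            {"lambda0": 0.0, "lambda1": (-1.0, 1.0), "lambda2": 1.0, "lambda3": 0.0}
        )
        wide = ab.bounds_over_box(logistic_model, tb, lb_wide, "grid", 15)
        narrow = ab.bounds_over_box(logistic_model, tb, lb_narrow, "grid", 15)
        assert narrow.lower >= wide.lower - 1e-12
        assert narrow.upper <= wide.upper + 1e-12

    def test_box_outside_declared_space_rejected(self):
        model = ab.MechanisticModel(
            mediator_law=lambda a, th: float(np.clip(th[0], 0, 1)),
            outcome_law=lambda a, m, la: float(np.clip(la[0], 0, 1)),
            theta_space=ParameterBox.from_dict({"t": (0.0, 1.0)}),
            lambda_space=ParameterBox.from_dict({"l": (0.0, 1.0)}),
        )
        tb = ParameterBox.from_dict({"t": (0.0, 2.0)})
        lb = ParameterBox.from_dict({"l": 0.5})
        with pytest.raises(ValueError, match="declared space"):
            ab.bounds_over_box(model, tb, lb)


class TestVacuousnessDiagnostic:
    def test_logistic_model_vacuous_compatible(self, logistic_model):
        rep = ab.vacuousness_diagnostic(logistic_model, with_components=False)
        assert rep.verdict == "vacuous-compatible"
        assert rep.achieved_min <= -0.99
        assert rep.achieved_max >= 0.99

    def test_h_constant_restriction_non_vacuous(self):
        rep = ab.vacuousness_diagnostic(h_constant_model(), with_components=False)
        assert rep.verdict == "non-vacuous-evidence"
        assert rep.achieved_min == pytest.approx(0.0, abs=1e-9)
        assert rep.achieved_max == pytest.approx(0.0, abs=1e-9)

    def test_component_envelopes_reported(self, logistic_model):
        rep = ab.vacuousness_diagnostic(
            logistic_model, magnitude_schedule=(10.0,), with_components=True
        )
        lo, hi = rep.component_envelopes["g(a=1)"]
        assert lo < 0.01 and hi > 0.99
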