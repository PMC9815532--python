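import numpy as np
import pytest
from scipy.integrate import quad

from eldercare_game import (
    StrategyProfile,
    classify_equilibrium,
    corner_jacobian,
    corner_name,
    enumerate_corner_equilibria,
    incentive_difference,
    penalty_threshold_Fs,
    replicator_rhs,
    reports_to_frame,
    stability_report,
    strategy_volumes,
    subsidy_threshold_S,
    superior_penalty_threshold_Fg,
    table_eigenvalues,
    threshold_w0,
    threshold_w1,
    threshold_x0,
)
from eldercare_game.equilibrium_stability import CORNER_ORDER, DegenerateThresholdError
from eldercare_game.parameters import sample_admissible_parameters
from eldercare_game.payoff_engine import Player


class TestCornerEnumeration:
    def test_census(self):
        corners = enumerate_corner_equilibria()
        assert len(corners) == 16
        assert len(set(tuple(c) for c in corners)) == 16
        assert all(c.is_corner() for c in corners)

    def test_named_endpoints(self):
        corners = enumerate_corner_equilibria()
        assert tuple(corners[0]) == (0, 0, 0, 0) and corner_name(corners[0]) == "E1"
        assert tuple(corners[15]) == (1, 1, 1, 1) and corner_name(corners[15]) == "E16"
        assert corner_name(StrategyProfile(1, 1, 0, 1)) == "E13"

    def test_all_are_fixed_points(self, baseline):
        for corner in enumerate_corner_equilibria():
            assert np.all(replicator_rhs(baseline, corner).as_array() == 0.0)


class TestCornerJacobian:
    def test_baseline_e13_is_attracting(self, baseline):
        jac = corner_jacobian(baseline, StrategyProfile(1, 1, 0, 1))
        assert np.diag(jac) == pytest.approx([-27.0, -27.0, -10.0, -2.0])
        assert np.all(jac[~np.eye(4, dtype=bool)] == 0.0)

    def test_baseline_e15_third_eigenvalue_is_plus_cg(self, baseline):
        jac = corner_jacobian(baseline, StrategyProfile(1, 0, 1, 1))
        assert jac[2, 2] == pytest.approx(10.0)

    def test_rejects_interior_states(self, baseline):
        with pytest.raises(ValueError, match="corner"):
            corner_jacobian(baseline, StrategyProfile(0.5, 1, 0, 1))

    def test_matches_finite_difference_jacobian(self, rng):
        h = 1e-6
        for _ in range(10):
            p = sample_admissible_parameters(rng)
            for name, coords in CORNER_ORDER[::3]:
                corner = StrategyProfile(*map(float, coords))
                exact = corner_jacobian(p, corner)
                arr = corner.as_array()
                fd = np.empty((4, 4))
                for j in range(4):
                    up, dn = arr.copy(), arr.copy()
                    up[j] += h
                    dn[j] -= h
                    fd[:, j] = (
                        replicator_rhs(p, StrategyProfile.from_array(up)).as_array()
                        - replicator_rhs(p, StrategyProfile.from_array(dn)).as_array()
                    ) / (2 * h)
                scale = max(1.0, np.abs(exact).max())
                assert fd == pytest.approx(exact, abs=1e-4 * scale)

    def test_matches_tabulated_eigenvalue_expressions(self, rng):
        """The Jacobian diagonal reproduces the tabulated symbolic
        eigenvalues at every corner for random admissible parameters."""
        for _ in range(100):
            p = sample_admissible_parameters(rng)
            for name, coords in CORNER_ORDER:
                corner = StrategyProfile(*map(float, coords))
                got = np.diag(corner_jacobian(p, corner))
                assert got == pytest.approx(
                    np.array(table_eigenvalues(p, name)), abs=1e-9
                ), name


class TestClassification:
    @pytest.mark.parametrize(
        "eigs, label",
        [
            ((-27, -27, -10, -2), "ESS"),
            ((-1, -1, 10, -2), "unstable"),
            ((0.0, -1, -1, -1), "indeterminate"),
            ((-1e-12, -1, -1, -1), "indeterminate"),
        ],
    )
    def test_labels(self, eigs, label):
        assert classify_equilibrium(eigs, tol=1e-9) == label

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            classify_equilibrium((np.nan, 0, 0, 0))


@pytest.fixture(scope="module")
def reports():
    from eldercare_game import make_baseline_parameters

    return stability_report(make_baseline_parameters(), n_draws=1000, seed=7)


class TestStabilityReport:
    def test_unique_baseline_ess(self, reports):
        ess = [r for r in reports if r.label == "ESS"]
        assert len(ess) == 1
        assert tuple(ess[0].corner) == (1, 1, 0, 1)
        assert ess[0].name == "E13"

    def test_always_unstable_corners(self, reports):
        flagged = {r.name for r in reports if r.always_unstable}
        assert flagged == {"E7", "E8", "E15", "E16"}

    def test_frame_export(self, reports):
        frame = reports_to_frame(reports)
        assert len(frame) == 16
        assert list(frame.name) == [name for name, _ in CORNER_ORDER]
        assert frame.loc[frame.name == "E13", "label"].item() == "ESS"


class TestThresholds:
    def test_w0_examples(self, baseline):
        res = threshold_w0(baseline, y=0.0, z=0.0)
        assert res.value == pytest.approx(22.6 / 39.9, abs=1e-9)
        assert threshold_w0(baseline, y=1.0, z=1.0).value < 0.0

    def test_w1_examples(self, baseline):
        res = threshold_w1(baseline, x=1.0, z=0.0)
        assert res.value == pytest.approx(-6.1 / 20.9, abs=1e-9)
        assert threshold_w1(baseline, x=0.0, z=1.0).value < res.value

    def test_x0_examples(self, baseline):
        assert threshold_x0(baseline, y=1.0).value == pytest.approx(0.5)
        assert threshold_x0(baseline, y=0.0).value == pytest.approx(
            1.0 - 10.0 / 26.75, abs=1e-9
        )

    def test_penalty_threshold_fs(self, baseline):
        res = penalty_threshold_Fs(baseline, w=0.0, y=0.0, z=0.0)
        assert res.value == pytest.approx(2280.0, abs=1e-6)
        higher_w = penalty_threshold_Fs(baseline, w=0.5, y=0.0, z=0.0)
        assert higher_w.value < res.value  # more online evaluation, smaller fine needed
        with pytest.raises(DegenerateThresholdError):
            penalty_threshold_Fs(baseline.replace(beta=0.0), w=0.0, y=0.0, z=0.0)

    def test_subsidy_threshold_s(self, baseline):
        res = subsidy_threshold_S(baseline, w=1.0, x=1.0, z=1.0)
        assert res.value == pytest.approx(-17.0, abs=1e-9)
        lower_x = subsidy_threshold_S(baseline, w=1.0, x=0.0, z=1.0)
        assert lower_x.value < res.value  # S' increases with x

    def test_superior_penalty_threshold_fg(self, baseline):
        res = superior_penalty_threshold_Fg(baseline, x=0.0, y=0.0)
        assert res.value == pytest.approx(-1475.0, abs=1e-6)
        costly = superior_penalty_threshold_Fg(
            baseline.replace(Cg=20.0), x=0.0, y=0.0
        )
        assert costly.value > res.value  # Fg' increases with Cg
        with pytest.raises(DegenerateThresholdError):
            superior_penalty_threshold_Fg(baseline, x=1.0, y=0.0)

    def test_every_threshold_zeroes_its_incentive(self, rng):
        for _ in range(50):
            p = sample_admissible_parameters(rng)
            x, y, z, w = rng.uniform(size=4)
            res = threshold_w0(p, y, z)
            assert incentive_difference(
                p, StrategyProfile(0, y, z, res.value), Player.PROVIDER
            ) == pytest.approx(0.0, abs=1e-9 * max(1, abs(res.value)))
            res = threshold_w1(p, x, z)
            assert incentive_difference(
                p, StrategyProfile(x, 0, z, res.value), Player.PLATFORM
            ) == pytest.approx(0.0, abs=1e-9 * max(1, abs(res.value)))
            res = threshold_x0(p, y)
            assert incentive_difference(
                p, StrategyProfile(res.value, y, 0, 0), Player.GOVERNMENT
            ) == pytest.approx(0.0, abs=1e-9 * max(1, abs(res.value)))
            res = penalty_threshold_Fs(p, w, y, z)
            assert incentive_difference(
                p.replace(Fs=res.value), StrategyProfile(0, y, z, w), Player.PROVIDER
            ) == pytest.approx(0.0, abs=1e-9 * max(1, abs(res.value)))
            res = subsidy_threshold_S(p, w, x, z)
            assert incentive_difference(
                p.replace(S=res.value), StrategyProfile(x, 0, z, w), Player.PLATFORM
            ) == pytest.approx(0.0, abs=1e-9 * max(1, abs(res.value)))
            if x < 0.99 and y < 0.99:
                res = superior_penalty_threshold_Fg(p, x, y)
                assert incentive_difference(
                    p.replace(Fg=res.value), StrategyProfile(x, y, 0, 0),
                    Player.GOVERNMENT,
                ) == pytest.approx(0.0, abs=1e-9 * max(1, abs(res.value)))


def _quadrature_volume(p, which, y=None, z=None):
    g = p.gamma
    if which == "provider":
        def w0(zv):
            a = p.Csh - p.Csl - p.Is * g - p.Ds * g - y * p.Io - p.beta * (1 - y) * (p.Fs + p.Io)
            b = (1 - y) * (p.beta * p.Fs + p.beta * p.Io - p.Io) - p.Fs
            return (a + b * zv) / ((1 - g) * (p.Is + p.Ds))

        return quad(w0, 0, 1)[0]
    if which == "platform":
        def w1(xv):
            c = p.Cei - p.S - p.Ie * g - p.De * g
            d = z * p.Fe + (1 - z) * p.beta * p.Fe
            return (c - d + d * xv) / ((1 - g) * (p.Ie + p.De))

        return quad(w1, 0, 1)[0]
    if which == "government":
        m = p.Fe - p.beta * p.Fs - p.beta * p.Fe + p.beta * p.Fg

        def x0(yv):
            return 1 - p.Cg / (p.Fs + (1 - yv) * m)

        return quad(x0, 0, 1)[0]  # this is Vz1
    raise ValueError(which)


class TestStrategyVolumes:
    def test_government_baseline(self, baseline):
        vol = strategy_volumes(baseline, "government")
        assert vol.v0 == pytest.approx(0.430818, abs=1e-6)
        assert vol.v1 == pytest.approx(0.569182, abs=1e-6)

    def test_provider_baseline(self, baseline):
        vol = strategy_volumes(baseline, "provider", y=0.0)
        assert vol.v0 == pytest.approx(15.5 / 79.8, abs=1e-9)

    def test_platform_negative_raw_clamps_to_zero(self, baseline):
        vol = strategy_volumes(baseline, "platform", z=0.0)
        assert vol.v0 < 0.0
        assert vol.v0_clamped == 0.0 and vol.v1_clamped == 1.0

    def test_raw_pair_sums_to_one(self, rng):
        for _ in range(20):
            p = sample_admissible_parameters(rng)
            for which, kwargs in (
                ("provider", {"y": float(rng.uniform())}),
                ("platform", {"z": float(rng.uniform())}),
                ("government", {}),
            ):
                vol = strategy_volumes(p, which, **kwargs)
                assert vol.v0 + vol.v1 == pytest.approx(1.0, abs=1e-12)
                assert 0.0 <= vol.v0_clamped <= 1.0

    def test_closed_forms_match_quadrature(self, baseline, rng):
        params = [baseline] + [sample_admissible_parameters(rng) for _ in range(20)]
        for p in params:
            y, z = rng.uniform(size=2)
            assert strategy_volumes(p, "provider", y=y).v0 == pytest.approx(
                _quadrature_volume(p, "provider", y=y), abs=1e-6
            )
            assert strategy_volumes(p, "platform", z=z).v0 == pytest.approx(
                _quadrature_volume(p, "platform", z=z), abs=1e-6
            )
            assert strategy_volumes(p, "government").v1 == pytest.approx(
                _quadrature_volume(p, "government"), abs=1e-6
            )

    def test_government_small_m_limit(self, baseline):
        # m -> 0 by cancelling the fine terms; the volume tends to 1 - Cg/Fs.
        p = baseline.replace(Fe=0.0, Fg=baseline.Fs)  # m = -bFs - 0 + bFs = 0
        vol = strategy_volumes(p, "government")
        assert vol.v1 == pytest.approx(1 - p.Cg / p.Fs, abs=1e-9)
        with pytest.raises(DegenerateThresholdError):
            strategy_volumes(baseline.replace(Fs=0.0), "government")

    def test_provider_volume_monotonicity(self, baseline):
        """High-quality mass shrinks with the cost gap and grows with
        reputation stakes and fines."""
        v1 = strategy_volumes(baseline, "provider", y=0.0).v1
        assert strategy_volumes(
            baseline.replace(Csh=55.0), "provider", y=0.0
        ).v1 < v1
        for name in ("Is", "Ds", "Fs"):
            bumped = baseline.replace(**{name: getattr(baseline, name) * 1.2})
            assert strategy_volumes(bumped, "provider", y=0.0).v1 > v1, name

    def test_platform_volume_monotonicity(self, baseline):
        v1 = strategy_volumes(baseline, "platform", z=0.5).v1
        assert strategy_volumes(
            baseline.replace(Cei=8.0), "platform", z=0.5
        ).v1 < v1
        for name in ("beta", "Fe"):
            bumped = baseline.replace(**{name: getattr(baseline, name) * 1.2})
            assert strategy_volumes(bumped, "platform", z=0.5).v1 > v1, name
        # Reputation raises the positive-visit mass whenever the raw
        # negative-visit volume is a genuine probability (2c - d > 0); at
        # baseline it is already negative and the clamped mass stays at 1.
        assert strategy_volumes(baseline, "platform", z=0.5).v1_clamped == 1.0
        costly = baseline.replace(Cei=30.0)  # c > 0: visits genuinely costly
        v1 = strategy_volumes(costly, "platform", z=0.5).v1
        assert 0.0 < strategy_volumes(costly, "platform", z=0.5).v0 < 1.0
        for name in ("Ie", "De"):
            bumped = costly.replace(**{name: getattr(costly, name) * 1.2})
            assert strategy_volumes(bumped, "platform", z=0.5).v1 > v1, name

    def test_government_volume_decreases_in_regulation_cost(self, baseline):
        # Fg = 200 > Fs = 20 at baseline, the regime where the claim holds.
        v1 = strategy_volumes(baseline, "government").v1
        assert strategy_volumes(baseline.replace(Cg=12.0), "government").v1 < v1
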