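"""Sobol analysis: ranges, Saltelli design, estimators vs analytic oracles."""

import numpy as np
import pytest

import magbone as mb
from magbone.sensitivity import (
    classify_influential,
    make_ranges,
    model_output_scalar,
    pooled_ranges,
    saltelli_sample,
    sobol_indices,
)


class TestRanges:
    def test_basic_arithmetic(self):
        r = make_ranges({"k": 10.0})
        assert r["k"] == pytest.approx((8.0, 12.0))

    def test_table_optimum_example(self):
        r = make_ranges({"r_prime": 0.062})
        assert r["r_prime"][0] == pytest.approx(0.0496)
        assert r["r_prime"][1] == pytest.approx(0.0744)

    def test_zero_width_rejected(self):
        with pytest.raises(ValueError):
            make_ranges({"k": 1.0}, fraction=0.0)

    def test_zero_optimum_expands_with_scale(self):
        r = make_ranges({"k": 0.0}, fraction=0.2, zero_scale=5.0)
        assert r["k"] == (0.0, 1.0)

    def test_pooled_ranges_span_both_optima(self):
        r = pooled_ranges([{"r_prime": 1.104}, {"r_prime": 0.062}])
        assert r["r_prime"][0] == pytest.approx(0.062 * 0.8)
        assert r["r_prime"][1] == pytest.approx(1.104 * 1.2)


class TestSaltelliDesign:
    def test_size_formula(self):
        X = saltelli_sample({"a": (0, 1), "b": (2, 3)}, n_base=4, seed=0)
        assert X.shape == (4 * (2 + 2), 2)

    def test_rows_within_box_and_deterministic(self):
        ranges = {"a": (0.5, 1.5), "b": (-2.0, -1.0), "c": (10.0, 20.0)}
        X1 = saltelli_sample(ranges, n_base=16, seed=3)
        X2 = saltelli_sample(ranges, n_base=16, seed=3)
        lo = np.array([r[0] for r in ranges.values()])
        hi = np.array([r[1] for r in ranges.values()])
        assert np.all(X1 >= lo) and np.all(X1 <= hi)
        assert np.array_equal(X1, X2)


class TestEstimators:
    def _run(self, f, ranges, n_base=1024, seed=0):
        X = saltelli_sample(ranges, n_base, seed=seed)
        y = np.apply_along_axis(f, 1, X)
        return sobol_indices(y, d=len(ranges), n_base=n_base, names=list(ranges), seed=seed)

    def test_single_factor_model(self):
        res = self._run(lambda x: x[0], {"x1": (0.0, 1.0), "x2": (0.0, 1.0)})
        assert res.Si[0] == pytest.approx(1.0, abs=0.05)
        assert abs(res.Si[1]) < 0.05
        assert res.STi[1] < 0.05

    def test_additive_model_no_interactions(self):
        res = self._run(lambda x: x[0] + x[1], {"x1": (0.0, 1.0), "x2": (0.0, 1.0)})
        assert np.allclose(res.Si, res.STi, atol=0.05)
        assert res.Si.sum() == pytest.approx(1.0, abs=0.08)

    def test_ishigami_against_closed_form(self):
        """Standard Ishigami benchmark (a=7, b=0.1) vs analytic indices."""
        a, b = 7.0, 0.1
        rng = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}

        def ishigami(x):
            return np.sin(x[0]) + a * np.sin(x[1]) ** 2 + b * x[2] ** 4 * np.sin(x[0])

        V = a**2 / 8 + b * np.pi**4 / 5 + b**2 * np.pi**8 / 18 + 0.5
        S1 = (0.5 * (1 + b * np.pi**4 / 5) ** 2) / V
        S2 = (a**2 / 8) / V
        res = self._run(ishigami, rng, n_base=2**10, seed=5)
        assert res.Si[0] == pytest.approx(S1, abs=0.05)
        assert res.Si[1] == pytest.approx(S2, abs=0.05)
        assert res.Si[2] == pytest.approx(0.0, abs=0.05)
        assert np.all(res.STi >= res.Si - 0.05)

    def test_ishigami_against_scipy_estimator(self):
        """Cross-check our Saltelli estimators against an independent one."""
        from scipy.stats import sobol_indices as scipy_sobol
        from scipy.stats import uniform

        a, b = 7.0, 0.1

        def ishigami_vec(x):
            return np.sin(x[0]) + a * np.sin(x[1]) ** 2 + b * x[2] ** 4 * np.sin(x[0])

        ref = scipy_sobol(
            func=ishigami_vec,
            n=2**10,
            dists=[uniform(loc=-np.pi, scale=2 * np.pi)] * 3,
            rng=np.random.default_rng(1),
        )
        rng = {f"x{i}": (-np.pi, np.pi) for i in (1, 2, 3)}
        res = self._run(lambda x: ishigami_vec(x), rng, n_base=2**10, seed=5)
        assert np.allclose(res.Si, ref.first_order, atol=0.06)
        assert np.allclose(res.STi, ref.total_order, atol=0.06)

    def test_constant_model_rejected(self):
        X = saltelli_sample({"a": (0, 1)}, n_base=8, seed=0)
        with pytest.raises(ValueError):
            sobol_indices(np.ones(len(X)), d=1, n_base=8)


class TestClassification:
    @pytest.mark.parametrize(
        "si, sti, expected",
        [(0.06, 0.0, True), (0.01, 0.05, False), (0.01, 0.2, True)],
    )
    def test_thresholds(self, si, sti, expected):
        flags = classify_influential({"p": si}, {"p": sti})
        assert flags["p"] is expected


class TestScalarization:
    def test_modes(self):
        v = np.array([1.0, 2.0, 3.0])
        assert model_output_scalar(v) == 2.0
        assert model_output_scalar(v, "final") == 3.0
        assert model_output_scalar(v, "l2") == pytest.approx(np.sqrt(14))
        with pytest.raises(ValueError):
            model_output_scalar(v, "max")


class TestVolumeLossApplication:
    def test_dprime_dominates_rprime(self):
        """Around the pooled Mg optima the precipitation parameter drives
        most of the volume-loss variance (first-order Si of d' > Si of r')."""
        optima = [
            {"r_prime": 1.104, "d_prime": 0.040},
            {"r_prime": 0.062, "d_prime": 0.068},
        ]
        ranges = pooled_ranges(optima, fraction=0.2)
        X = saltelli_sample(ranges, n_base=1024, seed=2)
        grid = np.array(mb.study1_design().grids["vloss"])
        y = np.array([
            model_output_scalar(mb.volume_loss(
                mb.DegradationParams("surface_rate", r_prime=row[0], d_prime=row[1]), grid))
            for row in X
        ])
        res = sobol_indices(y, d=2, n_base=1024, names=list(ranges), seed=2)
        si = dict(zip(res.names, res.Si))
        assert si["d_prime"] > si["r_prime"]
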