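"""Loss functions, bounds, and small-scale optimization behavior."""

import numpy as np
import pandas as pd
import pytest

import magbone as mb
from magbone.calibration import (
    LossSpec,
    check_within_bounds,
    loss_bvtv_cwidth,
    loss_lattice,
    loss_volume,
    optimize,
    param_bounds,
)
from magbone.optim import OptimizerConfig, lhs_init


def _dataset(rows):
    df = pd.DataFrame(rows, columns=["material", "variable", "time_days", "median", "sd", "n"])
    return mb.StudyDataset(df)


class TestBounds:
    def test_material_conditional_ranges(self):
        ti, mg = param_bounds("Ti"), param_bounds("Mg-10Gd")
        assert ti["k3"] == (0.1, 10.0) and mg["k3"] == (1.0, 30.0)
        assert ti["k6"] == (1.0, 3.0) and mg["k6"] == (1.0, 5.0)
        assert ti["r_prime"] == mg["r_prime"] == (0.0001, 1.2)

    def test_printed_optima_lie_inside_bounds(self, truth):
        check_within_bounds(
            {"k1": 0.3880, "v1": 0.0164, "r1": 0.4915, "r2": 23.1846, "k3": 0.5744},
            "Ti",
        )
        with pytest.raises(ValueError):
            check_within_bounds({"k3": 50.0}, "Mg-10Gd")


class TestLosses:
    def test_perfect_model_zero_loss(self, truth, noise_free_study):
        ti = truth["Ti"]
        val = loss_bvtv_cwidth(ti.rem, ti.ultra["310"], None, noise_free_study, "Ti",
                               LossSpec(), rtol=1e-8, atol=1e-10)
        assert val == pytest.approx(0.0, abs=1e-7)

    def test_single_residual_arithmetic(self, truth):
        # one BV/TV point with residual 2 and unit weight -> loss 4
        ti = truth["Ti"]
        grid = np.linspace(0, 56, 57)
        traj = mb.simulate(ti.rem, grid, ultra=ti.ultra["310"])
        h28 = float(np.interp(28.0, grid, traj.data["H"]))
        ds = _dataset([("Ti", "bvtv", 28.0, h28 + 2.0, 0.0, 6)])
        val = loss_bvtv_cwidth(ti.rem, ti.ultra["310"], None, ds, "Ti", LossSpec())
        assert val == pytest.approx(4.0, rel=1e-4)

    def test_regularization_plug_in(self, truth):
        # zero residuals but k3 = 10, v1 = 1 under (0.001, 0.01) ridge -> 0.11
        rem = mb.RemodellingParams(k1=0.3880, v1=1.0, r1=0.4915, r2=23.1846, k3=10.0)
        grid = np.linspace(0, 56, 57)
        traj = mb.simulate(rem, grid, ultra=truth["Ti"].ultra["310"])
        h28 = float(np.interp(28.0, grid, traj.data["H"]))
        ds = _dataset([("Ti", "bvtv", 28.0, h28, 0.0, 6)])
        val = loss_bvtv_cwidth(rem, truth["Ti"].ultra["310"], None, ds, "Ti",
                               LossSpec(lambda_k=0.001, lambda_v=0.01))
        assert val == pytest.approx(0.11, abs=1e-5)

    def test_artificial_point_pulls_loss_up(self, truth):
        # a model whose H is already high at t = 3 d is penalized by the
        # artificial early-time point
        ti = truth["Ti"]
        grid = np.linspace(0, 56, 57)
        traj = mb.simulate(ti.rem, grid, ultra=ti.ultra["310"], H0=0.4)
        h28 = float(np.interp(28.0, grid, traj.data["H"]))
        ds = _dataset([("Ti", "bvtv", 28.0, h28, 0.0, 6)])
        with_art = loss_bvtv_cwidth(ti.rem, ti.ultra["310"], None, ds, "Ti",
                                    LossSpec(artificial_points=((3.0, 0.0),)), H0=0.4)
        without = loss_bvtv_cwidth(ti.rem, ti.ultra["310"], None, ds, "Ti",
                                   LossSpec(), H0=0.4)
        assert with_art > without + 0.05

    def test_volume_loss_values(self, deg_mg10):
        t = np.array([10.0, 50.0])
        v = mb.volume_loss(deg_mg10, t)
        ds = _dataset([("Mg-10Gd", "vloss", 10.0, v[0], 0.0, 6),
                       ("Mg-10Gd", "vloss", 50.0, v[1] + 0.1, 0.0, 6)])
        assert loss_volume(deg_mg10, ds, "Mg-10Gd") == pytest.approx(0.005, rel=1e-10)

    def test_lattice_loss_zero_at_truth(self, truth, noise_free_study):
        mg = truth["Mg-10Gd"]
        for plane in ("310", "002"):
            val = loss_lattice(mg.ultra[plane], mg.deg, noise_free_study, "Mg-10Gd", plane)
            assert val == pytest.approx(0.0, abs=1e-10)

    def test_empty_dataset_rejected(self, truth, deg_mg10):
        empty = _dataset([])
        with pytest.raises(ValueError):
            loss_volume(deg_mg10, empty, "Mg-10Gd")
        with pytest.raises(ValueError):
            loss_bvtv_cwidth(truth["Ti"].rem, truth["Ti"].ultra["310"], None,
                             empty, "Ti", LossSpec())


class TestOptimize:
    def test_quadratic_bowl_named_params(self):
        loss = lambda th: (th["a"] - 2.0) ** 2 + (th["b"] - 30.0) ** 2 / 100
        bounds = {"a": (0.0, 5.0), "b": (1.0, 1000.0)}
        fit = optimize(loss, bounds, lhs_init(bounds, 3, seed=0),
                       OptimizerConfig(max_iter=200), seed=1)
        assert fit.params["a"] == pytest.approx(2.0, abs=1e-3)
        assert fit.params["b"] == pytest.approx(30.0, abs=0.5)
        assert fit.loss == min(min(s["loss"] for s in fit.starts), fit.loss)

    def test_deterministic_given_seeds(self):
        loss = lambda th: (th["a"] - 0.5) ** 2
        bounds = {"a": (0.0, 1.0)}
        fits = [optimize(loss, bounds, lhs_init(bounds, 2, seed=3),
                         OptimizerConfig(max_iter=60), seed=4) for _ in range(2)]
        assert fits[0].params == fits[1].params and fits[0].loss == fits[1].loss

    def test_degradation_self_consistency(self, noise_free_study, deg_mg10):
        """Refit on data generated by the model: loss at the refit never
        exceeds the loss at the generating parameters."""
        bounds = {k: param_bounds("Mg-10Gd")[k] for k in ("r_prime", "d_prime")}

        def loss(th):
            d = mb.DegradationParams("surface_rate", r_prime=max(th["r_prime"], 1e-12),
                                     d_prime=max(th["d_prime"], 1e-12))
            return loss_volume(d, noise_free_study, "Mg-10Gd")

        fit = optimize(loss, bounds, lhs_init(bounds, 3, seed=5),
                       OptimizerConfig(max_iter=150), seed=6)
        loss_truth = loss({"r_prime": 0.062, "d_prime": 0.068})
        assert fit.loss <= loss_truth + 1e-12
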