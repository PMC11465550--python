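"""Numerical simulation and least-squares estimation."""

import numpy as np
import pandas as pd
import pytest

import odeident as oi
from odeident.fitting import OdeMLE, fit, objective
from odeident.model import Dataset
from odeident.simulate import SimulationError, simulate


def closed_form_model1(p, times):
    """Analytic solution of the linear two-state regulation model."""
    k1, k2, k3, k4 = p["k1"], p["k2"], p["k3"], p["k4"]
    m0, pr0 = 2.5, 6.5
    mss = k1 / k2
    mrna = mss + (m0 - mss) * np.exp(-k2 * times)
    # protein: dP/dt = k3 m(t) - k4 P  (k2 != k4 assumed in the test point)
    pss = k3 * mss / k4
    a = k3 * (m0 - mss) / (k4 - k2)
    prot = pss + a * np.exp(-k2 * times) + (pr0 - pss - a) * np.exp(-k4 * times)
    return mrna, prot


class TestSimulate:
    def test_matches_closed_form_linear_solution(self, m1_both):
        p = {"k1": 0.3, "k2": 0.45, "k3": 0.2, "k4": 0.8}
        times = np.linspace(0, 25, 60)
        traj = simulate(m1_both, p, times)
        mrna, prot = closed_form_model1(p, times)
        np.testing.assert_allclose(traj.outputs["mRNA"], mrna, rtol=1e-6)
        np.testing.assert_allclose(traj.outputs["Protein"], prot, rtol=1e-6)

    def test_single_time_zero_returns_initial_conditions(self, m1_both, m2, p1):
        traj = simulate(m1_both, p1, [0.0])
        np.testing.assert_array_equal(traj.states[0], [2.5, 6.5])
        traj2 = simulate(m2, oi.reference_params("model2"), [0.0])
        np.testing.assert_array_equal(traj2.states[0], [1.01, 3.98, 0.46])

    def test_washout_without_cells_relaxes_glucose_to_feed(self):
        """With X(0) = 0 the culture never grows and the glucose ODE is
        linear: X stays 0 and glucose approaches the feed concentration."""
        import odeident.model as om

        m2 = oi.model2("original")  # GF = 7 mM
        init = dict(m2.init)
        init[[s for s in m2.states if str(s) == "X"][0]] = 0.0
        m = om.OdeModel(
            name=m2.name, states=m2.states, params=m2.params, rhs=m2.rhs,
            outputs=dict(m2.outputs), init=init, constants=dict(m2.constants),
        )
        p = oi.reference_params("model2")
        traj = simulate(m, p, np.linspace(0, 600, 50))
        assert np.all(traj.outputs["X"] == 0)
        assert traj.outputs["Glucose"][-1] == pytest.approx(7.0, rel=1e-3)

    def test_nonfinite_blowup_is_reported_with_time(self):
        m = oi.parse_model(
            "states: [x]\nparameters: [k]\nodes: {x: k*x^2}\n"
            "outputs: {x: x}\ninit: {x: 1.0}\n"
        )
        with pytest.raises(SimulationError, match="t ="):
            simulate(m, {"k": 1.0}, np.linspace(0, 10, 30))

    def test_times_must_start_at_or_after_zero(self, m1_both, p1):
        with pytest.raises(ValueError):
            simulate(m1_both, p1, [-1.0, 0.0, 1.0])


class TestObjective:
    def test_zero_for_noise_free_data_at_generating_point(self, m1_both, p1):
        design = oi.Design(
            times=np.linspace(1, 10, 10),
            observables=["mRNA", "Protein"],
            sigma=1.0,
        )
        clean = oi.generate(m1_both, p1, design, seed=0)
        clean.frame["value"] = (
            simulate(m1_both, p1, np.unique(np.r_[0.0, clean.frame["time"]]))
            .as_frame()
            .pipe(lambda df: _lookup(df, clean.frame))
        )
        assert objective(m1_both, p1, clean) == pytest.approx(0.0, abs=1e-12)

    def test_single_record_weighted_square(self, m1_both, p1):
        traj = simulate(m1_both, p1, [0.0, 2.0])
        y = traj.outputs["mRNA"][1]
        data = Dataset(pd.DataFrame(
            {"time": [2.0], "observable": ["mRNA"], "value": [y + 0.3], "sigma": [0.15]}
        ))
        assert objective(m1_both, p1, data) == pytest.approx((0.3 / 0.15) ** 2, rel=1e-6)

    def test_equals_brute_force_record_loop(self, m1_both, p1, model1_data):
        """Independent oracle: explicit per-record summation."""
        total = 0.0
        for _, row in model1_data.frame.iterrows():
            traj = simulate(m1_both, p1, [0.0, row["time"]])
            resid = row["value"] - traj.outputs[row["observable"]][-1]
            total += (resid / row["sigma"]) ** 2
        assert objective(m1_both, p1, model1_data) == pytest.approx(total, rel=1e-8)

    def test_chi_square_mean_at_generating_parameters(self, m1_both, p1):
        """At the truth with correct sigmas, the objective is a chi-square
        variable with one term per record: its average over replicates is
        the record count."""
        design = oi.Design(
            times=np.linspace(1, 15, 8), observables=["mRNA", "Protein"]
        )
        R, vals = 120, []
        for seed in range(R):
            data = oi.generate(m1_both, p1, design, seed=seed)
            vals.append(objective(m1_both, p1, data))
        n_records = 16
        # mean of chi2_n over R replicates: sd = sqrt(2 n / R)
        assert np.mean(vals) == pytest.approx(n_records, abs=4 * np.sqrt(2 * n_records / R))


def _lookup(traj_frame, records):
    out = []
    tf = traj_frame.set_index("time")
    for _, row in records.iterrows():
        out.append(tf.loc[row["time"], f"output:{row['observable']}"])
    return out


class TestFit:
    def test_noise_free_data_init_at_truth(self, m1_both, p1):
        design = oi.Design(
            times=np.linspace(1, 15, 12), observables=["mRNA", "Protein"], sigma=1e-12
        )
        clean = oi.generate(m1_both, p1, design, seed=0)
        clean.frame["sigma"] = 0.05
        res = fit(m1_both, clean, init=p1, n_starts=1)
        assert res.objective < 1e-10
        for k, v in p1.items():
            assert res.estimate[k] == pytest.approx(v, rel=1e-4)

    def test_recovers_truth_from_perturbed_start(self, m1_both, p1):
        """Noise-free data, init off by x10 per parameter, 20 starts."""
        design = oi.Design(
            times=np.linspace(0.5, 20, 16), observables=["mRNA", "Protein"], sigma=1e-9
        )
        data = oi.generate(m1_both, p1, design, seed=4)
        data.frame["sigma"] = 0.05  # weighting only; the values are noise-free
        init = {k: v * 10 for k, v in p1.items()}
        bounds = {k: (v * 1e-3, v * 1e3) for k, v in p1.items()}
        res = fit(m1_both, data, init=init, bounds=bounds, n_starts=20, seed=2)
        for k, v in p1.items():
            assert res.estimate[k] == pytest.approx(v, rel=0.01), k

    def test_estimates_sharpen_with_sample_size(self, m1_both, p1):
        """Median relative estimation error shrinks from n=10 to n=100."""
        errs = {}
        for n in (10, 100):
            rel = []
            for seed in range(12):
                design = oi.Design(
                    times=np.linspace(0.5, 20, n), observables=["mRNA", "Protein"]
                )
                data = oi.generate(m1_both, p1, design, seed=seed)
                res = fit(m1_both, data, init=p1, n_starts=1)
                rel.append(np.median([abs(res.estimate[k] - v) / v for k, v in p1.items()]))
            errs[n] = np.median(rel)
        assert errs[100] < errs[10]

    def test_deterministic_given_seed(self, m1_both, p1, model1_data):
        a = fit(m1_both, model1_data, init={k: v * 3 for k, v in p1.items()},
                n_starts=5, seed=42)
        b = fit(m1_both, model1_data, init={k: v * 3 for k, v in p1.items()},
                n_starts=5, seed=42)
        assert a.estimate == b.estimate and a.objective == b.objective

    def test_objective_nonnegative_with_sigmas(self, model1_fit):
        assert model1_fit.objective >= 0
        for k, (lo, hi) in model1_fit.bounds.items():
            assert lo <= model1_fit.estimate[k] <= hi

    def test_profiled_sigma_path_without_sigma_column(self, m1_both, p1):
        design = oi.Design(times=np.linspace(1, 15, 10), observables=["mRNA"])
        data = oi.generate(m1_both, p1, design, seed=1)
        data.frame["sigma"] = pd.NA
        res = fit(
            m1_both, data,
            init={"k1": 0.3, "k2": 0.6, "k3": 0.25, "k4": 0.5},
            fixed={"k3": p1["k3"], "k4": p1["k4"]},
            n_starts=3, seed=0,
        )
        assert res.success
        assert res.estimate["k1"] == pytest.approx(p1["k1"], rel=0.15)


class TestOdeMLEFrontEnd:
    def test_fit_profile_summary_round_trip(self, m1_both, model1_data, p1):
        mle = OdeMLE(m1_both, model1_data)
        res = mle.fit(init=p1, n_starts=1)
        text = res.summary()
        assert "objective" in text and "k1" in text
        assert set(res.params) == set(p1)

    def test_from_files(self, tmp_path, m1_both, model1_data, p1):
        mpath = tmp_path / "m.yaml"
        dpath = tmp_path / "d.csv"
        mpath.write_text(oi.serialize_model(m1_both))
        model1_data.to_csv(dpath)
        mle = OdeMLE.from_files(mpath, dpath)
        assert mle.objective(p1) == pytest.approx(
            objective(m1_both, p1, model1_data), rel=1e-9
        )
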