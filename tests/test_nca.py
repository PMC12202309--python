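"""Batch/serial AUC estimation: oracles, invariances, bootstrap behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from olzpk import nca
from olzpk import synthetic_data as syn
from olzpk.nca import (BatchDataset, NCAError, auc_ratio, batch_auc, blq_rule,
                       serial_auc, trapezoid_weights)
from olzpk.pk_model import solve


class TestTrapezoidWeights:
    def test_three_point_grid(self):
        assert np.allclose(trapezoid_weights([0, 1, 2]), [0.5, 1.0, 0.5])

    def test_two_point_grid(self):
        assert np.allclose(trapezoid_weights([0, 24]), [12.0, 12.0])

    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2,
                    max_size=12, unique=True))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_weights_sum_to_span(self, times):
        t = sorted(times)
        assert np.sum(trapezoid_weights(t)) == pytest.approx(t[-1] - t[0])

    @pytest.mark.parametrize("bad", [[1.0], [2.0, 1.0], [1.0, 1.0, 2.0]])
    def test_rejects_degenerate_grids(self, bad):
        with pytest.raises(NCAError):
            trapezoid_weights(bad)


def _one_animal_per_time(per_time_conc):
    rows = [{"animal_id": f"a{j}{i}", "time_h": t, "conc": c}
            for j, (t, concs) in enumerate(per_time_conc.items())
            for i, c in enumerate(concs)]
    return BatchDataset.from_frame(pd.DataFrame(rows))


class TestBatchAUC:
    def test_weighted_means_point_estimate(self):
        data = _one_animal_per_time({0.0: [0, 0, 0], 1.0: [10, 10, 10],
                                     2.0: [5, 5, 5]})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton batches
            res = batch_auc(data, n_boot=0)
        assert res.auc == pytest.approx(12.5)
        assert res.se == 0.0

    def test_zero_concentrations_everywhere(self):
        data = _one_animal_per_time({0.0: [0.0] * 3, 1.0: [0.0] * 3})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = batch_auc(data, n_boot=0)
        assert res.auc == 0.0
        assert res.se == 0.0

    def test_complete_data_matches_per_animal_average_oracle(
            self, complete_profiles):
        # brute-force oracle: average of each animal's own trapezoid AUC
        oracle = serial_auc(complete_profiles)["auc"].mean()
        res = batch_auc(BatchDataset.from_frame(complete_profiles),
                        n_boot=400, seed=7)
        assert res.auc == pytest.approx(oracle, rel=1e-12)
        assert res.ci_lower <= res.auc <= res.ci_upper

    def test_scale_equivariance(self, complete_profiles):
        scaled = complete_profiles.assign(conc=complete_profiles.conc * 3.5)
        a = batch_auc(BatchDataset.from_frame(complete_profiles),
                      n_boot=300, seed=5)
        b = batch_auc(BatchDataset.from_frame(scaled), n_boot=300, seed=5)
        for attr in ("auc", "se", "ci_lower", "ci_upper"):
            assert getattr(b, attr) == pytest.approx(
                3.5 * getattr(a, attr), rel=1e-9)

    def test_time_unit_invariance(self, complete_profiles):
        minutes = complete_profiles.assign(time_h=complete_profiles.time_h * 60)
        a = batch_auc(BatchDataset.from_frame(complete_profiles), n_boot=0)
        b = batch_auc(BatchDataset.from_frame(minutes), n_boot=0)
        assert b.auc == pytest.approx(60.0 * a.auc, rel=1e-12)

    def test_seed_reproducibility(self, complete_profiles):
        data = BatchDataset.from_frame(complete_profiles)
        a = batch_auc(data, n_boot=200, seed=3)
        b = batch_auc(data, n_boot=200, seed=3)
        assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)

    def test_bootstrap_requires_seed(self, complete_profiles):
        with pytest.raises(NCAError, match="seed"):
            batch_auc(BatchDataset.from_frame(complete_profiles),
                      n_boot=100, seed=None)

    def test_singleton_batches_warn_and_yield_undefined_interval(self):
        data = _one_animal_per_time({0.0: [1.0], 1.0: [2.0]})
        with pytest.warns(UserWarning, match="single animal|two animals"):
            res = batch_auc(data, n_boot=100, seed=1)
        assert np.isnan(res.ci_lower)

    def test_estimator_unbiased_over_simulated_destructive_studies(self):
        """Over >= 2000 destructive studies with proportional error, the
        mean estimate matches the schedule-trapezoid AUC of the generating
        curve (the estimator's estimand) within 2%."""
        arm = syn.default_design().arms[0]
        assign = syn.destructive_assignment(arm.schedule, arm.n_animals, 2)
        sched = np.array(sorted(arm.schedule))
        curve = solve(syn.CONTROL_MEDIANS, [arm.dose], sched)["parent"]
        truth = float(trapezoid_weights(sched) @ curve)
        tmap = dict(zip(sched, curve))
        rng = np.random.default_rng(2024)
        estimates = []
        for _ in range(2000):
            rows = [{"animal_id": i, "time_h": t,
                     "conc": max(tmap[t] * (1 + 0.15 * rng.standard_normal()),
                                 0.0) if t > 0 else 0.0}
                    for i, pat in enumerate(assign) for t in pat]
            res = batch_auc(BatchDataset.from_frame(pd.DataFrame(rows)),
                            n_boot=0)
            estimates.append(res.auc)
        assert np.mean(estimates) == pytest.approx(truth, rel=0.02)

    def test_noise_widens_bootstrap_interval(self):
        """Larger residual CV widens the bootstrap-t interval on average."""
        arm = syn.default_design().arms[0]
        assign = syn.destructive_assignment(arm.schedule, arm.n_animals, 2)
        sched = np.array(sorted(arm.schedule))
        curve = solve(syn.CONTROL_MEDIANS, [arm.dose], sched)["parent"]
        tmap = dict(zip(sched, curve))
        rng = np.random.default_rng(99)

        def mean_width(cv, n_rep=30):
            widths = []
            for _ in range(n_rep):
                rows = [{"animal_id": i, "time_h": t,
                         "conc": max(tmap[t] * (1 + cv * rng.standard_normal()),
                                     0.0) if t > 0 else 0.0}
                        for i, pat in enumerate(assign) for t in pat]
                res = batch_auc(BatchDataset.from_frame(pd.DataFrame(rows)),
                                n_boot=500, seed=int(rng.integers(2**31)))
                widths.append(res.ci_upper - res.ci_lower)
            return np.mean(widths)

        assert mean_width(0.05) < mean_width(0.15) < mean_width(0.40)


class TestAUCRatio:
    def test_published_po_metabolic_ratio(self):
        assert auc_ratio(1070, 462) == pytest.approx(2.32, abs=0.005)

    def test_published_group_exposure_ratio(self):
        assert auc_ratio(462, 121) == pytest.approx(3.82, abs=0.005)

    def test_self_ratio_is_one(self, complete_profiles):
        res = batch_auc(BatchDataset.from_frame(complete_profiles), n_boot=0)
        assert auc_ratio(res, res) == 1.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(NCAError):
            auc_ratio(10.0, 0.0)


class TestSerialAUC:
    def test_constant_profile(self):
        df = pd.DataFrame({"animal_id": "a", "time_h": [0, 2, 6.0],
                           "conc": [10.0, 10.0, 10.0]})
        assert serial_auc(df)["auc"].iloc[0] == pytest.approx(60.0)

    def test_straight_line(self):
        df = pd.DataFrame({"animal_id": "a", "time_h": [0, 1.0],
                           "conc": [0.0, 10.0]})
        assert serial_auc(df)["auc"].iloc[0] == pytest.approx(5.0)

    def test_single_point_animal_skipped_with_warning(self):
        df = pd.DataFrame({"animal_id": ["a", "b", "b"],
                           "time_h": [1.0, 0.0, 2.0],
                           "conc": [5.0, 1.0, 3.0]})
        with pytest.warns(UserWarning, match="<2 points"):
            out = serial_auc(df)
        assert list(out["animal_id"]) == ["b"]

    def test_matches_quadrature_of_generating_model(self, control_params):
        from olzpk.pk_model import DoseArm, DoseEvent
        dose = DoseEvent(DoseArm.IV_PARENT, 0.5)
        sched = np.array(sorted(syn.IV_SCHEDULE))
        c = solve(control_params, [dose], sched)["parent"]
        df = pd.DataFrame({"animal_id": "m", "time_h": sched, "conc": c})
        est = serial_auc(df)["auc"].iloc[0]
        dense = np.linspace(sched[0], sched[-1], 20000)
        quad = np.trapezoid(solve(control_params, [dose], dense)["parent"],
                            dense)
        # trapezoid on the design grid vs dense quadrature
        assert est == pytest.approx(quad, rel=0.05)


class TestBLQRule:
    def _frame(self):
        return pd.DataFrame({
            "animal_id": list("abcdef"),
            "time_h": [0.0, 0.5, 1.0, 2.0, 8.0, 24.0],
            "conc": [0.0, 5.0, 10.0, 8.0, 0.05, 0.02],
            "blq_flag": [True, False, False, False, True, True],
        })

    def test_zero_before_tmax_and_drop_after(self):
        out = blq_rule(self._frame())
        assert 0.0 in out["time_h"].values  # predose kept as zero
        assert out.loc[out.time_h == 0.0, "conc"].iloc[0] == 0.0
        assert 8.0 not in out["time_h"].values
        assert 24.0 not in out["time_h"].values

    def test_lloq_half_imputation(self):
        out = blq_rule(self._frame(), rule="lloq_half", lloq=0.1)
        assert (out.loc[out.blq_flag, "conc"] == 0.05).all()

    def test_drop_rule_removes_all_flagged(self):
        out = blq_rule(self._frame(), rule="drop")
        assert not out["blq_flag"].any()
        assert len(out) == 3
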