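"""The two-layer dust-competition model: noise law, winner-take-all,
per-bout dust transfer, and whole-run behavior."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from groomsim import (
    BODY_PARTS,
    LEG_PARTS,
    DustState,
    ModelParams,
    SensoryActivity,
    run_cohort,
    sample_activity,
    select_winner,
    simulate,
    update_dust,
    wild_type_dust,
)
from groomsim.bouts import EmpiricalBoutModel


def activity(**kwargs) -> SensoryActivity:
    a = {p: 0.0 for p in BODY_PARTS}
    a.update(kwargs)
    return SensoryActivity(a=a, sigma={p: 0.0 for p in BODY_PARTS})


class TestSampleActivity:
    def test_mean_and_noise_ratio(self):
        """a ~ N(d, (d/5)^2): at d = 1000, mean ~= 1000 and mean/SD ~= 5."""
        rng = np.random.default_rng(11)
        d = DustState(head=1000.0)
        a = sample_activity(d, 5.0, rng, size=1_000_000).a["head"]
        assert abs(a.mean() - 1000.0) <= 1.0
        assert abs(1000.0 / a.std(ddof=1) - 5.0) <= 0.05

    def test_zero_dust_is_silent(self):
        rng = np.random.default_rng(0)
        a = sample_activity(DustState(), 5.0, rng)
        assert all(a.a[p] == 0.0 for p in BODY_PARTS)
        assert all(a.sigma[p] == 0.0 for p in BODY_PARTS)

    def test_two_part_competition_matches_normal_difference(self):
        """P(a_head > a_abdomen) at d = (1200, 600) equals the closed form
        Phi(600 / sqrt(240^2 + 120^2)) for the difference of two normals."""
        rng = np.random.default_rng(7)
        d = DustState(head=1200.0, abdomen=600.0)
        a = sample_activity(d, 5.0, rng, size=1_000_000)
        expected = stats.norm.cdf(600.0 / math.hypot(240.0, 120.0))
        observed = float((a.a["head"] > a.a["abdomen"]).mean())
        assert abs(observed - expected) < 3 * math.sqrt(expected * (1 - expected) / 1e6) + 1e-4

    def test_rejects_bad_noise_divisor(self):
        with pytest.raises(ValueError):
            sample_activity(DustState(head=1.0), 0.0, np.random.default_rng(0))


class TestSelectWinner:
    def test_unique_maximum(self):
        a = activity(head=5.0, wings=3.0, abdomen=1.0)
        assert select_winner(a, np.random.default_rng(0)) == "head"

    def test_exact_ties_uniform(self):
        """All-equal drives: each of the five parts wins ~1/5 of the time."""
        rng = np.random.default_rng(3)
        a = activity(**{p: 1.0 for p in BODY_PARTS})
        counts = {p: 0 for p in BODY_PARTS}
        n = 100_000
        for _ in range(n):
            counts[select_winner(a, rng)] += 1
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 1e-4

    def test_all_zero_still_selects(self):
        winner = select_winner(activity(), np.random.default_rng(1))
        assert winner in BODY_PARTS


class TestUpdateDust:
    def test_body_win_transfers_to_cleaning_legs(self):
        d = DustState(head=1200.0, front_legs=200.0)
        out = update_dust(d, "head", 0.002)
        assert out["head"] == pytest.approx(1197.6)
        assert out["front_legs"] == pytest.approx(202.4)
        assert out.total == pytest.approx(d.total)  # conserved transfer

    def test_leg_win_discards_ten_dr(self):
        d = DustState(back_legs=200.0)
        out = update_dust(d, "back_legs", 0.002)
        assert out["back_legs"] == pytest.approx(196.0)
        assert d.total - out.total == pytest.approx(4.0)

    def test_dr_zero_is_identity(self):
        d = wild_type_dust()
        for winner in BODY_PARTS:
            assert update_dust(d, winner, 0.0) == d

    def test_leg_to_body_removal_ratio_is_ten(self):
        """One leg win sheds exactly 10x the fraction a body win transfers."""
        dr = 0.004
        body = update_dust(DustState(head=1000.0), "head", dr)
        leg = update_dust(DustState(back_legs=1000.0), "back_legs", dr)
        frac_body = 1.0 - body["head"] / 1000.0
        frac_leg = 1.0 - leg["back_legs"] / 1000.0
        assert frac_leg == pytest.approx(10.0 * frac_body)

    def test_rejects_unknown_winner(self):
        with pytest.raises(KeyError):
            update_dust(wild_type_dust(), "tail", 0.002)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        loads=st.lists(st.floats(0.0, 2000.0), min_size=5, max_size=5),
        winner=st.sampled_from(BODY_PARTS),
        dr=st.floats(0.0, 0.1),
    )
    def test_conservation_and_nonnegativity(self, loads, winner, dr):
        """Body wins conserve total dust exactly; leg wins only remove it;
        no entry ever goes negative."""
        d = DustState.from_mapping(dict(zip(BODY_PARTS, loads)))
        out = update_dust(d, winner, dr)
        assert all(out[p] >= 0.0 for p in BODY_PARTS)
        if winner in LEG_PARTS:
            assert out.total <= d.total + 1e-9
            expected_loss = d[winner] * 10.0 * dr
            assert d.total - out.total == pytest.approx(expected_loss, abs=1e-9)
        else:
            assert out.total == pytest.approx(d.total, abs=1e-9)


class TestSimulate:
    def test_deterministic_under_seed(self):
        params = ModelParams(run_frames=5_000, seed=42)
        t1, e1 = simulate(params)
        t2, e2 = simulate(ModelParams(run_frames=5_000, seed=42))
        assert np.array_equal(e1.labels, e2.labels)
        assert [b.winner for b in t1.bouts] == [b.winner for b in t2.bouts]
        assert t1.final_dust == t2.final_dust

    def test_horizon_truncates_last_bout(self):
        params = ModelParams(run_frames=1_000, seed=0)
        trace, e = simulate(params)
        assert e.n_frames == 1_000
        assert sum(b.duration_frames for b in trace.bouts) == 1_000

    def test_total_dust_non_increasing_along_trace(self):
        trace, _ = simulate(ModelParams(run_frames=20_000, seed=5))
        totals = [b.dust_before.total for b in trace.bouts] + [trace.final_dust.total]
        assert all(t1 >= t2 - 1e-9 for t1, t2 in zip(totals, totals[1:]))
        assert all(
            min(b.dust_before.as_dict().values()) >= 0.0 for b in trace.bouts
        )

    def test_emits_grooming_labels_only(self):
        _, e = simulate(ModelParams(run_frames=3_000, seed=1))
        assert set(np.unique(e.labels)) <= {
            "head_sweep", "front_leg_rub", "body_sweep", "back_leg_rub", "wing_sweep"
        }

    def test_missing_bout_behavior_raises(self):
        params = ModelParams(
            initial_dust=DustState(abdomen=500.0),  # winner emits body_sweep
            run_frames=1_000, seed=0,
            bout_model=EmpiricalBoutModel({"head_sweep": [30]}),
        )
        with pytest.raises(KeyError):
            simulate(params)

    def test_all_zero_dust_terminates(self):
        params = ModelParams(initial_dust=DustState(), run_frames=500, seed=0)
        _, e = simulate(params)
        assert e.n_frames == 500

    def test_external_drive_overrides_dust(self):
        """With a user-supplied drive, the part with the stronger time series
        dominates and dust is not consumed."""
        drive = {"head": lambda t: 100.0 if t < 10 else 1.0,
                 "abdomen": lambda t: 10.0}
        params = ModelParams(run_frames=6_000, seed=2, drive=drive)
        trace, e = simulate(params)
        assert trace.final_dust == params.initial_dust
        codes = e.coarse_codes()
        first = codes[:150]
        assert (first == 0).mean() > 0.9  # head dominates under high drive


class TestRunCohort:
    def test_distinct_ids_and_determinism(self):
        params = ModelParams(run_frames=2_000)
        c1 = run_cohort(params, 10, base_seed=9)
        c2 = run_cohort(params, 10, base_seed=9)
        assert len(set(c1.fly_ids)) == 10
        for a, b in zip(c1, c2):
            assert np.array_equal(a.labels, b.labels)

    def test_single_fly(self):
        c = run_cohort(ModelParams(run_frames=1_000), 1, base_seed=0)
        assert len(c) == 1

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(dr=0.2)  # 10*dr would exceed 1
        with pytest.raises(ValueError):
            ModelParams(noise_divisor=-1.0)
        with pytest.raises(ValueError):
            DustState(head=-5.0)


class TestWinnerFrequenciesAgainstOracle:
    """First-iteration winner frequencies vs. an independent brute-force
    Monte-Carlo argmax oracle (vectorized normal draws, no model code)."""

    @staticmethod
    def oracle_probs(d: dict, noise_divisor: float, n: int, seed: int) -> np.ndarray:
        rng = np.random.default_rng(seed)
        loc = np.array([d.get(p, 0.0) for p in BODY_PARTS])
        draws = rng.normal(loc, loc / noise_divisor, size=(n, len(BODY_PARTS)))
        return np.bincount(draws.argmax(axis=1), minlength=len(BODY_PARTS)) / n

    @pytest.mark.parametrize(
        "dust",
        [
            {"head": 1200.0, "abdomen": 600.0},  # two-part competition
            {"head": 1200.0, "wings": 400.0, "abdomen": 600.0,
             "front_legs": 200.0, "back_legs": 200.0},  # full wild type
        ],
        ids=["two_part", "five_part"],
    )
    def test_model_matches_oracle(self, dust):
        n = 100_000
        d = DustState.from_mapping(dust)
        rng = np.random.default_rng(17)
        counts = {p: 0 for p in BODY_PARTS}
        for _ in range(n):
            a = sample_activity(d, 5.0, rng)
            counts[select_winner(a, rng)] += 1
        probs = self.oracle_probs(dust, 5.0, 1_000_000, seed=23)
        for i, part in enumerate(BODY_PARTS):
            p = float(np.clip(probs[i], 1e-9, 1 - 1e-9))
            res = stats.binomtest(counts[part], n, p)
            assert res.pvalue > 1e-4, f"{part}: {counts[part]}/{n} vs oracle p={p:.5f}"

    def test_two_part_closed_form(self):
        """The oracle itself agrees with the normal-difference closed form."""
        probs = self.oracle_probs({"head": 1200.0, "abdomen": 600.0}, 5.0, 1_000_000, seed=29)
        expected = stats.norm.cdf(600.0 / math.hypot(240.0, 120.0))
        assert probs[BODY_PARTS.index("head")] == pytest.approx(expected, abs=5e-4)
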