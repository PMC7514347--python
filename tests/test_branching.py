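import numpy as np
import pandas as pd
import pytest

from critmem.branching import (
    ActivitySeries,
    GroupSummary,
    SpikeDataset,
    bin_bout,
    group_change_summary,
    lag_slopes,
    learning_score,
    mr_estimate,
    stationarity_screen,
    subject_sigma,
)
from critmem.synthetic import BranchingProcessSpec, simulate_branching


def _dataset(units, bouts):
    return SpikeDataset(
        units=units,
        bouts=pd.DataFrame(bouts),
        subject_id="s1",
        condition="CFC",
    )


class TestBinBout:
    def test_hand_binning(self):
        """Spikes at 1, 10, 20 ms in a 48 ms bout at 16 ms bins → [2, 1, 0]."""
        spikes = np.array([0.001, 0.010, 0.020])
        series = bin_bout(spikes, (0.0, 0.048), 0.016)
        assert series.counts.tolist() == [2, 1, 0]

    def test_empty_bout_is_all_zero(self):
        series = bin_bout(np.array([]), (0.0, 1.0), 0.016)
        assert series.counts.sum() == 0
        assert series.n_bins == 62

    def test_bin_count_arithmetic(self):
        """A 60 s bout at 16 ms bins yields 3750 bins."""
        series = bin_bout(np.array([1.0]), (0.0, 60.0), 0.016)
        assert series.n_bins == 3750

    def test_mass_conservation_with_partial_bin_discarded(self):
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0.0, 1.0, 500))
        series = bin_bout(spikes, (0.0, 1.0), 0.016)
        cutoff = series.n_bins * 0.016
        assert series.counts.sum() == (spikes < cutoff).sum()

    def test_units_pooled(self):
        ds = _dataset(
            [np.array([0.001, 0.035]), np.array([0.002])],
            [{"start": 0.0, "end": 0.048, "epoch": "baseline"}],
        )
        series = bin_bout(ds, (0.0, 0.048), 0.016)
        assert series.counts.tolist() == [2, 0, 1]

    def test_min_bins_gate(self):
        with pytest.raises(ValueError, match="too short"):
            bin_bout(np.array([0.001]), (0.0, 0.1), 0.016, min_bins=100)


class TestMrEstimate:
    def test_recovers_known_sigma(self):
        errs = []
        for seed in range(5):
            spec = BranchingProcessSpec(
                sigma=0.9, drive_rate=2.0, n_bins=50_000, seed=seed
            )
            est = mr_estimate(simulate_branching(spec))
            errs.append(est.sigma - 0.9)
        assert np.abs(errs).max() < 0.02

    def test_poisson_noise_rejected(self):
        """σ = 0 (i.i.d. Poisson) has no autocorrelation structure."""
        spec = BranchingProcessSpec(sigma=0.0, drive_rate=3.0, n_bins=20_000, seed=1)
        est = mr_estimate(simulate_branching(spec))
        assert est.sigma < 0.2 or not est.accepted

    def test_subsampling_invariance(self):
        """Binomial subsampling leaves σ̂ intact while crushing the naive
        single-lag slope — the multistep-regression property."""
        base = BranchingProcessSpec(sigma=0.95, drive_rate=2.0, n_bins=100_000, seed=3)
        sub = BranchingProcessSpec(
            sigma=0.95, drive_rate=2.0, n_bins=100_000, subsample_prob=0.1, seed=3
        )
        est_full = mr_estimate(simulate_branching(base))
        s_sub = simulate_branching(sub)
        est_sub = mr_estimate(s_sub)
        assert abs(est_full.sigma - est_sub.sigma) < 0.02
        r1_naive = lag_slopes(s_sub.counts, 1)[0]
        assert r1_naive < 0.7  # naive slope collapses under subsampling

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            mr_estimate(ActivitySeries(np.ones(100, dtype=int)), k_max=40)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            mr_estimate(ActivitySeries(np.full(1000, 5)), k_max=10)


class TestStationarityScreen:
    def test_stationary_accepted(self):
        spec = BranchingProcessSpec(sigma=0.9, drive_rate=2.0, n_bins=20_000, seed=1)
        est = stationarity_screen(simulate_branching(spec))
        assert est.accepted

    def test_drive_doubling_rejected_for_drift(self):
        spec = BranchingProcessSpec(
            sigma=0.9, drive_rate=2.0, n_bins=20_000,
            nonstationarity=("drift", 2.0), seed=1,
        )
        est = stationarity_screen(simulate_branching(spec))
        assert not est.accepted
        assert "drift" in est.reason

    def test_fast_updown_switching_rejected(self):
        """Fast alternation between up and down states breaks the
        single-σ exponential lag structure."""
        spec = BranchingProcessSpec(
            sigma=0.9, drive_rate=1.0, n_bins=20_000,
            nonstationarity=("updown", 20, 0.2, 8.0), seed=1,
        )
        est = stationarity_screen(simulate_branching(spec))
        assert not est.accepted

    def test_runaway_sigma_rejected(self):
        est = mr_estimate(
            simulate_branching(
                BranchingProcessSpec(sigma=0.9, drive_rate=2.0, n_bins=20_000, seed=0)
            )
        )
        est.sigma = 1.15  # simulate a runaway fit
        out = stationarity_screen(
            simulate_branching(
                BranchingProcessSpec(sigma=0.9, drive_rate=2.0, n_bins=20_000, seed=0)
            ),
            estimate=est,
        )
        assert not out.accepted
        assert "runaway" in out.reason


class TestSubjectAndGroup:
    def test_subject_sigma_recovers_epoch_shift(self):
        """A subject with baseline σ = 0.98 and post σ = 0.93 yields
        Δσ ≈ −0.05."""
        rng = np.random.default_rng(5)
        from critmem.synthetic import spikes_from_counts

        units = [[] for _ in range(5)]
        bouts = []
        t = 0.0
        for epoch, sigma in (("baseline", 0.98), ("post_cond", 0.93)):
            for _ in range(4):
                n_bins = 15_000
                spec = BranchingProcessSpec(
                    sigma=sigma, drive_rate=3.0 * (1 - sigma), n_bins=n_bins
                )
                series = simulate_branching(spec, rng)
                sp = spikes_from_counts(series, 5, rng, t_start=t)
                for u in range(5):
                    units[u].append(sp[u])
                bouts.append(
                    {"start": t, "end": t + n_bins * 0.016, "epoch": epoch}
                )
                t += n_bins * 0.016 + 10.0
        ds = _dataset([np.concatenate(u) for u in units], bouts)
        summ, table = subject_sigma(ds)
        assert table["accepted"].sum() >= 6
        assert summ.delta_sigma == pytest.approx(-0.05, abs=0.02)

    def test_learning_score_arithmetic(self):
        assert learning_score(60, 10) == 50
        assert learning_score(10, 10) == 0
        assert learning_score(5, 20) == -15
        with pytest.raises(ValueError):
            learning_score(120, 10)

    def test_group_summary_sign_and_test(self):
        subs = [
            GroupSummary("c1", "CFC", 1.0, 0.01, 0.95, 0.01),
            GroupSummary("c2", "CFC", 0.99, 0.01, 0.95, 0.01),
            GroupSummary("c3", "CFC", 1.0, 0.01, 0.96, 0.01),
            GroupSummary("s1", "Sham", 1.0, 0.01, 0.99, 0.01),
            GroupSummary("s2", "Sham", 0.99, 0.01, 0.99, 0.01),
        ]
        out = group_change_summary(subs).set_index("condition")
        assert out.loc["CFC", "mean_delta_sigma"] < out.loc["Sham", "mean_delta_sigma"]
        assert out.loc["CFC", "p_value"] < 0.05

    def test_null_group_not_significant(self):
        subs = [
            GroupSummary(f"s{i}", "Sham", 1.0, 0.01, 1.0, 0.01) for i in range(3)
        ]
        out = group_change_summary(subs)
        assert out["mean_delta_sigma"].iloc[0] == pytest.approx(0.0)
        assert not (out["p_value"] < 0.1).any()
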