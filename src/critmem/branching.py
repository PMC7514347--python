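"""Branching-parameter analysis of pooled spike trains.

Population spiking within each slow-wave-sleep bout is binned into 16 ms
sub-intervals; the branching parameter σ — the expected number of
"offspring" events per event, σ = 1 being critical — is estimated by
multistep regression: the lag-k regression slope r_k = Cov(a_t, a_{t+k}) /
Var(a_t) of a stationary driven branching process decays as r_k = b·σ^k,
and fitting that exponential across many lags cancels the constant bias b
that spatial subsampling (observing only a fraction of the units) induces
in any single-lag slope.

Bouts whose activity is non-stationary (drifting drive, up/down-state
switching) violate the single-σ model and are screened out before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "SpikeDataset",
    "ActivitySeries",
    "BranchingEstimate",
    "GroupSummary",
    "bin_bout",
    "mr_estimate",
    "lag_slopes",
    "stationarity_screen",
    "subject_sigma",
    "learning_score",
    "group_change_summary",
    "DEFAULT_BIN_WIDTH",
    "DEFAULT_K_MAX",
]

DEFAULT_BIN_WIDTH = 0.016  # seconds
DEFAULT_K_MAX = 40  # lags: 640 ms at 16 ms bins


@dataclass
class SpikeDataset:
    """Spike times (seconds) per unit plus bout intervals and labels.

    ``bouts`` is a DataFrame with columns start, end (seconds) and epoch
    ('baseline' or 'post_cond'); spikes within a bout are pooled across all
    units before binning.
    """

    units: list[np.ndarray]
    bouts: pd.DataFrame
    subject_id: str = ""
    condition: str = ""  # 'CFC' or 'Sham'

    def __post_init__(self):
        self.units = [np.sort(np.asarray(u, dtype=float)) for u in self.units]
        b = self.bouts
        if len(b) and (b["start"] >= b["end"]).any():
            raise ValueError("every bout needs start < end")
        if len(b) > 1:
            for ep, g in b.groupby("epoch"):
                g = g.sort_values("start")
                if (g["start"].values[1:] < g["end"].values[:-1]).any():
                    raise ValueError(f"overlapping bouts in epoch {ep!r}")

    def pooled_spikes(self) -> np.ndarray:
        if not self.units:
            return np.empty(0)
        return np.sort(np.concatenate(self.units))


@dataclass
class ActivitySeries:
    """Pooled spike counts per fixed-width time bin within one bout."""

    counts: np.ndarray
    bin_width: float = DEFAULT_BIN_WIDTH

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.size and self.counts.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.size


@dataclass
class BranchingEstimate:
    """Multistep-regression result for one activity series."""

    sigma: float
    lag_slopes: np.ndarray  # r_k, k = 1..k_max
    amplitude: float  # b in r_k = b·σ^k + c
    offset: float  # c
    r_squared: float  # of the exponential fit
    accepted: bool = True
    reason: str = ""


@dataclass
class GroupSummary:
    """Per-subject σ summary across epochs, plus the behavioral score."""

    subject_id: str
    condition: str
    sigma_baseline: float
    sem_baseline: float
    sigma_post: float
    sem_post: float
    n_bouts_baseline: int = 0
    n_bouts_post: int = 0
    learning_score: float = float("nan")

    @property
    def delta_sigma(self) -> float:
        return self.sigma_post - self.sigma_baseline


def bin_bout(
    spikes: SpikeDataset | np.ndarray,
    bout: tuple[float, float],
    bin_width: float = DEFAULT_BIN_WIDTH,
    *,
    min_bins: int = 0,
) -> ActivitySeries:
    """Pool spikes from all units and count them in half-open bins
    [t, t + bin) anchored at the bout start; the final partial bin is
    discarded.

    ``min_bins`` (0 by default) lets pipelines enforce a minimum usable
    length; sub-threshold bouts raise.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    start, end = float(bout[0]), float(bout[1])
    if end <= start:
        raise ValueError("bout must have start < end")
    n_bins = int(np.floor((end - start) / bin_width))
    if n_bins < min_bins:
        raise ValueError(
            f"bout spans only {n_bins} bins (< {min_bins}); too short for a "
            "reliable branching estimate"
        )
    times = (
        spikes.pooled_spikes() if isinstance(spikes, SpikeDataset) else np.asarray(spikes)
    )
    sel = times[(times >= start) & (times < start + n_bins * bin_width)]
    counts = np.bincount(
        ((sel - start) / bin_width).astype(np.intp), minlength=n_bins
    )[:n_bins]
    return ActivitySeries(counts=counts.astype(np.int64), bin_width=bin_width)


def lag_slopes(counts: np.ndarray, k_max: int) -> np.ndarray:
    """r_k = Cov(a_t, a_{t+k}) / Var(a_t) for k = 1..k_max (the linear-
    regression slope of a_{t+k} on a_t)."""
    a = np.asarray(counts, dtype=np.float64)
    n = a.size
    out = np.empty(k_max)
    for k in range(1, k_max + 1):
        x, y = a[:-k], a[k:]
        vx = x.var()
        if vx == 0:
            out[k - 1] = 0.0
        else:
            out[k - 1] = ((x - x.mean()) * (y - y.mean())).mean() / vx
    return out


def _exp_model(k, b, sigma, c):
    return b * np.power(sigma, k) + c


def mr_estimate(
    series: ActivitySeries, k_max: int = DEFAULT_K_MAX
) -> BranchingEstimate:
    """Multistep-regression branching-parameter estimate.

    Fits r_k = b·σ^k + c over k = 1..k_max by least squares; the constant
    offset c absorbs slow drifts.  Because subsampling scales every r_k by
    the same factor (absorbed into b), σ itself is recovered without bias —
    the point of regressing over multiple lags rather than using r_1.
    """
    a = series.counts
    if a.size < 10 * k_max:
        raise ValueError(
            f"series of {a.size} bins is shorter than 10·k_max = {10 * k_max}"
        )
    if np.var(a) == 0:
        raise ValueError("series has zero variance")

    r = lag_slopes(a, k_max)
    ks = np.arange(1, k_max + 1, dtype=float)

    # no structure: every slope non-positive, or none exceeds the sampling
    # noise of a slope under independence (~1/sqrt(n), 3-sigma)
    if (r <= 0).all() or r.max() < 3.0 / np.sqrt(a.size):
        return BranchingEstimate(
            sigma=0.0, lag_slopes=r, amplitude=0.0, offset=0.0,
            r_squared=0.0, accepted=False, reason="no autocorrelation structure",
        )

    # log-linear initial guess from the positive slopes
    pos = r > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(ks[pos], np.log(r[pos]), 1)
        sigma0 = float(np.clip(np.exp(slope), 1e-3, 1.5))
        b0 = float(np.clip(np.exp(intercept), 1e-6, 10.0))
    else:
        sigma0, b0 = 0.9, max(float(r[0]), 1e-3)

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = scipy.optimize.curve_fit(
                _exp_model,
                ks,
                r,
                p0=(b0, sigma0, 0.0),
                bounds=([1e-9, 1e-6, -1.0], [100.0, 2.0, 1.0]),
                maxfev=20000,
            )
    except (RuntimeError, ValueError):
        return BranchingEstimate(
            sigma=float("nan"), lag_slopes=r, amplitude=float("nan"),
            offset=float("nan"), r_squared=0.0,
            accepted=False, reason="exponential fit did not converge",
        )

    b, sigma, c = (float(v) for v in popt)
    resid = r - _exp_model(ks, *popt)
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return BranchingEstimate(
        sigma=sigma, lag_slopes=r, amplitude=b, offset=c, r_squared=r2,
    )


def stationarity_screen(
    series: ActivitySeries,
    estimate: BranchingEstimate | None = None,
    k_max: int = DEFAULT_K_MAX,
    *,
    drift_sd_factor: float = 0.5,
    min_r_squared: float = 0.7,
    sigma_cap: float = 1.1,
) -> BranchingEstimate:
    """Accept or reject one bout's estimate on stationarity grounds.

    Rejection causes (first match wins): (a) mean drift between the two
    halves exceeding ``drift_sd_factor`` pooled standard deviations;
    (b) exponential-fit R² below ``min_r_squared`` — the lag structure is
    inconsistent with a single branching ratio; (c) σ̂ at or above
    ``sigma_cap`` — runaway slopes typical of up/down-state switching.
    Returns the estimate with ``accepted``/``reason`` set.
    """
    a = series.counts.astype(np.float64)
    if a.size < 200:
        raise ValueError("need at least 200 bins to screen stationarity")
    est = estimate if estimate is not None else mr_estimate(series, k_max)
    if not est.accepted:
        return est

    half = a.size // 2
    first, second = a[:half], a[half:]
    pooled_sd = a.std()
    if pooled_sd > 0 and abs(first.mean() - second.mean()) > drift_sd_factor * pooled_sd:
        est.accepted, est.reason = False, "mean drift between halves"
    elif est.r_squared < min_r_squared:
        est.accepted, est.reason = False, "lag structure inconsistent with single sigma"
    elif est.sigma >= sigma_cap:
        est.accepted, est.reason = False, "runaway sigma (up/down switching)"
    return est


def subject_sigma(
    dataset: SpikeDataset,
    bin_width: float = DEFAULT_BIN_WIDTH,
    k_max: int = DEFAULT_K_MAX,
    *,
    min_bins: int = 100,
) -> tuple[GroupSummary, pd.DataFrame]:
    """Per-epoch mean σ ± sem over accepted bouts of one subject.

    Returns the summary and a per-bout table (epoch, start, end, sigma,
    accepted, reason).  Epochs with no accepted bout carry NaN and are
    flagged in the table.
    """
    rows = []
    for _, bout in dataset.bouts.iterrows():
        rec = {
            "epoch": bout["epoch"],
            "start": bout["start"],
            "end": bout["end"],
            "sigma": float("nan"),
            "accepted": False,
            "reason": "",
        }
        try:
            series = bin_bout(
                dataset, (bout["start"], bout["end"]), bin_width, min_bins=min_bins
            )
            est = stationarity_screen(series, k_max=k_max)
            rec["sigma"] = est.sigma
            rec["accepted"] = est.accepted
            rec["reason"] = est.reason
        except ValueError as exc:
            rec["reason"] = str(exc)
        rows.append(rec)
    table = pd.DataFrame(rows)

    def epoch_stats(name):
        ok = table[(table["epoch"] == name) & table["accepted"]]["sigma"]
        if len(ok) == 0:
            return float("nan"), float("nan"), 0
        sem = ok.sem() if len(ok) > 1 else float("nan")
        return float(ok.mean()), float(sem), int(len(ok))

    mb, sb, nb = epoch_stats("baseline")
    mp, sp_, np_ = epoch_stats("post_cond")
    summary = GroupSummary(
        subject_id=dataset.subject_id,
        condition=dataset.condition,
        sigma_baseline=mb,
        sem_baseline=sb,
        sigma_post=mp,
        sem_post=sp_,
        n_bouts_baseline=nb,
        n_bouts_post=np_,
    )
    return summary, table


def learning_score(freeze_test_pct: float, freeze_baseline_pct: float) -> float:
    """Behavioral consolidation score: percentage points of context freezing
    at test minus pre-shock baseline.  Negative scores are allowed."""
    for v in (freeze_test_pct, freeze_baseline_pct):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"freezing percentage out of [0, 100]: {v}")
    return float(freeze_test_pct - freeze_baseline_pct)


def group_change_summary(subjects: list[GroupSummary]) -> pd.DataFrame:
    """Per-condition mean Δσ = σ_post − σ_baseline with sem and a one-sample
    t-test of Δσ < 0 (one-sided); groups of size < 2 get no test."""
    per = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "condition": [s.condition for s in subjects],
            "delta_sigma": [s.delta_sigma for s in subjects],
        }
    )
    rows = []
    for cond, g in per.groupby("condition"):
        d = g["delta_sigma"].dropna().values
        row = {
            "condition": cond,
            "n_subjects": len(d),
            "mean_delta_sigma": float(np.mean(d)) if len(d) else float("nan"),
            "sem_delta_sigma": (
                float(np.std(d, ddof=1) / np.sqrt(len(d))) if len(d) > 1 else float("nan")
            ),
            "t_statistic": float("nan"),
            "p_value": float("nan"),
        }
        if len(d) >= 2:
            t = scipy.stats.ttest_1samp(d, 0.0, alternative="less")
            row["t_statistic"] = float(t.statistic)
            row["p_value"] = float(t.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
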