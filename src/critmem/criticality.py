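"""Critical-temperature estimation, learning-induced T_c shifts, and the
capacity/loading phase diagram.

Two order parameters locate the transition: the overlap with a stored
memory (high below T_c, near zero above) and the network stability — the
per-sweep fraction of state changes, which rises from 0 toward 1/2 across
the transition.  T_c is read off either by linear interpolation of the
half-maximum crossing or by fitting the sigmoid
f(T) = 0.5 / (1 + exp(−(T − T_c)/μ)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from critmem.learning import LearningConfig, SweepGrid, protocol_learn_sweep

__all__ = [
    "TransitionFit",
    "tc_from_halfmax",
    "fit_sigmoid_stability",
    "delta_tc_vs_epsilon",
    "capacity_diagram",
    "hopfield_capacity_check",
]


@dataclass(frozen=True)
class TransitionFit:
    """Estimated transition: half-max temperature t_c, slope μ (sigmoid
    width; NaN for pure interpolation), method tag, and a residual
    (R² for fits, 0 for interpolation)."""

    t_c: float
    slope: float
    method: str
    residual: float = 0.0


def tc_from_halfmax(
    temperatures: np.ndarray, values: np.ndarray
) -> TransitionFit:
    """Half-maximum crossing of an order-parameter curve by linear
    interpolation between the bracketing point pair.

    The half level is half of the curve's observed maximum (robust to
    imperfect low-T recall).  Decreasing curves (overlap) use the first
    downward crossing; increasing curves (flip fraction) the first upward
    crossing.
    """
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(values, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 points to locate a transition")
    half = y.max() / 2.0
    increasing = y[-1] > y[0]

    if increasing:
        above = y >= half
        if not above.any() or above[0]:
            raise ValueError("curve never crosses half-maximum upward")
        j = int(np.argmax(above))
    else:
        below = y <= half
        if not below.any() or below[0]:
            raise ValueError("curve never crosses half-maximum downward")
        j = int(np.argmax(below))

    t0, t1 = T[j - 1], T[j]
    y0, y1 = y[j - 1], y[j]
    tc = t0 if y1 == y0 else t0 + (half - y0) * (t1 - t0) / (y1 - y0)
    return TransitionFit(t_c=float(tc), slope=float("nan"), method="interpolation")


def _sigmoid(T, tc, mu):
    return 0.5 / (1.0 + np.exp(-(T - tc) / mu))


def fit_sigmoid_stability(
    temperatures: np.ndarray, flip_fraction: np.ndarray
) -> TransitionFit:
    """Least-squares fit of f(T) = 0.5/(1+exp(−(T−T_c)/μ)) to a stability
    curve normalized to [0, 0.5]; falls back to half-max interpolation if
    the optimizer fails."""
    T = np.asarray(temperatures, dtype=float)
    y = np.asarray(flip_fraction, dtype=float)
    try:
        guess_tc = tc_from_halfmax(T, y).t_c
    except ValueError:
        guess_tc = float(T.mean())
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = scipy.optimize.curve_fit(
                _sigmoid,
                T,
                y,
                p0=(guess_tc, max(0.1, 0.1 * (T[-1] - T[0]))),
                bounds=([T[0] - 5.0, 1e-6], [T[-1] + 5.0, 10.0 * (T[-1] - T[0])]),
                maxfev=10000,
            )
    except (RuntimeError, ValueError):
        warnings.warn("sigmoid fit failed; falling back to half-max interpolation")
        fb = tc_from_halfmax(T, y)
        return TransitionFit(fb.t_c, fb.slope, "interpolation_fallback", 0.0)
    resid = y - _sigmoid(T, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return TransitionFit(float(popt[0]), float(popt[1]), "sigmoid_fit", r2)


def delta_tc_vs_epsilon(
    epsilons: np.ndarray,
    grid: SweepGrid,
    p: int = 1,
    input_size: int = 70,
    input_weight: float = 3.0,
    config: LearningConfig | None = None,
) -> pd.DataFrame:
    """Critical-temperature shift as a function of the learning rate.

    For each ε the learn protocol is run; sigmoids are fitted to the pre-
    and post-learning stability curves and the signed shift
    ΔT_c = T_c(post) − T_c(pre) recorded.  The returned frame carries the
    least-squares linear slope and R² of ΔT_c vs ε as attributes
    ``linear_slope`` / ``linear_r2``.
    """
    eps = np.asarray(epsilons, dtype=float)
    if eps.size == 0 or np.any(eps <= 0):
        raise ValueError("epsilons must be non-empty and positive")
    if config is None:
        # short consolidation burst: with the unbounded rule, long learning
        # pushes the post-learning transition far beyond any practical sweep
        # window; 20 interleaved sweeps keep both transitions measurable
        config = LearningConfig(phase_lengths=(100, 20, 100))
    rows = []
    for e in eps:
        res = protocol_learn_sweep(
            grid, p, input_size, input_weight, learning_rate=e, config=config
        )
        fit_pre = fit_sigmoid_stability(grid.temperatures, res.pre.flip_fraction)
        fit_post = fit_sigmoid_stability(grid.temperatures, res.post.flip_fraction)
        rows.append(
            {
                "epsilon": e,
                "tc_pre": fit_pre.t_c,
                "tc_post": fit_post.t_c,
                "delta_tc": fit_post.t_c - fit_pre.t_c,
            }
        )
    out = pd.DataFrame(rows)
    slope, intercept = np.polyfit(out["epsilon"], out["delta_tc"], 1)
    pred = slope * out["epsilon"] + intercept
    ss_res = float(((out["delta_tc"] - pred) ** 2).sum())
    ss_tot = float(((out["delta_tc"] - out["delta_tc"].mean()) ** 2).sum())
    out.attrs["linear_slope"] = float(slope)
    out.attrs["linear_r2"] = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return out


def capacity_diagram(
    p_values: np.ndarray,
    grid: SweepGrid,
    input_size: int = 70,
    input_weight: float = 3.0,
    learning_rate: float = 0.1,
    config: LearningConfig | None = None,
    stability_threshold: float = 0.45,
) -> pd.DataFrame:
    """Phase map over memory loading α = p/⟨k⟩ and temperature.

    Per (p, T): whether the pre-learning network retains a native memory
    (m^n ≥ 0.45) and whether learning consolidates the new configuration
    (m^e ≥ 0.45).  The pre-learning critical line is the first temperature
    where native stability is lost.  Loadings above the nominal capacity
    0.14·⟨k⟩ are allowed but flagged.
    """
    rows = []
    for p in np.asarray(p_values, dtype=int):
        res = protocol_learn_sweep(
            grid, int(p), input_size, input_weight, learning_rate, config
        )
        alpha = p / grid.in_degree
        above = alpha > 0.14
        tc_line = np.nan
        lost = res.pre.overlap_native < stability_threshold
        if lost.any():
            tc_line = float(grid.temperatures[int(np.argmax(lost))])
        for i, T in enumerate(grid.temperatures):
            rows.append(
                {
                    "p": int(p),
                    "alpha": alpha,
                    "temperature": float(T),
                    "native_stable_pre": bool(
                        res.pre.overlap_native[i] >= stability_threshold
                    ),
                    "consolidated_post": bool(
                        res.post.overlap_new[i] >= stability_threshold
                    ),
                    "overlap_native_pre": float(res.pre.overlap_native[i]),
                    "overlap_new_post": float(res.post.overlap_new[i]),
                    "tc_pre_line": tc_line,
                    "above_nominal_capacity": above,
                }
            )
    return pd.DataFrame(rows)


def _deterministic_recall_ok(
    J: np.ndarray, patterns: np.ndarray, threshold: float, n_sweeps: int = 50
) -> bool:
    """T = 0 recall test: from each stored pattern, run deterministic sign
    alignment and require the final overlap to stay above threshold.

    All patterns relax in parallel as columns of one state matrix; sign(0)
    keeps the current state.  Synchronous period-2 orbits simply exhaust the
    sweep budget, after which the overlap is measured as-is.
    """
    S = patterns.T.astype(np.float64).copy()  # (N, p)
    prev = None
    for _ in range(n_sweeps):
        H = J @ S
        new = np.where(H == 0, S, np.sign(H))
        if np.array_equal(new, S) or (prev is not None and np.array_equal(new, prev)):
            S = new
            break
        prev = S
        S = new
    m = np.abs(np.mean(patterns.T * S, axis=0))
    return bool((m >= threshold).all())


def hopfield_capacity_check(
    n_neurons: int = 500,
    recall_threshold: float = 0.9,
    n_seeds: int = 10,
    seed: int = 0,
) -> float:
    """Estimate the maximal loading α_max = p_max/N of the fully connected
    outer-product network under deterministic (T = 0) dynamics.

    For a given p, recall succeeds if relaxation from every stored pattern
    keeps its overlap ≥ ``recall_threshold``.  p_max is found by bisection
    (resolution Δp = max(1, N/200)) and averaged over seeds; the classic
    result is α_max ≈ 0.14.
    """
    dp = max(1, n_neurons // 200)
    rngs = np.random.SeedSequence(seed).spawn(n_seeds)
    alpha_max = []
    for ss in rngs:
        rng = np.random.default_rng(ss)
        # one large pattern bank per seed; loadings use its prefix
        p_hi_bound = int(0.3 * n_neurons)
        bank = rng.choice((-1, 1), size=(p_hi_bound, n_neurons)).astype(np.float64)

        def ok(p):
            patt = bank[:p]
            J = (patt.T @ patt) / p
            np.fill_diagonal(J, 0.0)
            return _deterministic_recall_ok(J, patt, recall_threshold)

        lo, hi = 1, p_hi_bound
        if not ok(lo):
            alpha_max.append(0.0)
            continue
        while ok(hi) and hi < n_neurons:
            hi = min(n_neurons, hi * 2)
        while hi - lo > dp:
            mid = (lo + hi) // 2
            if ok(mid):
                lo = mid
            else:
                hi = mid
        alpha_max.append(lo / n_neurons)
    return float(np.mean(alpha_max))
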