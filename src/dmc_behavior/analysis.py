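"""Behavioral statistics: outcome rates, d-prime, psychometric MLE fits,
reaction times, rolling performance, pre-stimulus turning regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import erf

__all__ = [
    "OutcomeCounts",
    "PsychometricFit",
    "rates",
    "dprime",
    "psychometric_value",
    "fit_psychometric",
    "rolling_performance",
    "reaction_time",
    "prestim_rt_regression",
    "session_bias",
    "filter_first_minutes",
    "per_level_choices",
]


@dataclass(frozen=True)
class OutcomeCounts:
    """Go/NoGo outcome tallies used for H, F, and d-prime."""

    n_hit: int
    n_miss: int
    n_cr: int
    n_fa: int

    def __post_init__(self) -> None:
        if min(self.n_hit, self.n_miss, self.n_cr, self.n_fa) < 0:
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_trials(cls, trials) -> "OutcomeCounts":
        out = [t.outcome for t in trials]
        return cls(
            n_hit=out.count("hit"),
            n_miss=out.count("miss"),
            n_cr=out.count("correct_rejection"),
            n_fa=out.count("false_alarm"),
        )


def rates(counts: OutcomeCounts) -> tuple[float, float]:
    """Hit rate H = hits/(hits+misses) and false-alarm rate F = fa/(fa+cr)."""
    n_go = counts.n_hit + counts.n_miss
    n_nogo = counts.n_fa + counts.n_cr
    if n_go == 0 or n_nogo == 0:
        raise ValueError("need at least one Go and one NoGo trial")
    return counts.n_hit / n_go, counts.n_fa / n_nogo


def dprime(counts: OutcomeCounts) -> float:
    """Discriminability d' = z(H) - z(F).

    Rates at 0 or 1 are clamped to [1/(2N), 1 - 1/(2N)] with N the
    respective trial count, keeping the z-scores finite.
    """
    h, f = rates(counts)
    n_go = counts.n_hit + counts.n_miss
    n_nogo = counts.n_fa + counts.n_cr
    h = float(np.clip(h, 1 / (2 * n_go), 1 - 1 / (2 * n_go)))
    f = float(np.clip(f, 1 / (2 * n_nogo), 1 - 1 / (2 * n_nogo)))
    return float(stats.norm.ppf(h) - stats.norm.ppf(f))


def psychometric_value(
    x, lapse1: float, lapse2: float, bias: float, slope: float
):
    """P(right | x) = lapse1 + (1 - lapse1 - lapse2) * (erf((x - bias)/slope) + 1)/2."""
    x = np.asarray(x, dtype=float)
    p = lapse1 + (1 - lapse1 - lapse2) * (erf((x - bias) / slope) + 1) / 2
    return p if p.ndim else float(p)


@dataclass
class PsychometricFit:
    """Fitted psychometric parameters plus diagnostics."""

    lapse1: float
    lapse2: float
    bias: float
    slope: float
    nll: float
    x: np.ndarray = field(default_factory=lambda: np.empty(0))
    n: np.ndarray = field(default_factory=lambda: np.empty(0))
    k: np.ndarray = field(default_factory=lambda: np.empty(0))
    at_bounds: dict = field(default_factory=dict)

    def __call__(self, x):
        return psychometric_value(x, self.lapse1, self.lapse2, self.bias, self.slope)


_BOUNDS = [(0.0, 0.5), (0.0, 0.5), (-100.0, 100.0), (1.0, 300.0)]


def _nll(params, x, n, k):
    l1, l2, bias, slope = params
    p = np.clip(psychometric_value(x, l1, l2, bias, slope), 1e-9, 1 - 1e-9)
    return -float(np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def fit_psychometric(
    x: Sequence[float], n: Sequence[int], k: Sequence[int]
) -> PsychometricFit:
    """Maximum-likelihood psychometric fit of right-choice counts.

    Parameters
    ----------
    x, n, k
        Signed stimulus strengths, trials per level, right choices per level.

    Bounded L-BFGS-B over (lapse1, lapse2, bias, slope) from a fixed start
    grid; the best negative log-likelihood is retained, so the result is
    deterministic given the data. Degenerate data return a fit with boundary
    flags rather than raising.
    """
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("need at least 2 distinct stimulus strengths")
    if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
        raise ValueError("invalid per-level counts")

    starts = [
        (l, l, b, s)
        for l in (0.01, 0.1)
        for b in (-20.0, 0.0, 20.0)
        for s in (3.0, 10.0, 30.0, 80.0)
    ]
    def _preference(params):
        # tie-break among likelihood-equivalent optima (degenerate data make
        # the likelihood flat): prefer small |bias|, then small slope
        return abs(params[2]) + 0.01 * params[3]

    best = None
    for p0 in starts:
        res = optimize.minimize(
            _nll, p0, args=(x, n, k), method="L-BFGS-B", bounds=_BOUNDS
        )
        if (
            best is None
            or res.fun < best.fun - 1e-6
            or (res.fun < best.fun + 1e-6 and _preference(res.x) < _preference(best.x))
        ):
            best = res
    l1, l2, bias, slope = best.x
    at_bounds = {
        "lapse1": l1 <= _BOUNDS[0][0] + 1e-9 or l1 >= _BOUNDS[0][1] - 1e-9,
        "lapse2": l2 <= _BOUNDS[1][0] + 1e-9 or l2 >= _BOUNDS[1][1] - 1e-9,
        "bias": abs(bias) >= _BOUNDS[2][1] - 1e-6,
        "slope": slope <= _BOUNDS[3][0] + 1e-6 or slope >= _BOUNDS[3][1] - 1e-6,
    }
    return PsychometricFit(
        lapse1=float(l1),
        lapse2=float(l2),
        bias=float(bias),
        slope=float(slope),
        nll=float(best.fun),
        x=x,
        n=n,
        k=k,
        at_bounds=at_bounds,
    )


def per_level_choices(trials) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Aggregate responded 2AFC trials into (x, n, k) right-choice counts."""
    data: dict[float, list[int]] = {}
    for t in trials:
        if t.turn_direction == "none":
            continue
        xs = float(t.signed_strength)
        cnt = data.setdefault(xs, [0, 0])
        cnt[0] += 1
        cnt[1] += int(t.turn_direction == "right")
    levels = sorted(data)
    x = np.array(levels)
    n = np.array([data[v][0] for v in levels], dtype=float)
    k = np.array([data[v][1] for v in levels], dtype=float)
    return x, n, k


def rolling_performance(correct: Sequence, window: int = 10) -> np.ndarray:
    """Trailing-window mean of a correct indicator; NaN before a full window.

    ``correct`` may be booleans/0-1 or trial records with an ``outcome``.
    """
    vals = [
        c.outcome in ("correct", "hit", "correct_rejection")
        if hasattr(c, "outcome")
        else bool(c)
        for c in correct
    ]
    arr = np.asarray(vals, dtype=float)
    out = np.full(len(arr), np.nan)
    if len(arr) >= window:
        csum = np.concatenate([[0.0], np.cumsum(arr)])
        out[window - 1 :] = (csum[window:] - csum[:-window]) / window
    return out


def reaction_time(trial) -> Optional[float]:
    """Time from stimulus onset to the turning-goal crossing, None if absent."""
    if trial.response_time is None:
        return None
    return trial.response_time - trial.stim_onset


def prestim_rt_regression(trials) -> tuple[float, float, float]:
    """OLS of RT on accumulated pre-stimulus turning: (slope, intercept, R^2)."""
    pts = [
        (t.prestim_turning, t.rt)
        for t in trials
        if t.rt is not None
    ]
    if len(pts) < 3:
        raise ValueError("need at least 3 trials with RT and pre-stimulus turning")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def session_bias(trials) -> float:
    """Percent of responded trials answered with a rightward turn."""
    responded = [t for t in trials if t.turn_direction != "none"]
    if not responded:
        raise ValueError("no responded trials")
    n_right = sum(1 for t in responded if t.turn_direction == "right")
    return 100.0 * n_right / len(responded)


def filter_first_minutes(session, minutes: float = 20.0):
    """Trials starting within the first ``minutes`` of the session."""
    cutoff = session.t_start + minutes * 60.0
    return [t for t in session.trials if t.t_start < cutoff]
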