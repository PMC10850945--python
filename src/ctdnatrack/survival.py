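"""Mutation-stratified progression-free-survival analysis.

Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
the two-group Cox hazard ratio is fit in-package by Newton iteration on the
one-parameter partial likelihood, with Breslow tie handling as the default
and Efron available by flag.

Orientation convention: the hazard ratio is reported for the "detected"
group (group == 1) relative to "not detected" (group == 0); HR > 1 denotes
worse PFS for the detected group. Because published survival figures can
print the reciprocal orientation, the convention is recorded on the result
rather than assumed by readers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "ConvergenceError",
    "CoxResult",
    "KMResult",
    "cox_two_group",
    "km_estimate",
    "logrank_test",
    "plot_km",
]

ORIENTATION_NOTE = "HR for detected vs not detected; HR > 1 denotes worse PFS for the detected group"


class ConvergenceError(RuntimeError):
    """Cox fit diverged (typically complete separation of event histories)."""


@dataclass(frozen=True)
class KMResult:
    """Product-limit estimate for one group; ``median`` is None if never reached."""

    times: np.ndarray
    survival: np.ndarray
    median: Optional[float]
    n: int
    n_events: int


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMResult:
    """Kaplan–Meier product-limit estimator for one group."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("cannot estimate survival from an empty group")
    if np.any(t < 0):
        raise ValueError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    median = float(kmf.median_survival_time_)
    return KMResult(
        times=kmf.survival_function_.index.to_numpy(dtype=float),
        survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        median=None if np.isinf(median) else median,
        n=int(t.size),
        n_events=int(e.sum()),
    )


def logrank_test(
    times_a: Sequence[float], events_a: Sequence[bool],
    times_b: Sequence[float], events_b: Sequence[bool],
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p), 1 df."""
    ta, tb = np.asarray(times_a, float), np.asarray(times_b, float)
    ea, eb = np.asarray(events_a, bool), np.asarray(events_b, bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be nonempty")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass(frozen=True)
class CoxResult:
    hazard_ratio: float
    ci_low: float
    ci_high: float
    beta: float
    se: float
    n: int
    n_events: int
    ties: str
    orientation: str = ORIENTATION_NOTE


def _cox_score_info(
    beta: float,
    event_times: np.ndarray,
    d_total: np.ndarray,
    d_group1: np.ndarray,
    at_risk1: np.ndarray,
    at_risk0: np.ndarray,
    ties: str,
) -> tuple[float, float]:
    """Score U(beta) and information I(beta) for a binary covariate."""
    eb = np.exp(beta)
    U = 0.0
    I = 0.0
    for k in range(event_times.size):
        d, s = d_total[k], d_group1[k]
        S0 = at_risk0[k] + at_risk1[k] * eb
        S1 = at_risk1[k] * eb
        if ties == "breslow":
            p = S1 / S0
            U += s - d * p
            I += d * p * (1.0 - p)
        else:  # efron
            tied_all = (d - s) + s * eb
            tied_1 = s * eb
            for ell in range(d):
                frac = ell / d
                D = S0 - frac * tied_all
                N = S1 - frac * tied_1
                p = N / D
                U += s / d - p
                I += p * (1.0 - p)
    return U, I


def cox_two_group(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
    ties: str = "breslow",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Fit the one-covariate Cox model by Newton–Raphson.

    The covariate is the binary detected/not-detected label; the 95% CI is
    exp(beta +/- 1.96 * SE) with SE from the observed information at the
    maximum. Raises :class:`ConvergenceError` when the partial likelihood
    has no interior maximum (complete separation) and ``ValueError`` when a
    group has no events.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    x = np.asarray(group, int)
    if not set(np.unique(x)) <= {0, 1}:
        raise ValueError("group labels must be binary 0/1")
    if e[x == 1].sum() == 0 or e[x == 0].sum() == 0:
        raise ValueError("each group needs at least one event")

    event_times = np.unique(t[e])
    d_total = np.array([int(np.sum(e & (t == tau))) for tau in event_times])
    d_group1 = np.array([int(np.sum(e & (t == tau) & (x == 1))) for tau in event_times])
    at_risk1 = np.array([int(np.sum((t >= tau) & (x == 1))) for tau in event_times])
    at_risk0 = np.array([int(np.sum((t >= tau) & (x == 0))) for tau in event_times])

    beta = 0.0
    for _ in range(max_iter):
        U, I = _cox_score_info(beta, event_times, d_total, d_group1, at_risk1, at_risk0, ties)
        if I <= 1e-12:
            raise ConvergenceError("information vanished; cannot estimate hazard ratio")
        step = U / I
        beta += step
        if abs(beta) > 15.0:
            raise ConvergenceError(
                "diverging coefficient (|beta| > 15): complete separation of event histories"
            )
        if abs(step) < tol:
            break
    else:
        raise ConvergenceError(f"Newton iteration did not converge in {max_iter} steps")

    _, I = _cox_score_info(beta, event_times, d_total, d_group1, at_risk1, at_risk0, ties)
    se = 1.0 / np.sqrt(I)
    return CoxResult(
        hazard_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        beta=float(beta),
        se=float(se),
        n=int(t.size),
        n_events=int(e.sum()),
        ties=ties,
    )


def plot_km(
    times: Sequence[float], events: Sequence[bool], group: Sequence[int],
    path: str, labels: tuple[str, str] = ("not detected", "detected"),
) -> None:
    """Write a two-group Kaplan–Meier plot to ``path``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(times, float)
    e = np.asarray(events, bool)
    x = np.asarray(group, int)
    fig, ax = plt.subplots(figsize=(5, 4))
    for g, label in zip((0, 1), labels):
        if np.sum(x == g) == 0:
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[x == g], event_observed=e[x == g], label=label)
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("progression-free survival")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
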