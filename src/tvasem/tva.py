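"""Whole-report race model: closed-form score distribution and ML estimation.

The model treats a brief display of ``n`` items as a parallel exponential
race.  Each item accrues evidence at rate C/n (items per second), the race
runs for the effective exposure ``max(0, exposure - t0)``, and at most K
items can be encoded into visual short-term memory.  A fractional capacity
K is realized as a per-trial mixture of the two adjacent integer capacities.
The three parameters have the usual interpretation:

C   total visual processing speed, items/second
K   VSTM storage capacity, items (0 < K <= n, may be fractional)
t0  perceptual threshold, ms of exposure below which nothing is encoded
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "TvaParams",
    "WholeReportTrial",
    "TvaFit",
    "score_distribution",
    "whole_report_loglik",
    "fit_whole_report",
    "laterality_ok",
    "score_histograms",
]

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class TvaParams:
    """Race-model parameters (C items/s, K items, t0 ms)."""

    C: float
    K: float
    t0: float
    n_items: int = 6

    def __post_init__(self) -> None:
        if not self.C > 0:
            raise ValueError(f"C must be positive, got {self.C}")
        if not 0 < self.K <= self.n_items:
            raise ValueError(f"K must be in (0, {self.n_items}], got {self.K}")
        if self.t0 < 0:
            raise ValueError(f"t0 must be non-negative, got {self.t0}")


@dataclass(frozen=True)
class WholeReportTrial:
    """One brief-exposure display/report event.

    ``displayed`` is a string of six distinct letters; by convention the
    first three occupy the left hemifield and the last three the right.
    ``reported`` holds the correctly reported subset (unordered).
    """

    participant_id: str
    exposure_ms: float
    displayed: str
    reported: str

    def __post_init__(self) -> None:
        if self.exposure_ms <= 0:
            raise ValueError("exposure_ms must be positive")
        if len(set(self.displayed)) != len(self.displayed):
            raise ValueError("displayed letters must be distinct")
        if not set(self.reported) <= set(self.displayed):
            raise ValueError("reported must be a subset of displayed")

    @property
    def score(self) -> int:
        return len(self.reported)

    @property
    def n_left_correct(self) -> int:
        half = len(self.displayed) // 2
        left = set(self.displayed[:half])
        return sum(1 for ch in self.reported if ch in left)


@dataclass
class TvaFit:
    """Maximum-likelihood fit of (C, K, t0) to whole-report trials."""

    params: TvaParams
    loglik: float
    converged: bool
    n_trials: int
    laterality_index: float | None
    at_bounds: bool = False
    start_used: tuple[float, float, float] | None = field(default=None, repr=False)


def _capped_binomial(b: np.ndarray, k: int) -> np.ndarray:
    """Score pmf when at most ``k`` of the binomial finishers can be stored."""
    v = np.zeros_like(b)
    v[..., :k] = b[..., :k]
    v[..., k] = b[..., k:].sum(axis=-1)
    return v


def _score_matrix(params: TvaParams, exposures_ms: np.ndarray, n_items: int) -> np.ndarray:
    """(len(exposures), n_items+1) matrix of score probabilities."""
    t_e = np.maximum(0.0, np.asarray(exposures_ms, dtype=float) - params.t0) / 1000.0
    p = 1.0 - np.exp(-(params.C / n_items) * t_e)
    s = np.arange(n_items + 1)
    b = stats.binom.pmf(s, n_items, p[:, None])
    k_lo = int(np.floor(params.K))
    frac = params.K - k_lo
    if k_lo == 0:
        lo = np.zeros_like(b)
        lo[:, 0] = 1.0
    else:
        lo = _capped_binomial(b, k_lo)
    if frac < 1e-12:
        return lo
    hi = _capped_binomial(b, min(k_lo + 1, n_items))
    return (1.0 - frac) * lo + frac * hi


def score_distribution(
    params: TvaParams, exposure_ms: float, n_items: int = 6
) -> np.ndarray:
    """Probability vector over scores 0..n_items for a single exposure.

    With effective exposure t_e = max(0, exposure - t0)/1000 s, each item
    independently finishes with probability p = 1 - exp(-(C/n)·t_e); the
    score is min(k*, B) with B ~ Binomial(n, p) and k* the adjacent-integer
    mixture realizing fractional K.
    """
    if params.n_items != n_items:
        params = TvaParams(params.C, params.K, params.t0, n_items=n_items)
    if exposure_ms <= 0:
        raise ValueError("exposure_ms must be positive")
    return _score_matrix(params, np.array([exposure_ms]), n_items)[0]


def score_histograms(
    trials: Iterable[WholeReportTrial], n_items: int = 6
) -> dict[float, np.ndarray]:
    """Per-exposure histograms of scores, keyed by exposure in ms."""
    out: dict[float, np.ndarray] = {}
    for tr in trials:
        h = out.setdefault(float(tr.exposure_ms), np.zeros(n_items + 1, dtype=int))
        h[tr.score] += 1
    return out


def whole_report_loglik(
    params: TvaParams,
    counts: Mapping[float, Sequence[float]],
    n_items: int = 6,
) -> float:
    """Multinomial log-likelihood of per-exposure score histograms.

    Probabilities are floored at 1e-12 before the log so the result is
    always finite; the combinatorial constant is omitted (it does not
    depend on the parameters).
    """
    exposures = np.array(sorted(counts), dtype=float)
    if exposures.size == 0:
        raise ValueError("counts is empty")
    cmat = np.array([counts[e] for e in exposures], dtype=float)
    if cmat.shape[1] != n_items + 1:
        raise ValueError(f"histograms must have {n_items + 1} bins (scores 0..{n_items})")
    if np.any(cmat < 0):
        raise ValueError("negative counts")
    if not np.any(cmat > 0):
        raise ValueError("at least one nonzero cell required")
    probs = _score_matrix(params, exposures, n_items)
    return float(np.sum(cmat * np.log(np.maximum(probs, _PROB_FLOOR))))


# Deterministic coarse grid over plausible whole-report values.  The high-K
# starts exceed 5 on purpose: with K <= 5 a score of 6 has probability zero,
# so data containing full reports leave the likelihood flat in K there.
_DEFAULT_STARTS = [
    (15.0, 2.0, 10.0),
    (15.0, 5.5, 10.0),
    (45.0, 2.0, 10.0),
    (45.0, 5.5, 10.0),
    (90.0, 2.0, 10.0),
    (90.0, 5.5, 10.0),
    (45.0, 3.5, 30.0),
]


def fit_whole_report(
    trials: Sequence[WholeReportTrial],
    bounds: Mapping[str, tuple[float, float]] | None = None,
    starts: Sequence[tuple[float, float, float]] | None = None,
    n_items: int = 6,
) -> TvaFit:
    """Fit (C, K, t0) by maximum likelihood with deterministic multistart.

    Box bounds default to C in [1, 200], K in [0.5, n], t0 in
    [0, min exposure].  Each start is refined with bounded Nelder-Mead;
    ties are broken by the first start reaching the best log-likelihood.
    Refitting the same trials yields an identical result.
    """
    trials = list(trials)
    if not trials:
        raise ValueError("no trials to fit")
    counts = score_histograms(trials, n_items)
    if len(counts) < 2:
        warnings.warn("fewer than 2 distinct exposure durations; t0 and C are poorly separated")
    if len(trials) < 50:
        warnings.warn(f"only {len(trials)} trials; estimates may be unstable")

    min_exp = min(counts)
    b = {
        "C": (1.0, 200.0),
        "K": (0.5, float(n_items)),
        "t0": (0.0, float(min_exp)),
    }
    if bounds:
        b.update(bounds)
    box = [b["C"], b["K"], b["t0"]]

    all_zero = all(int(h[1:].sum()) == 0 for h in counts.values())

    def neg_ll(x: np.ndarray) -> float:
        params = TvaParams(
            min(max(x[0], box[0][0]), box[0][1]),
            min(max(x[1], box[1][0]), box[1][1]),
            min(max(x[2], box[2][0]), box[2][1]),
            n_items=n_items,
        )
        return -whole_report_loglik(params, counts, n_items)

    start_list = list(starts) if starts is not None else _DEFAULT_STARTS
    clipped = [
        tuple(min(max(s[i], box[i][0]), box[i][1]) for i in range(3)) for s in start_list
    ]

    best = None
    for s in clipped:
        res = optimize.minimize(
            neg_ll,
            np.array(s, dtype=float),
            method="Nelder-Mead",
            bounds=box,
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if best is None or res.fun < best[0].fun - 1e-10:
            best = (res, s)
    res, start_used = best

    x = np.array([min(max(res.x[i], box[i][0]), box[i][1]) for i in range(3)])
    params = TvaParams(x[0], x[1], x[2], n_items=n_items)
    at_bounds = any(
        np.isclose(x[i], box[i][0]) or np.isclose(x[i], box[i][1]) for i in range(3)
    )
    if all_zero:
        warnings.warn("all trials report 0 items; fit lies on the parameter boundary")

    n_correct = sum(t.score for t in trials)
    lat = None
    if n_correct > 0:
        lat = sum(t.n_left_correct for t in trials) / n_correct

    return TvaFit(
        params=params,
        loglik=-res.fun,
        converged=bool(res.success) or all_zero,
        n_trials=len(trials),
        laterality_index=lat,
        at_bounds=at_bounds,
        start_used=start_used,
    )


def laterality_ok(fit: TvaFit, low: float = 0.3, high: float = 0.7) -> bool:
    """True iff the left-side report fraction lies in [low, high] (inclusive).

    An index outside this range indicates a strong spatial bias: the
    participant sampled only one hemifield, which undermines the capacity
    estimate.  An undefined index (no correct reports) also fails.
    """
    if fit.laterality_index is None:
        return False
    return low <= fit.laterality_index <= high
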