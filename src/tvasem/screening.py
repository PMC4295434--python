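"""MAD-based outlier screening at trial and subject level.

The pipeline is fully automated: response-time trials are square-root
transformed and filtered at ±2.5 scaled MADs around the median, subject
scores are the mean of the surviving raw trials, and subject-level
screening applies the same ±2.5 MAD rule per measure (untransformed)
across the cohort.  Flagging any measure of a test masks every measure of
that test for that subject, so a valid-but-meaningless companion measure
(e.g. the RT of a random responder) cannot survive on its own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import TEST_MEASURES, DWM_GUESS_RATE

__all__ = [
    "mad",
    "MadFilterResult",
    "mad_filter",
    "clean_trial_rts",
    "ScreeningReport",
    "screen_subjects",
]

MAD_SCALE = 1.4826  # consistency constant vs. the Gaussian SD
MAD_CUTOFF = 2.5


def mad(values: Sequence[float], scale_constant: float = MAD_SCALE) -> float:
    """Scaled median absolute deviation: c · median(|x - median(x)|)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("mad requires at least one finite value")
    return float(scale_constant * np.median(np.abs(x - np.median(x))))


@dataclass
class MadFilterResult:
    kept_mask: np.ndarray
    median: float
    mad: float
    lower: float
    upper: float
    transform: str = "none"

    @property
    def n_excluded(self) -> int:
        return int((~self.kept_mask).sum())


def mad_filter(
    values: Sequence[float],
    k: float = MAD_CUTOFF,
    transform: str = "none",
    scale_constant: float = MAD_SCALE,
) -> MadFilterResult:
    """Flag values outside median ± k·MAD, optionally on the sqrt scale.

    Values exactly at a bound are kept.  When the MAD degenerates to 0
    (over half the values identical) only exact matches to the median
    survive — the limit of the rule as MAD → 0.  NaNs are excluded from
    the statistics and flagged as not kept.
    """
    x = np.asarray(values, dtype=float)
    if transform == "sqrt":
        neg = np.where(x < 0)[0]
        if neg.size:
            raise ValueError(f"sqrt transform requires non-negative values; first offender index {neg[0]}")
        t = np.sqrt(x)
    elif transform == "none":
        t = x
    else:
        raise ValueError(f"unknown transform {transform!r}")
    finite = np.isfinite(t)
    if not finite.any():
        raise ValueError("mad_filter requires at least one finite value")
    med = float(np.median(t[finite]))
    m = float(scale_constant * np.median(np.abs(t[finite] - med)))
    if m == 0.0:
        kept = finite & (t == med)
        return MadFilterResult(kept, med, m, med, med, transform)
    lower, upper = med - k * m, med + k * m
    kept = finite & (t >= lower) & (t <= upper)
    return MadFilterResult(kept, med, m, lower, upper, transform)


def clean_trial_rts(
    rts: Sequence[float],
    k: float = MAD_CUTOFF,
    transform: str = "sqrt",
    min_trials: int = 5,
) -> tuple[float, int]:
    """Subject RT score: mean of raw trials surviving the transformed MAD filter.

    Correct and incorrect trials are pooled — with difficulty-limited tasks
    an error trial still carries a valid response time.  Returns
    (mean_rt, n_excluded); the mean is NaN when nothing survives.
    """
    x = np.asarray(rts, dtype=float)
    if x[np.isfinite(x)].size < min_trials:
        raise ValueError(f"need at least {min_trials} trials, got {x[np.isfinite(x)].size}")
    res = mad_filter(x, k=k, transform=transform)
    kept = x[res.kept_mask]
    n_excluded = int(np.isfinite(x).sum() - kept.size)
    if kept.size == 0:
        return float("nan"), n_excluded
    return float(kept.mean()), n_excluded


@dataclass
class ScreeningReport:
    """Bookkeeping of everything the screening pipeline masked and why."""

    table: pd.DataFrame
    flags: pd.DataFrame
    subject_reasons: dict[str, list[str]] = field(default_factory=dict)
    n_excluded_per_test: dict[str, int] = field(default_factory=dict)
    trial_exclusion_fractions: dict[str, float] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "n_excluded_per_test": self.n_excluded_per_test,
            "subject_reasons": self.subject_reasons,
            "trial_exclusion_fractions": self.trial_exclusion_fractions,
            "n_flagged_cells": int(self.flags.to_numpy().sum()),
        }
        s = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def screen_subjects(
    measure_table: pd.DataFrame,
    laterality_ok: Mapping[str, bool] | pd.Series | None = None,
    k: float = MAD_CUTOFF,
    tests: Mapping[str, tuple[str, ...]] = TEST_MEASURES,
) -> ScreeningReport:
    """Subject-level ±k·MAD screening with whole-test masking.

    Each measure column is screened across subjects on its raw scale; a
    flag on any measure of a test masks all of that test's measures for
    that subject.  TVA measures are additionally masked for subjects whose
    laterality check failed.  Columns outside the known battery (other
    than ``Age``) are rejected.
    """
    known = {m for ms in tests.values() for m in ms}
    measure_cols = [c for c in measure_table.columns if c != "Age"]
    unknown = set(measure_cols) - known
    if unknown:
        raise ValueError(f"unknown measure columns: {sorted(unknown)}")

    flags = pd.DataFrame(False, index=measure_table.index, columns=measure_cols)
    for col in measure_cols:
        x = measure_table[col].to_numpy(dtype=float)
        if np.isfinite(x).sum() == 0:
            continue
        res = mad_filter(x, k=k, transform="none")
        flags[col] = np.isfinite(x) & ~res.kept_mask

    table = measure_table.copy()
    reasons: dict[str, list[str]] = {}
    n_excl = {t: 0 for t in tests}
    for test, measures in tests.items():
        present = [m for m in measures if m in measure_cols]
        if not present:
            continue
        hit = flags[present].any(axis=1)
        for pid in measure_table.index[hit]:
            why = [f"{m}_flagged" for m in present if flags.at[pid, m]]
            if "DWM_Acc" in present and flags.at[pid, "DWM_Acc"]:
                v = measure_table.at[pid, "DWM_Acc"]
                if np.isfinite(v) and abs(v - DWM_GUESS_RATE) <= 0.08:
                    why.append("random_responder_suspected")
            reasons.setdefault(str(pid), []).extend(why)
        n_excl[test] = int(hit.sum())
        table.loc[hit, present] = np.nan

    if laterality_ok is not None and "TVA" in tests:
        lat = pd.Series(laterality_ok)
        bad = lat.index[~lat.astype(bool)]
        present = [m for m in tests["TVA"] if m in measure_cols]
        affected = [pid for pid in bad if pid in table.index]
        for pid in affected:
            reasons.setdefault(str(pid), []).append("laterality")
        if affected and present:
            newly = [
                pid for pid in affected
                if np.isfinite(measure_table.loc[pid, present].to_numpy(dtype=float)).any()
            ]
            n_excl["TVA"] = int(
                len(set(newly) | set(measure_table.index[flags[present].any(axis=1)]))
            )
            table.loc[affected, present] = np.nan

    return ScreeningReport(
        table=table, flags=flags, subject_reasons=reasons, n_excluded_per_test=n_excl
    )
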