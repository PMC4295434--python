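"""Synthetic aging-cohort generator.

Emulates a battery study of older adults (default: 112 participants aged
60-75) in which two latent abilities — visual processing speed and VSTM
capacity — drive ten observed measures.  Age regresses on the speed latent
(default standardized slope -0.3) and, by default, not on capacity.  The
generator produces data at two resolutions:

* subject-level measure tables drawn directly from the latent model
  (:func:`generate_measure_table`), and
* raw trial tables per test (:func:`generate_battery_trials`), including
  exponential-race whole-report trials, planted response-time outliers,
  random responders whose accuracy sits at the guessing rate, laterally
  biased observers, and test-level MCAR missingness.

Everything is driven by one integer seed and is bit-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .tva import TvaParams, WholeReportTrial

__all__ = [
    "SyntheticCohortConfig",
    "Participant",
    "generate_population",
    "generate_measure_table",
    "generate_battery_trials",
    "simulate_whole_report",
    "simulate_whole_report_scores",
    "write_cohort",
    "MEASURE_FACTORS",
    "TEST_MEASURES",
]

# Letter pool conventionally used in whole-report displays (no easily
# confusable glyphs).
LETTER_POOL = "ABDEFGHJKLMNOPRSTVXZ"

# Which latent each measure loads on.  Positive speed = faster processing,
# so completion/response times load negatively; accuracy, span and capacity
# measures load positively on capacity.  t0 is modelled as latent-free noise
# (empirically it correlates with little else in this battery).
MEASURE_FACTORS: dict[str, str] = {
    "TVA_C": "speed",
    "DWM_RT": "speed",
    "Read_Time": "speed",
    "Memo_Time": "speed",
    "FM_Time": "speed",
    "TVA_K": "capacity",
    "Corsi_Span": "capacity",
    "FM_Acc": "capacity",
    "DWM_Acc": "capacity",
    "TVA_t0": "none",
}

# Loading magnitudes are calibrated so that, with the default age slope of
# -0.3 on the speed latent, the implied age-by-indicator correlations
# (slope x loading, about 0.21-0.24) sit in the range such batteries report
# for their timed measures (about 0.2-0.27).
DEFAULT_LOADINGS: dict[str, float] = {
    "TVA_C": 0.85,
    "DWM_RT": -0.80,
    "Read_Time": -0.80,
    "Memo_Time": -0.75,
    "FM_Time": -0.45,
    "TVA_K": 0.85,
    "Corsi_Span": 0.75,
    "FM_Acc": 0.65,
    "DWM_Acc": 0.60,
    "TVA_t0": 0.0,
}

# (mean, sd) on the natural scale for each measure; times in the unit the
# battery reports them (DWM_RT ms; FM/Memo/Read s).
DEFAULT_TARGETS: dict[str, tuple[float, float]] = {
    "DWM_Acc": (0.69, 0.14),
    "DWM_RT": (1468.0, 354.0),
    "FM_Acc": (0.66, 0.14),
    "FM_Time": (11.5, 3.5),
    "Corsi_Span": (5.0, 1.0),
    "Memo_Time": (222.0, 58.0),
    "Read_Time": (249.0, 64.0),
    "TVA_t0": (21.9, 14.5),
    "TVA_C": (43.21, 16.54),
    "TVA_K": (3.58, 0.67),
}

# Measures grouped by test; flagging any one masks the whole test.
TEST_MEASURES: dict[str, tuple[str, ...]] = {
    "DWM": ("DWM_Acc", "DWM_RT"),
    "FM": ("FM_Acc", "FM_Time"),
    "Corsi": ("Corsi_Span",),
    "Memo": ("Memo_Time",),
    "Read": ("Read_Time",),
    "TVA": ("TVA_C", "TVA_K", "TVA_t0"),
}

DWM_TRIALS = 55  # usable trials after practice/interruption exclusion
FM_TRIALS = 27
DWM_GUESS_RATE = 0.25
_RT_TRIAL_CV = 0.25  # lognormal within-subject CV of DWM response times
_FM_TRIAL_CV = 0.30


@dataclass
class SyntheticCohortConfig:
    """All generator knobs; defaults reproduce the reference study conditions."""

    n_participants: int = 112
    age_mean: float = 67.8
    age_sd: float = 4.0
    age_range: tuple[float, float] = (60.0, 75.0)
    beta_age_speed: float = -0.3
    beta_age_capacity: float = 0.0
    latent_resid_corr: float = 0.0
    measure_loadings: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_LOADINGS))
    measure_targets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TARGETS)
    )
    trial_outlier_rate: float = 0.03
    random_responder_rate: float = 0.03
    lateral_bias_rate: float = 0.05
    missing_rate: float = 0.05
    exposure_set_ms: tuple[float, ...] = (20.0, 50.0, 80.0, 140.0, 200.0)
    trials_per_exposure: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 3:
            raise ValueError(f"n_participants must be >= 3, got {self.n_participants}")
        for name in (
            "trial_outlier_rate",
            "random_responder_rate",
            "lateral_bias_rate",
            "missing_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -1.0 <= self.latent_resid_corr <= 1.0:
            raise ValueError(f"latent_resid_corr must be in [-1, 1], got {self.latent_resid_corr}")
        if self.age_sd <= 0:
            raise ValueError(f"age_sd must be positive, got {self.age_sd}")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError(f"age_range must be increasing, got {self.age_range}")
        if len(self.exposure_set_ms) == 0:
            raise ValueError("exposure_set_ms must not be empty")
        if any(e <= 0 for e in self.exposure_set_ms):
            raise ValueError(f"exposure_set_ms must be positive, got {self.exposure_set_ms}")
        if self.trials_per_exposure < 1:
            raise ValueError(f"trials_per_exposure must be >= 1, got {self.trials_per_exposure}")
        unknown = set(self.measure_loadings) - set(MEASURE_FACTORS)
        if unknown:
            raise ValueError(f"measure_loadings has unknown measures: {sorted(unknown)}")
        for m, (mu, sd) in self.measure_targets.items():
            if m not in MEASURE_FACTORS:
                raise ValueError(f"measure_targets has unknown measure: {m}")
            if sd <= 0:
                raise ValueError(f"measure_targets[{m}] sd must be positive, got {sd}")

    def latent_sd(self, factor: str) -> float:
        """Theoretical SD of a latent: beta·z(age) plus unit-variance residual."""
        beta = {"speed": self.beta_age_speed, "capacity": self.beta_age_capacity}.get(factor, 0.0)
        return float(np.sqrt(1.0 + beta**2))


@dataclass
class Participant:
    """Ground-truth state of one simulated subject."""

    id: str
    age: float
    speed_latent: float
    capacity_latent: float
    true_C: float
    true_K: float
    true_t0: float
    true_laterality: float = 0.5
    is_random_responder: bool = False

    def __post_init__(self) -> None:
        if not self.true_C > 0:
            raise ValueError("true_C must be positive")
        if not 0 < self.true_K <= 6:
            raise ValueError("true_K must be in (0, 6]")
        if self.true_t0 < 0:
            raise ValueError("true_t0 must be non-negative")

    @property
    def tva_params(self) -> TvaParams:
        return TvaParams(self.true_C, self.true_K, self.true_t0)


def _draw_measure(
    config: SyntheticCohortConfig,
    measure: str,
    z_speed: np.ndarray,
    z_capacity: np.ndarray,
    rng: np.random.Generator,
    sd_override: float | None = None,
) -> np.ndarray:
    """mean + sd·(λ·z_factor + sqrt(1-λ²)·noise) on the natural scale."""
    lam = config.measure_loadings.get(measure, DEFAULT_LOADINGS[measure])
    mu, sd = config.measure_targets.get(measure, DEFAULT_TARGETS[measure])
    if sd_override is not None:
        sd = sd_override
    factor = MEASURE_FACTORS[measure]
    z = {"speed": z_speed, "capacity": z_capacity}.get(factor, np.zeros_like(z_speed))
    noise = rng.standard_normal(z.shape)
    return mu + sd * (lam * z + np.sqrt(max(0.0, 1.0 - lam**2)) * noise)


def generate_population(
    config: SyntheticCohortConfig, rng: np.random.Generator | None = None
) -> list[Participant]:
    """Draw participants: truncated-normal ages, latents, true TVA parameters.

    Latents follow ``beta·z(age) + residual`` with unit-variance residuals
    (correlated across factors by ``latent_resid_corr``); true TVA
    parameters are affine maps of the standardized latents onto the
    configured natural-scale targets, clipped to their admissible ranges.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    tn = stats.truncnorm(a, b, loc=config.age_mean, scale=config.age_sd)
    ages = tn.rvs(size=n, random_state=rng)
    # standardize by the truncated distribution's true moments so the
    # configured slope is the standardized slope on the realized ages
    mu_t, var_t = tn.stats("mv")
    z_age = (ages - float(mu_t)) / float(np.sqrt(var_t))

    rho = config.latent_resid_corr
    resid = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    speed = config.beta_age_speed * z_age + resid[:, 0]
    capacity = config.beta_age_capacity * z_age + resid[:, 1]
    z_speed = speed / config.latent_sd("speed")
    z_capacity = capacity / config.latent_sd("capacity")

    true_c = np.clip(_draw_measure(config, "TVA_C", z_speed, z_capacity, rng), 2.0, None)
    true_k = np.clip(_draw_measure(config, "TVA_K", z_speed, z_capacity, rng), 0.5, 6.0)
    true_t0 = np.clip(_draw_measure(config, "TVA_t0", z_speed, z_capacity, rng), 0.0, None)

    biased = rng.random(n) < config.lateral_bias_rate
    w = np.clip(rng.normal(0.5, 0.02, size=n), 0.05, 0.95)
    bias_mag = rng.uniform(0.80, 0.95, size=n)
    bias_side = rng.random(n) < 0.5
    w = np.where(biased, np.where(bias_side, bias_mag, 1.0 - bias_mag), w)

    random_resp = rng.random(n) < config.random_responder_rate

    width = len(str(n))
    return [
        Participant(
            id=f"P{i + 1:0{width}d}",
            age=float(ages[i]),
            speed_latent=float(speed[i]),
            capacity_latent=float(capacity[i]),
            true_C=float(true_c[i]),
            true_K=float(true_k[i]),
            true_t0=float(true_t0[i]),
            true_laterality=float(w[i]),
            is_random_responder=bool(random_resp[i]),
        )
        for i in range(n)
    ]


def _mcar_test_mask(
    config: SyntheticCohortConfig, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-test boolean mask (True = test missing), MCAR at test level."""
    return {t: rng.random(n) < config.missing_rate for t in TEST_MEASURES}


def generate_measure_table(
    participants: Sequence[Participant],
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Subject-level measure table drawn directly from the latent model.

    This is the idealized (no trial noise, no outliers beyond random
    responders) view used for factor-model power analyses; TVA columns carry
    the true parameters.  MCAR missingness masks whole tests jointly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = len(participants)
    z_speed = np.array([p.speed_latent for p in participants]) / config.latent_sd("speed")
    z_cap = np.array([p.capacity_latent for p in participants]) / config.latent_sd("capacity")

    df = pd.DataFrame({"participant_id": [p.id for p in participants]})
    df["Age"] = [p.age for p in participants]
    for m in ("DWM_Acc", "DWM_RT", "FM_Acc", "FM_Time", "Corsi_Span", "Memo_Time", "Read_Time"):
        df[m] = _draw_measure(config, m, z_speed, z_cap, rng)
    df["Corsi_Span"] = np.clip(np.round(df["Corsi_Span"]), 0, 9)
    df["DWM_Acc"] = np.clip(df["DWM_Acc"], 0.02, 0.98)
    df["FM_Acc"] = np.clip(df["FM_Acc"], 0.02, 0.98)
    df["TVA_C"] = [p.true_C for p in participants]
    df["TVA_K"] = [p.true_K for p in participants]
    df["TVA_t0"] = [p.true_t0 for p in participants]

    for i, p in enumerate(participants):
        if p.is_random_responder:
            df.loc[i, "DWM_Acc"] = float(np.clip(rng.normal(DWM_GUESS_RATE, 0.02), 0.02, 0.98))

    mask = _mcar_test_mask(config, n, rng)
    for test, measures in TEST_MEASURES.items():
        for m in measures:
            df.loc[mask[test], m] = np.nan
    return df.set_index("participant_id")


# ---------------------------------------------------------------------------
# Whole-report trial simulation


def simulate_whole_report_scores(
    params: TvaParams,
    exposure_ms: float,
    n_trials: int,
    rng: np.random.Generator,
    w: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized race simulation at one exposure.

    Returns (orders, scores): ``orders`` is an (n_trials, 6) array of item
    positions sorted by finishing time, ``scores`` the number of items
    encoded per trial.  Items 0-2 sit in the left hemifield (race rate
    (C/3)·w each), items 3-5 right ((C/3)·(1-w)).
    """
    n = params.n_items
    half = n // 2
    rate_left = (params.C / half) * w
    rate_right = (params.C / half) * (1.0 - w)
    rates = np.array([rate_left] * half + [rate_right] * (n - half))
    t_e = max(0.0, exposure_ms - params.t0) / 1000.0
    # Exponential finishing times; zero rate = never finishes.
    with np.errstate(divide="ignore"):
        times = rng.exponential(1.0, size=(n_trials, n)) / np.where(rates > 0, rates, np.inf)
    k_lo = int(np.floor(params.K))
    frac = params.K - k_lo
    kstar = k_lo + (rng.random(n_trials) < frac).astype(int)
    kstar = np.minimum(kstar, n)
    finished = (times < t_e).sum(axis=1)
    scores = np.minimum(finished, kstar)
    orders = np.argsort(times, axis=1, kind="stable")
    return orders, scores


def simulate_whole_report(
    participant: Participant | TvaParams,
    exposure_set_ms: Sequence[float],
    trials_per_exposure: int,
    seed: int | np.random.Generator,
    w: float | None = None,
) -> list[WholeReportTrial]:
    """Simulate whole-report trials for one observer across an exposure set.

    Per trial, six distinct letters race with per-side rates (C/3)·w (left)
    and (C/3)·(1-w) (right); an item is reported iff it finishes before the
    effective exposure and ranks among the first k* finishers, where k* is
    the adjacent-integer mixture realizing fractional K.
    """
    if len(exposure_set_ms) == 0:
        raise ValueError("exposure_set_ms must not be empty")
    if isinstance(participant, Participant):
        params = participant.tva_params
        pid = participant.id
        if w is None:
            w = participant.true_laterality
    else:
        params = participant
        pid = "sim"
        if w is None:
            w = 0.5
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    letters = np.frombuffer(LETTER_POOL.encode(), dtype="S1").astype("U1")
    trials: list[WholeReportTrial] = []
    for exp in exposure_set_ms:
        orders, scores = simulate_whole_report_scores(params, exp, trials_per_exposure, rng, w=w)
        # distinct letters per trial via random permutation of the pool
        perm = np.argsort(rng.random((trials_per_exposure, len(letters))), axis=1)[:, : params.n_items]
        for t in range(trials_per_exposure):
            disp = letters[perm[t]]
            reported_pos = orders[t, : scores[t]]
            trials.append(
                WholeReportTrial(
                    participant_id=pid,
                    exposure_ms=float(exp),
                    displayed="".join(disp),
                    reported="".join(disp[np.sort(reported_pos)]),
                )
            )
    return trials


# ---------------------------------------------------------------------------
# Full battery


def _deflated_sd(target_sd: float, sampling_sd: float) -> float:
    """Subject-level SD such that subject + trial-sampling variance hits the target."""
    return float(np.sqrt(max(target_sd**2 - sampling_sd**2, (0.3 * target_sd) ** 2)))


def _lognormal_trials(
    mean: float, cv: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=n)


def _plant_rt_outliers(
    rts: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Replace a Bernoulli(rate) subset of RTs by values >= +10 reference MADs.

    The reference MAD is the scaled MAD of the pre-contamination trials, so
    plants are extreme relative to the subject's own clean distribution.
    """
    med = np.median(rts)
    mad = 1.4826 * np.median(np.abs(rts - med))
    if mad == 0:
        mad = 0.1 * max(med, 1.0)
    hit = rng.random(rts.size) < rate
    shift = (10.0 + rng.exponential(3.0, size=rts.size)) * mad
    out = np.where(hit, rts + shift, rts)
    return out, hit


def generate_battery_trials(
    participants: Sequence[Participant],
    config: SyntheticCohortConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, pd.DataFrame]:
    """Raw trial tables for the whole battery.

    Returns a dict of DataFrames:

    ``dwm``           one row per delayed-working-memory trial (rt_ms, correct)
    ``fm``            one row per four-mountains trial (time_s, correct)
    ``whole_report``  one row per whole-report trial (exposure_ms, displayed, reported)
    ``subject``       per-subject draws (Corsi_Span, Memo_Time, Read_Time,
                      plus the control measures Read_Acc and Memo_Misses)
    ``truth``         ground-truth per participant (latents, true TVA
                      parameters, planted-defect flags, masked tests,
                      planted outlier counts)

    Tests masked MCAR are absent from the trial tables and NaN in
    ``subject``, always as whole tests.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    n = len(participants)
    z_speed = np.array([p.speed_latent for p in participants]) / config.latent_sd("speed")
    z_cap = np.array([p.capacity_latent for p in participants]) / config.latent_sd("capacity")
    mask = _mcar_test_mask(config, n, rng)

    mu_da, sd_da = config.measure_targets.get("DWM_Acc", DEFAULT_TARGETS["DWM_Acc"])
    mu_dr, sd_dr = config.measure_targets.get("DWM_RT", DEFAULT_TARGETS["DWM_RT"])
    mu_fa, sd_fa = config.measure_targets.get("FM_Acc", DEFAULT_TARGETS["FM_Acc"])
    mu_ft, sd_ft = config.measure_targets.get("FM_Time", DEFAULT_TARGETS["FM_Time"])

    acc_dwm = np.clip(
        _draw_measure(config, "DWM_Acc", z_speed, z_cap, rng,
                      sd_override=_deflated_sd(sd_da, np.sqrt(mu_da * (1 - mu_da) / DWM_TRIALS))),
        0.02, 0.98,
    )
    rt_dwm = np.clip(
        _draw_measure(config, "DWM_RT", z_speed, z_cap, rng,
                      sd_override=_deflated_sd(sd_dr, mu_dr * _RT_TRIAL_CV / np.sqrt(DWM_TRIALS))),
        200.0, None,
    )
    acc_fm = np.clip(
        _draw_measure(config, "FM_Acc", z_speed, z_cap, rng,
                      sd_override=_deflated_sd(sd_fa, np.sqrt(mu_fa * (1 - mu_fa) / FM_TRIALS))),
        0.02, 0.98,
    )
    time_fm = np.clip(
        _draw_measure(config, "FM_Time", z_speed, z_cap, rng,
                      sd_override=_deflated_sd(sd_ft, mu_ft * _FM_TRIAL_CV / np.sqrt(FM_TRIALS))),
        1.0, None,
    )
    corsi = np.clip(np.round(_draw_measure(config, "Corsi_Span", z_speed, z_cap, rng)), 0, 9)
    memo = np.clip(_draw_measure(config, "Memo_Time", z_speed, z_cap, rng), 30.0, None)
    read = np.clip(_draw_measure(config, "Read_Time", z_speed, z_cap, rng), 30.0, None)
    # control measures the analysis later drops: strongly skewed reading
    # accuracy and memo misses tied to completion time
    read_acc = rng.binomial(4, 0.9, size=n) / 4.0
    memo_miss = rng.poisson(np.maximum(memo, 1.0) * 0.1)

    dwm_rows, fm_rows, wr_trials, subj_rows, truth_rows = [], [], [], [], []
    for i, p in enumerate(participants):
        acc_i = DWM_GUESS_RATE if p.is_random_responder else acc_dwm[i]
        n_out_dwm = n_out_fm = 0
        if not mask["DWM"][i]:
            correct = rng.random(DWM_TRIALS) < acc_i
            rts = _lognormal_trials(rt_dwm[i], _RT_TRIAL_CV, DWM_TRIALS, rng)
            rts, hit = _plant_rt_outliers(rts, config.trial_outlier_rate, rng)
            n_out_dwm = int(hit.sum())
            for t in range(DWM_TRIALS):
                dwm_rows.append((p.id, t, float(rts[t]), bool(correct[t]), bool(hit[t])))
        if not mask["FM"][i]:
            correct = rng.random(FM_TRIALS) < acc_fm[i]
            times = _lognormal_trials(time_fm[i], _FM_TRIAL_CV, FM_TRIALS, rng)
            times, hit = _plant_rt_outliers(times, config.trial_outlier_rate, rng)
            n_out_fm = int(hit.sum())
            for t in range(FM_TRIALS):
                fm_rows.append((p.id, t, float(times[t]), bool(correct[t]), bool(hit[t])))
        if not mask["TVA"][i]:
            wr_trials.extend(
                simulate_whole_report(
                    p, config.exposure_set_ms, config.trials_per_exposure, rng
                )
            )
        subj_rows.append(
            (
                p.id,
                np.nan if mask["Corsi"][i] else float(corsi[i]),
                np.nan if mask["Memo"][i] else float(memo[i]),
                np.nan if mask["Read"][i] else float(read[i]),
                np.nan if mask["Read"][i] else float(read_acc[i]),
                np.nan if mask["Memo"][i] else int(memo_miss[i]),
            )
        )
        truth_rows.append(
            {
                "participant_id": p.id,
                "age": p.age,
                "speed_latent": p.speed_latent,
                "capacity_latent": p.capacity_latent,
                "true_C": p.true_C,
                "true_K": p.true_K,
                "true_t0": p.true_t0,
                "true_laterality": p.true_laterality,
                "is_random_responder": p.is_random_responder,
                "n_planted_dwm_outliers": n_out_dwm,
                "n_planted_fm_outliers": n_out_fm,
                "masked_tests": ";".join(t for t in TEST_MEASURES if mask[t][i]),
            }
        )

    dwm = pd.DataFrame(dwm_rows, columns=["participant_id", "trial", "rt_ms", "correct", "planted_outlier"])
    fm = pd.DataFrame(fm_rows, columns=["participant_id", "trial", "time_s", "correct", "planted_outlier"])
    wr = pd.DataFrame(
        [(t.participant_id, t.exposure_ms, t.displayed, t.reported) for t in wr_trials],
        columns=["participant_id", "exposure_ms", "displayed", "reported"],
    )
    subject = pd.DataFrame(
        subj_rows,
        columns=["participant_id", "Corsi_Span", "Memo_Time", "Read_Time", "Read_Acc", "Memo_Misses"],
    )
    truth = pd.DataFrame(truth_rows)
    return {"dwm": dwm, "fm": fm, "whole_report": wr, "subject": subject, "truth": truth}


def write_cohort(
    tables: Mapping[str, pd.DataFrame], config: SyntheticCohortConfig, outdir: str | Path
) -> None:
    """Write the trial tables as CSV and the generating config as YAML."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    cfg = asdict(config)
    cfg["age_range"] = list(config.age_range)
    cfg["exposure_set_ms"] = list(config.exposure_set_ms)
    cfg["measure_targets"] = {k: list(v) for k, v in config.measure_targets.items()}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
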