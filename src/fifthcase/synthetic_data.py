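"""Synthetic 4-case OR cohorts with the statistical structure the analysis assumes.

The hospital dataset is not public, so the generator emulates its printed
statistical shape: per-day pace heterogeneity, cumulative within-day noise
(which makes per-case spread grow with case number), a 30-minute later
Wednesday start, and a heavy-tailed "slow day" mechanism that produces
unsuccessful days whose 4th cases straggle past 20:00.

A day is built as

    t_k = start + sum_{j<=k} d_j,   d_j = D + b * I_slow + e_j   (minutes)

with the start drawn around the weekday's nominal time (Normal jitter — the
per-day intercept of the analysis absorbs it, so it widens every case's
clock-time spread without touching fit quality); per-day base duration
D ~ Normal(mean_case, between_day_sd); a slow-day
bump b ~ LogNormal on a Bernoulli(slow_day_prob) subset of days, added to
every case of that day; and residuals e_j ~ Normal(0, sigma_j) with
sigma_j = within_day_noise_sd * (1 + noise_growth_per_case * (j - 1)) —
later cases are intrinsically noisier, which reproduces both the spread
pattern and the observed ordering of back-prediction errors (4th >= 3rd).
All randomness comes from one named stream per cohort, seeded explicitly.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass

import numpy as np

from fifthcase.classification import DEFAULT_CUTOFF
from fifthcase.predictor import fit_lines_matrix
from fifthcase.schedule_io import ClockTime, DayRecord, day_from_times


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults are calibrated once so that a 761-day cohort reproduces the
    study conditions: a ~39.55% day-success rate, all-cases per-case SDs
    rising from ~17-18 min (1st case) to ~40-44 min (4th), a mean per-day fit
    MAE near 4:45 min, and a right tail of 4th-case completions past 20:00.
    """

    n_days: int = 761
    target_ssr: float = 0.3955
    start_time_weekday: ClockTime = ClockTime.from_hms(7, 30)
    start_time_wednesday: ClockTime = ClockTime.from_hms(8, 0)
    start_jitter_sd_minutes: float = 5.0  # day-to-day first-case start variation
    mean_case_minutes: float = 119.0
    between_day_sd_minutes: float = 1.4
    within_day_noise_sd_minutes: float = 9.3
    noise_growth_per_case: float = 0.30
    slow_day_prob: float = 0.60
    slow_day_log_mu: float = 2.24  # log-minutes of the per-case slow-day bump
    slow_day_log_sd: float = 0.55
    min_case_minutes: float = 30.0
    start_date: _dt.date = _dt.date(2012, 1, 2)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if not 0 < self.target_ssr <= 1:
            raise ValueError("target_ssr must lie in (0, 1]")
        for name in ("mean_case_minutes", "slow_day_log_sd", "min_case_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("between_day_sd_minutes", "within_day_noise_sd_minutes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.slow_day_prob < 1:
            raise ValueError("slow_day_prob must lie in [0, 1)")
        if self.noise_growth_per_case < 0:
            raise ValueError("noise_growth_per_case must be >= 0")
        if self.start_jitter_sd_minutes < 0:
            raise ValueError("start_jitter_sd_minutes must be >= 0")


def _business_days(start: _dt.date, n: int) -> list[_dt.date]:
    out: list[_dt.date] = []
    d = start
    while len(out) < n:
        if d.weekday() < 5:
            out.append(d)
        d += _dt.timedelta(days=1)
    return out


def simulate_times(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[list[_dt.date], np.ndarray]:
    """Vectorised core: dates plus an (n_days, 4) matrix of whole seconds."""
    n = config.n_days
    dates = _business_days(config.start_date, n)
    wednesday = np.array([d.weekday() == 2 for d in dates])
    start = np.where(
        wednesday,
        config.start_time_wednesday.seconds,
        config.start_time_weekday.seconds,
    ).astype(float)
    start = start + 60.0 * config.start_jitter_sd_minutes * rng.standard_normal(n)

    base = rng.normal(config.mean_case_minutes, config.between_day_sd_minutes, size=n)
    slow = rng.random(n) < config.slow_day_prob
    bump = np.where(
        slow,
        np.exp(rng.normal(config.slow_day_log_mu, config.slow_day_log_sd, size=n)),
        0.0,
    )
    sigma = config.within_day_noise_sd_minutes * (
        1.0 + config.noise_growth_per_case * np.arange(4)
    )
    noise = rng.normal(0.0, 1.0, size=(n, 4)) * sigma
    durations = np.clip(
        base[:, None] + bump[:, None] + noise, config.min_case_minutes, 600.0
    )
    times = start[:, None] + np.cumsum(durations, axis=1) * 60.0
    times = np.rint(times).astype(np.int64)
    # whole-second rounding can collapse a (already clipped) tiny gap; keep order strict
    for k in range(1, 4):
        times[:, k] = np.maximum(times[:, k], times[:, k - 1] + 1)
    return dates, times


def generate_cohort(
    config: GeneratorConfig, seed: int | None = None
) -> list[DayRecord]:
    """Generate ``config.n_days`` synthetic :class:`DayRecord` days.

    ``seed`` overrides ``config.seed``; the same seed always yields the same
    cohort.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dates, times = simulate_times(config, rng)
    return [
        day_from_times(day_id=f"D{i:05d}", date=dates[i], times=list(times[i]))
        for i in range(config.n_days)
    ]


def _summaries_from_matrix(times: np.ndarray, cutoff_seconds: int) -> dict:
    """Vectorised summary statistics from an (n, 4) out-of-room matrix."""
    times = np.asarray(times, dtype=float)
    succ_mask = times[:, 3] <= cutoff_seconds
    out = {
        "ssr": float(succ_mask.mean()),
        "per_case_sd_minutes": tuple(times.std(axis=0, ddof=0) / 60.0),
        "mean_spare_minutes": (
            float((cutoff_seconds - times[succ_mask, 3]).mean() / 60.0)
            if succ_mask.any()
            else None
        ),
        "frac_fourth_past_20h": float((times[:, 3] > 20 * 3600).mean()),
    }
    succ = times[succ_mask]
    if len(succ) >= 2:
        w0_4, w1_4, mae_4 = fit_lines_matrix(succ, fit_cases=4)
        w0_2, w1_2, _ = fit_lines_matrix(succ, fit_cases=2)
        w0_3, w1_3, _ = fit_lines_matrix(succ, fit_cases=3)
        out.update(
            {
                "per_case_sd_minutes_successful": tuple(
                    succ.std(axis=0, ddof=0) / 60.0
                ),
                "fit_mae_minutes": float(mae_4.mean() / 60.0),
                "backpredict3_mae_minutes": float(
                    np.abs(succ[:, 2] - (w0_2 + 3 * w1_2)).mean() / 60.0
                ),
                "backpredict4_mae_minutes": float(
                    np.abs(succ[:, 3] - (w0_3 + 4 * w1_3)).mean() / 60.0
                ),
                "fifth_prediction_sd_minutes": float(
                    (w0_4 + 5 * w1_4).std(ddof=0) / 60.0
                ),
            }
        )
    return out


def cohort_summaries(
    days: list[DayRecord], cutoff: ClockTime = DEFAULT_CUTOFF
) -> dict:
    """Summary statistics used for calibration and the acceptance bands."""
    from fifthcase.schedule_io import times_matrix

    return _summaries_from_matrix(times_matrix(days), cutoff.seconds)


@dataclass(frozen=True)
class CalibrationTargets:
    """Cohort summaries the generator is tuned to reproduce."""

    ssr: float = 0.3955
    first_case_sd_minutes: float = 17.733  # 00:17:44
    fourth_case_sd_minutes: float = 42.083  # 00:42:05
    fit_mae_minutes: float = 4.75  # 4:45


def _pack(config: GeneratorConfig) -> np.ndarray:
    p = min(max(config.slow_day_prob, 1e-4), 1 - 1e-4)
    return np.array(
        [
            np.log(max(config.between_day_sd_minutes, 1e-3)),
            np.log(max(config.within_day_noise_sd_minutes, 1e-3)),
            np.log(p / (1 - p)),
            config.slow_day_log_mu,
        ]
    )


def _unpack(theta: np.ndarray, config: GeneratorConfig) -> GeneratorConfig:
    return dataclasses.replace(
        config,
        between_day_sd_minutes=float(np.exp(theta[0])),
        within_day_noise_sd_minutes=float(np.exp(theta[1])),
        slow_day_prob=float(1.0 / (1.0 + np.exp(-theta[2]))),
        slow_day_log_mu=float(theta[3]),
    )


def calibrate(
    config: GeneratorConfig,
    targets: CalibrationTargets = CalibrationTargets(),
    n_days: int = 4000,
    seed: int = 0,
    max_iter: int = 120,
) -> tuple[GeneratorConfig, dict]:
    """Tune the noise and slow-day parameters to match target summaries.

    Method-of-moments by simulation: the objective is the squared relative
    mismatch of SSR, 1st/4th-case SDs and fit MAE over (between-day SD,
    within-day SD, slow-day probability, slow-day log-location), evaluated
    with common random numbers (one fixed simulation seed), so the search is
    deterministic.  A coarse quasi-random scan over plausible ranges seeds a
    Nelder-Mead polish — the landscape has flat basins that trap a single
    local descent started far from the optimum.  Returns the calibrated
    config and a diagnostics dict with the achieved summaries; if the polish
    stops on its iteration budget the best point found is returned with
    ``converged=False``.
    """
    from scipy import optimize, stats

    base = dataclasses.replace(config, n_days=n_days)

    cutoff = DEFAULT_CUTOFF.seconds

    def measure(cfg: GeneratorConfig) -> dict:
        _, times = simulate_times(cfg, np.random.default_rng(seed))
        return _summaries_from_matrix(times, cutoff)

    def objective(theta: np.ndarray) -> float:
        cfg = _unpack(theta, base)
        s = measure(cfg)
        terms = [
            3.0 * ((s["ssr"] - targets.ssr) / max(targets.ssr, 1e-9)) ** 2,
            (
                (s["per_case_sd_minutes"][0] - targets.first_case_sd_minutes)
                / targets.first_case_sd_minutes
            )
            ** 2,
            (
                (s["per_case_sd_minutes"][3] - targets.fourth_case_sd_minutes)
                / targets.fourth_case_sd_minutes
            )
            ** 2,
        ]
        if "fit_mae_minutes" in s:
            terms.append(
                ((s["fit_mae_minutes"] - targets.fit_mae_minutes) / targets.fit_mae_minutes)
                ** 2
            )
        else:  # no successful days at all — heavily penalised
            terms.append(25.0)
        return float(sum(terms))

    # phase 1: quasi-random scan (Sobol) over plausible parameter ranges
    lo = np.array([np.log(0.3), np.log(3.0), np.log(0.05 / 0.95), 1.5])
    hi = np.array([np.log(8.0), np.log(15.0), np.log(0.85 / 0.15), 3.0])
    sampler = stats.qmc.Sobol(d=4, scramble=True, seed=seed + 1)
    candidates = [_pack(base)] + list(lo + sampler.random(64) * (hi - lo))
    x0 = min(candidates, key=objective)

    # phase 2: local polish
    res = optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"maxiter": max_iter, "xatol": 1e-3, "fatol": 1e-5},
    )
    best = _unpack(res.x, config)
    achieved = measure(dataclasses.replace(best, n_days=n_days))
    diagnostics = {
        "converged": bool(res.success),
        "objective": float(res.fun),
        "n_evaluations": int(res.nfev),
        "achieved": achieved,
        "targets": dataclasses.asdict(targets),
    }
    return best, diagnostics
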