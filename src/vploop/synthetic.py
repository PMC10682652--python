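"""Synthetic physiologic waveforms and study-structured cohorts.

Every downstream module is exercised on data from this generator, so it
produces (a) beat-level aortic-pressure / LVOT-velocity signal pairs with
analytically known landmark values, and (b) patient-level cohort tables
with the two-group covariate structure, ~80/20 outcome imbalance and
2-year survival split of a TAVI functional-improvement study.

Waveform model (R-peak at t = 0, period T = 60/heart_rate):

* velocity envelope: zero until ejection onset, half-cosine rise to Vpeak
  over the acceleration time, half-cosine fall back to zero at end-ejection;
* pressure: exponential diastolic decay toward the configured diastolic
  value, a raised-cosine systolic upstroke from the beat's minimum pressure
  to the systolic value, then exponential decay with a Gaussian dicrotic
  notch.  The signal is exactly periodic, so the pre-upstroke decay
  continues the previous beat's decay.

``severity_decoupling`` delays the pressure upstroke relative to the
velocity peak: the larger the delay, the earlier on the upstroke the
pressure is caught at the moment of peak velocity, hence the smaller
[P(Vmax) - P(Vo)]/Vmax — the morphological signature of a high valvular
afterload burden.

Cohort group distributions are truncated-at-zero normals whose parent
parameters are solved numerically so the *truncated* distribution has
exactly the configured mean and SD (moment-matched truncation); see
docs/methods.md for why this matters for the slope-index separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .io import Channel, SampledTrace

__all__ = [
    "BeatParams",
    "BeatPair",
    "CohortParams",
    "GroupSpec",
    "gen_beat_pair",
    "gen_ecg",
    "gen_cohort",
    "random_beat_params",
    "matched_truncnorm_params",
    "draw_truncated_normal",
]

DEFAULT_FS_HZ = 250.0   # fluid-filled manometer bandwidth scale
DEFAULT_N_BEATS = 25    # > the customary 20 so a partial beat can be dropped
NOTCH_WIDTH_S = 0.010


@dataclass(frozen=True)
class BeatParams:
    """Morphological parameters of one synthetic cardiac cycle.

    Defaults describe a well-coupled beat (prompt pressure upstroke, peak
    velocity landing late on the upstroke); raising ``severity_decoupling``
    moves the pair toward the decoupled morphology of a high stenotic
    burden.
    """

    heart_rate: float = 70.0            # bpm
    Pdia: float = 70.0                  # mmHg, diastolic asymptote
    Psys: float = 130.0                 # mmHg, systolic peak
    pressure_upstroke_delay: float = 0.06  # s from R-peak
    pressure_rise_time: float = 0.12    # s
    dicrotic_notch_depth: float = 0.12  # fraction of pulse pressure
    diastolic_decay_tau: float = 0.40   # s
    Vpeak: float = 85.0                 # cm/s
    ejection_onset_delay: float = 0.05  # s from R-peak
    ejection_duration: float = 0.32     # s
    acceleration_time: float = 0.12     # s (prolonged, as in significant AS)
    severity_decoupling: float = 0.0    # s extra pressure lag

    def __post_init__(self):
        T = self.period
        if self.heart_rate <= 0:
            raise ValueError("heart_rate must be positive")
        if not 0 < self.Pdia < self.Psys:
            raise ValueError("need 0 < Pdia < Psys")
        for name in ("pressure_rise_time", "diastolic_decay_tau", "Vpeak",
                     "ejection_duration", "acceleration_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("pressure_upstroke_delay", "ejection_onset_delay",
                     "severity_decoupling"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.dicrotic_notch_depth < 1:
            raise ValueError("dicrotic_notch_depth must be in [0, 1)")
        if self.acceleration_time >= self.ejection_duration:
            raise ValueError("acceleration_time must be < ejection_duration")
        if self.t_upstroke + self.pressure_rise_time >= T:
            raise ValueError("pressure upstroke must complete within the beat")
        if self.ejection_onset_delay + self.ejection_duration >= T:
            raise ValueError("ejection must complete within the beat")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def t_upstroke(self) -> float:
        return self.pressure_upstroke_delay + self.severity_decoupling

    @property
    def t_systole(self) -> float:
        return self.t_upstroke + self.pressure_rise_time

    @property
    def t_vmax(self) -> float:
        return self.ejection_onset_delay + self.acceleration_time

    @property
    def p_min(self) -> float:
        """Minimum (diastolic) pressure reached just before the upstroke."""
        pp = self.Psys - self.Pdia
        return self.Pdia + pp * np.exp(
            -(self.period - self.pressure_rise_time) / self.diastolic_decay_tau
        )

    def pressure(self, t_rel) -> np.ndarray:
        """Noise-free pressure at relative times within [0, period)."""
        t = np.asarray(t_rel, dtype=float)
        T, tau = self.period, self.diastolic_decay_tau
        t_up, t_sys = self.t_upstroke, self.t_systole
        pp = self.Psys - self.Pdia
        p = np.empty_like(t)
        pre = t < t_up
        p[pre] = self.Pdia + pp * np.exp(-(t[pre] + T - t_sys) / tau)
        rise = (t >= t_up) & (t <= t_sys)
        phase = (t[rise] - t_up) / self.pressure_rise_time
        p[rise] = self.p_min + (self.Psys - self.p_min) * 0.5 * (
            1.0 - np.cos(np.pi * phase)
        )
        post = t > t_sys
        p[post] = self.Pdia + pp * np.exp(-(t[post] - t_sys) / tau)
        t_notch = self.ejection_onset_delay + self.ejection_duration
        if self.dicrotic_notch_depth > 0 and t_notch > t_sys:
            dip = self.dicrotic_notch_depth * pp * np.exp(
                -0.5 * ((t - t_notch) / NOTCH_WIDTH_S) ** 2
            )
            p[post] -= dip[post]
        return p if p.shape else float(p)

    def velocity(self, t_rel) -> np.ndarray:
        """Noise-free LVOT velocity envelope at relative times."""
        t = np.asarray(t_rel, dtype=float)
        t_on = self.ejection_onset_delay
        t_pk = t_on + self.acceleration_time
        t_end = t_on + self.ejection_duration
        v = np.zeros_like(t)
        up = (t >= t_on) & (t <= t_pk)
        v[up] = self.Vpeak * 0.5 * (
            1.0 - np.cos(np.pi * (t[up] - t_on) / self.acceleration_time)
        )
        decel = self.ejection_duration - self.acceleration_time
        down = (t > t_pk) & (t <= t_end)
        v[down] = self.Vpeak * 0.5 * (
            1.0 + np.cos(np.pi * (t[down] - t_pk) / decel)
        )
        return v if v.shape else float(v)

    def true_landmarks(self) -> dict:
        """Analytic landmark values of the noise-free beat."""
        grid = np.arange(0.0, self.period, 1e-4)
        p = self.pressure(grid)
        p_vmax = float(self.pressure(self.t_vmax))
        p_vo = float(p.min())
        return {
            "Vmax": self.Vpeak,
            "t_Vmax": self.t_vmax,
            "P_Vmax": p_vmax,
            "P_Vo": p_vo,
            "Pmax": float(p.max()),
            "slope_index": (p_vmax - p_vo) / self.Vpeak,
        }


@dataclass(frozen=True)
class BeatPair:
    """A generated pressure/velocity trace pair with its ground truth."""

    pressure: SampledTrace
    velocity: SampledTrace
    truth: dict
    params: BeatParams


def gen_beat_pair(
    params: BeatParams,
    noise_sd: float = 0.0,
    seed=None,
    n_beats: int = DEFAULT_N_BEATS,
    fs: float = DEFAULT_FS_HZ,
) -> BeatPair:
    """Sample a periodic pressure/velocity pair with R-peaks and truth.

    Both channels are sampled at ``fs`` Hz over ``n_beats`` cardiac cycles;
    additive Gaussian noise of SD ``noise_sd`` (channel units) is applied to
    both, with the velocity envelope clipped at zero.
    """
    if n_beats < 2:
        raise ValueError("need at least 2 beats")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    T = params.period
    times = np.arange(0.0, n_beats * T, 1.0 / fs)
    t_rel = np.mod(times, T)
    p = params.pressure(t_rel)
    v = params.velocity(t_rel)
    if noise_sd > 0:
        p = p + rng.normal(0.0, noise_sd, size=p.shape)
        v = np.clip(v + rng.normal(0.0, noise_sd, size=v.shape), 0.0, None)
    r_peaks = np.arange(n_beats) * T
    return BeatPair(
        pressure=SampledTrace(Channel.PRESSURE, times, p, r_peaks),
        velocity=SampledTrace(Channel.VELOCITY, times, v, r_peaks),
        truth=params.true_landmarks(),
        params=params,
    )


def gen_ecg(
    r_times,
    fs: float = DEFAULT_FS_HZ,
    duration: Optional[float] = None,
    bump_width_s: float = 0.02,
    noise_sd: float = 0.0,
    seed=None,
) -> SampledTrace:
    """Synthetic ECG as unit-amplitude Gaussian bumps at the R times."""
    r_times = np.asarray(r_times, dtype=float)
    if duration is None:
        duration = float(r_times.max()) + 0.5
    times = np.arange(0.0, duration, 1.0 / fs)
    vals = np.zeros_like(times)
    for r in r_times:
        vals += np.exp(-0.5 * ((times - r) / bump_width_s) ** 2)
    if noise_sd > 0:
        vals = vals + np.random.default_rng(seed).normal(
            0.0, noise_sd, size=vals.shape)
    return SampledTrace(Channel.ECG, times, vals)


def random_beat_params(rng: np.random.Generator) -> BeatParams:
    """Draw a physiologically plausible random parameter set (for sweeps)."""
    ej = rng.uniform(0.28, 0.34)
    return BeatParams(
        heart_rate=rng.uniform(55.0, 90.0),
        Pdia=rng.uniform(55.0, 80.0),
        Psys=rng.uniform(110.0, 160.0),
        pressure_upstroke_delay=rng.uniform(0.03, 0.08),
        pressure_rise_time=rng.uniform(0.09, 0.14),
        dicrotic_notch_depth=rng.uniform(0.05, 0.20),
        diastolic_decay_tau=rng.uniform(0.30, 0.60),
        Vpeak=rng.uniform(60.0, 110.0),
        ejection_onset_delay=rng.uniform(0.02, 0.07),
        ejection_duration=ej,
        acceleration_time=rng.uniform(0.09, min(0.14, ej - 0.05)),
        severity_decoupling=0.0,
    )


# ---------------------------------------------------------------------------
# moment-matched truncated normals
# ---------------------------------------------------------------------------

def _truncnorm_moments(mu: float, sd: float) -> tuple[float, float]:
    a = (0.0 - mu) / sd
    d = sps.truncnorm(a, np.inf, loc=mu, scale=sd)
    return float(d.mean()), float(d.std())


def matched_truncnorm_params(mean: float, sd: float) -> tuple[float, float]:
    """Parent (mu, sigma) of a truncated-at-zero normal with given moments.

    Solved numerically so the truncated distribution has exactly the target
    mean and SD.  A truncated-at-zero normal cannot exceed a coefficient of
    variation of 1, so sd >= mean is rejected.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("need mean > 0 and sd >= 0")
    if sd == 0:
        return mean, 0.0
    if sd >= mean:
        raise ValueError(
            f"coefficient of variation {sd / mean:.2f} >= 1 is unreachable "
            "for a truncated-at-zero normal"
        )
    if sd / mean < 0.2:  # truncation negligible: parent = target
        return mean, sd
    def equations(p):
        m, s = _truncnorm_moments(p[0], abs(p[1]))
        return [m - mean, s - sd]
    sol, info, ier, msg = optimize.fsolve(
        equations, [mean, sd], full_output=True)
    if ier != 1:
        raise RuntimeError(f"moment matching failed for ({mean}, {sd}): {msg}")
    return float(sol[0]), float(abs(sol[1]))


def draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Draw n positive values whose mean/SD equal the configured moments."""
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = matched_truncnorm_params(mean, sd)
    a = (0.0 - mu) / sigma
    return sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n,
                             random_state=rng)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """(mean, sd) pairs of the baseline covariates for one outcome group."""

    slope_index: tuple[float, float]
    sbp: tuple[float, float]
    mean_gradient: tuple[float, float]
    max_gradient: tuple[float, float]
    svi: tuple[float, float]
    zva: tuple[float, float]
    two_year_mortality: float


#: group summaries of the motivating study (no-improvement / improvement)
NO_IMPROVEMENT_GROUP = GroupSpec(
    slope_index=(0.09, 0.08),
    sbp=(136.0, 4.0),
    mean_gradient=(48.0, 4.0),
    max_gradient=(81.0, 6.0),
    svi=(42.0, 3.0),
    zva=(4.6, 1.3),
    two_year_mortality=0.44,
)
IMPROVEMENT_GROUP = GroupSpec(
    slope_index=(0.23, 0.19),
    sbp=(130.0, 3.0),
    mean_gradient=(49.0, 2.0),
    max_gradient=(86.0, 3.0),
    svi=(43.0, 2.0),
    zva=(4.7, 1.7),
    two_year_mortality=0.09,
)


@dataclass(frozen=True)
class CohortParams:
    """Structure of a synthetic study cohort."""

    n: int = 102
    improvement_prob: float = 82.0 / 102.0
    improved: GroupSpec = IMPROVEMENT_GROUP
    not_improved: GroupSpec = NO_IMPROVEMENT_GROUP
    subjective_prob: float = 93.0 / 102.0
    low_gradient_fraction: float = 0.30
    censoring_rate: float = 0.05      # P(censored before 2 years)
    seed: int = 0

    def __post_init__(self):
        if self.n < 10:
            raise ValueError("cohort size must be at least 10")
        for name in ("improvement_prob", "subjective_prob",
                     "low_gradient_fraction", "censoring_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def _exp_times(rng, rate: float, n: int) -> np.ndarray:
    if rate <= 0:
        return np.full(n, np.inf)
    return rng.exponential(1.0 / rate, size=n)


def gen_cohort(params: CohortParams) -> pd.DataFrame:
    """Generate a patient table whose labels are rule-consistent.

    The ground-truth improvement label drives the 6-minute-walk and
    NT-proBNP trajectories with safe margins around the endpoint
    thresholds, so applying the endpoint rule to the generated table
    recovers the label (round-trip property).  Deaths follow per-group
    exponential hazards matched to the configured 2-year mortality, with
    independent exponential censoring; improvement-group deaths are
    non-cardiac, no-improvement-group deaths are heart-failure deaths.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    improved = rng.random(n) < params.improvement_prob

    def per_group(spec_attr):
        out = np.empty(n)
        for mask, spec in ((improved, params.improved),
                           (~improved, params.not_improved)):
            mean, sd = getattr(spec, spec_attr)
            out[mask] = draw_truncated_normal(rng, mean, sd, int(mask.sum()))
        return out

    slope = per_group("slope_index")
    sbp = per_group("sbp")
    mean_grad = per_group("mean_gradient")
    max_grad = per_group("max_gradient")
    svi = per_group("svi")
    zva_vals = per_group("zva")

    low_gradient = rng.random(n) < params.low_gradient_fraction
    mean_grad = np.where(low_gradient, rng.uniform(20.0, 39.0, n), mean_grad)
    max_grad = np.where(low_gradient, mean_grad * rng.uniform(1.5, 1.9, n),
                        max_grad)

    walk_base = np.clip(rng.normal(250.0, 80.0, n), 60.0, None)
    nt_base = np.exp(rng.normal(8.0, 0.6, n))

    # label-consistent trajectories with safe margins around the thresholds
    walk_route = rng.random(n) < 0.65
    walk_change = np.where(
        improved & walk_route, rng.uniform(0.12, 0.40, n),
        np.where(improved, rng.uniform(-0.10, 0.07, n),
                 rng.uniform(-0.15, 0.07, n)),
    )
    nt_ratio = np.where(
        improved & ~walk_route, rng.uniform(0.20, 0.48, n),
        np.where(improved, rng.uniform(0.55, 1.20, n),
                 rng.uniform(0.55, 1.40, n)),
    )
    walk_6m = walk_base * (1.0 + walk_change)
    nt_6m = nt_base * nt_ratio
    walk_30d = walk_base * (1.0 + 0.8 * walk_change)
    nt_30d = nt_base * np.where(improved & ~walk_route, nt_ratio,
                                np.clip(nt_ratio, 0.55, None))
    # the 30-day walk gain of walk-route improvers must already clear 10%
    walk_30d = np.where(improved & walk_route,
                        walk_base * (1.0 + np.maximum(0.8 * walk_change, 0.12)),
                        walk_30d)

    # subjective improvement: one NYHA class and/or >= 10 KCCQ points
    subj = rng.random(n) < params.subjective_prob
    nyha_pre = rng.integers(2, 5, size=n)
    nyha_post = np.where(subj, nyha_pre - 1, nyha_pre)
    kccq_pre = rng.uniform(25.0, 65.0, n)
    kccq_post = np.where(subj, kccq_pre + rng.uniform(12.0, 30.0, n),
                         kccq_pre + rng.uniform(-5.0, 8.0, n))

    # survival: exponential hazards matched to configured 2-year mortality
    rate = np.where(improved,
                    -np.log(1.0 - params.improved.two_year_mortality) / 730.0,
                    -np.log(1.0 - params.not_improved.two_year_mortality) / 730.0)
    t_death = rng.exponential(1.0 / rate)
    c_rate = (-np.log(1.0 - params.censoring_rate) / 730.0
              if params.censoring_rate > 0 else 0.0)
    t_cens = _exp_times(rng, c_rate, n)
    observed_death = t_death <= np.minimum(t_cens, 730.0)
    survival_time = np.minimum(np.minimum(t_death, t_cens), 730.0)

    death_time = np.where(observed_death, t_death, np.nan)
    death_cause = np.where(
        observed_death, np.where(improved, "other", "heart_failure"), "none"
    )
    died_before_6m = observed_death & (t_death <= 182.5)
    hf_event_after_30d = (~improved) & died_before_6m & (t_death > 30.0)

    # measurements that postdate death are missing
    walk_6m = np.where(died_before_6m, np.nan, walk_6m)
    nt_6m = np.where(died_before_6m, np.nan, nt_6m)
    died_before_30d = observed_death & (t_death < 30.0)
    walk_30d = np.where(died_before_30d, np.nan, walk_30d)
    nt_30d = np.where(died_before_30d, np.nan, nt_30d)
    nyha_post_f = np.where(died_before_30d, np.nan, nyha_post.astype(float))
    kccq_post = np.where(died_before_30d, np.nan, kccq_post)

    return pd.DataFrame({
        "id": [f"P{i:04d}" for i in range(n)],
        "true_improved": improved,
        "slope_index": slope,
        "alpha_deg": np.degrees(np.arctan(slope)),
        "sbp": sbp,
        "mean_gradient": mean_grad,
        "max_gradient": max_grad,
        "svi": svi,
        "zva": zva_vals,
        "low_gradient_flag": low_gradient,
        "walk_base": walk_base,
        "walk_30d": walk_30d,
        "walk_6m": walk_6m,
        "ntprobnp_base": nt_base,
        "ntprobnp_30d": nt_30d,
        "ntprobnp_6m": nt_6m,
        "nyha_pre": nyha_pre,
        "nyha_post": nyha_post_f,
        "kccq_pre": kccq_pre,
        "kccq_post": kccq_post,
        "death_time": death_time,
        "death_cause": death_cause,
        "eval_30d_available": ~died_before_30d,
        "hf_event_after_30d": hf_event_after_30d,
        "survival_time": survival_time,
        "survival_event": observed_death,
    })
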