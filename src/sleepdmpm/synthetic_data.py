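"""Synthetic sleep-diary panel generator.

The study's deposited diary data are access-controlled, so every stage of
the pipeline is exercised on generated panels that carry the same
statistical structure the analysis assumes: up to six consecutive diary
days per subject, the temporal-ordering DAG over the three outcome
channels, feedback from the previous cycle's outcomes into the current
cycle's stress items, weather shared by all subjects within a day (one
study site), and covariates on the scales the variable constructions
produce.  The generator runs the DAG forward under known ground-truth
parameters and returns them alongside the panel, so parameter-recovery
and contrast tests have an exact reference.

Day-1 outcomes are drawn from an approximately stationary marginal by
burning in ten discarded pre-days; the study treats day 1 as given data,
so the generator has to invent it somehow and this is the least arbitrary
choice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .dmpm_core import (
    CHANNELS,
    SIM_ORDER,
    ChannelParams,
    DMPMParams,
    _draw_level,
    _encode_parent,
    default_channel_specs,
)
from .panel_data import (
    COVARIATE_ORDER,
    SUBSAMPLES,
    SleepPanel,
    default_covariate_specs,
)

__all__ = [
    "GeneratorConfig",
    "default_true_params",
    "null_params",
    "generate_panel",
    "generate_all_subsamples",
    "write_true_params",
    "read_true_params",
]

#: Per-covariate sampling models; plausible diary/weather/FFQ scales,
#: not estimates from the restricted dataset.
DEFAULT_COVARIATE_MODEL: dict = {
    "stress_base_cum": (0.2, 0.5, 0.8),  # P(s<=1), P(s<=2), P(s<=3) at neutral feedback
    "bedtime_hr": {"mean": 0.0, "sd": 0.75},
    "time_in_bed_hr": {"mean": 7.0, "sd": 0.8, "min": 3.0},
    "caffeine": {"p": 0.15},
    "alcohol": {"p": 0.30},
    "ict": {"p": 0.50},
    "precip_mm": {"p_wet": 0.45, "mean": 4.0},
    "temp_mean": {"summer": 20.0, "winter": -2.0, "sd": 3.0},
    "temp_range": {"mean": 8.0, "sd": 2.0, "min": 0.5},
    "wind_mean": {"log_mean": np.log(3.0), "log_sd": 0.4},
    "sunshine_hr": {"mean": 6.0, "sd": 3.0, "min": 0.0, "max": 14.0},
    "age": {"mean": 50.0, "sd": 13.0, "min": 20.0, "max": 80.0},
    "bmi": {"male": 23.8, "female": 22.0, "sd": 3.0, "min": 15.0, "max": 40.0},
    "sbp": {"mean": 125.0, "sd": 15.0, "min": 85.0, "max": 200.0},
    "exercise_p": 0.4,
    # medians in g per 1000 kcal: cereals, potatoes, beans, green/yellow veg,
    # other veg, fruits, mushrooms, seaweeds, seafood, meat, eggs, dairy
    "diet_median": (150.0, 20.0, 30.0, 40.0, 50.0, 40.0, 8.0, 5.0, 40.0, 45.0, 25.0, 60.0),
    "diet_log_sd": 0.5,
}

#: Approximate interquartile ranges implied by the covariate model above;
#: the true-parameter fixture expresses effects per IQR and divides by these,
#: which keeps category-level contrast effects in the single-digit
#: percentage-point range.
APPROX_IQR: dict[str, float] = {
    "stress1": 1.0, "stress2": 1.0, "stress3": 1.0,
    "stress4": 1.0, "stress5": 1.0, "stress6": 1.0,
    "bedtime_hr": 1.0, "time_in_bed_hr": 1.1, "caffeine": 1.0,
    "alcohol": 1.0, "ict": 1.0,
    "precip_mm": 2.4, "temp_mean": 4.0, "temp_range": 2.7,
    "wind_mean": 1.6, "sunshine_hr": 4.0,
    "age": 17.0, "bmi": 4.0, "sbp": 20.0,
    "exercise1": 1.0, "exercise2": 1.0, "exercise3": 1.0, "exercise4": 1.0,
    **{f"diet{i + 1}": m * 0.687
       for i, m in enumerate(DEFAULT_COVARIATE_MODEL["diet_median"])},
}

#: Approximate covariate means (summer reference) used to place intercepts.
APPROX_MEAN: dict[str, float] = {
    **{f"stress{i}": 2.5 for i in range(1, 7)},
    "bedtime_hr": 0.0, "time_in_bed_hr": 7.0, "caffeine": 0.15,
    "alcohol": 0.30, "ict": 0.50,
    "precip_mm": 1.8, "temp_mean": 20.0, "temp_range": 8.0,
    "wind_mean": 3.2, "sunshine_hr": 6.0,
    "age": 50.0, "bmi": 23.0, "sbp": 125.0,
    **{f"exercise{i}": 0.4 for i in range(1, 5)},
    **{f"diet{i + 1}": m * 1.13  # lognormal mean = median * exp(sd^2/2)
       for i, m in enumerate(DEFAULT_COVARIATE_MODEL["diet_median"])},
}

#: Target stationary outcome distributions used to place intercepts/cutpoints.
_BASE_P_Y1 = 0.30                      # P(daytime sleepiness)
_BASE_CUM_Y2 = (0.15, 0.50)            # P(y2<=1), P(y2<=2)
_BASE_CUM_Y3 = (0.20, 0.65)            # P(y3<=1), P(y3<=2)

# Effects per interquartile shift on the linear predictor, by channel.
# Signs follow the narrative direction of each item (irritation worsens
# outcomes, alcohol eases onset but spoils waking, ...); every category
# keeps at least one active and at least one everywhere-null item.
_IQR_EFFECTS: dict[str, dict[str, float]] = {
    "y1": {  # eta up = more sleepiness
        "stress1": -0.20, "stress2": 0.30,
        "bedtime_hr": 0.30,
        "temp_range": 0.25,
        "bmi": 0.25,
        "exercise1": -0.30, "exercise2": 0.20, "exercise3": -0.25,
        "diet9": -0.25, "diet12": -0.20,
    },
    "y2": {  # eta up = easier sleep onset
        "stress2": -0.25,
        "bedtime_hr": -0.25, "caffeine": -0.40, "alcohol": 0.25,
        "time_in_bed_hr": -0.20,
        "temp_mean": -0.20,
        "age": -0.20,
        "exercise1": 0.20,
        "diet4": 0.25, "diet5": 0.20,
    },
    "y3": {  # eta up = more refreshed waking
        "stress1": 0.25, "stress5": -0.20,
        "alcohol": -0.30, "time_in_bed_hr": 0.30,
        "sunshine_hr": 0.20,
        "age": 0.20,
        "exercise3": 0.20,
        "diet1": -0.25, "diet8": 0.25,
    },
}

_LAG_BETAS = {
    # order = ChannelSpec.parent_columns()
    "y1": np.array([0.8, -0.3, -0.6, -0.3, -0.6]),   # y1_l1, y2_l1:2, y2_l1:3, y3_l0:2, y3_l0:3
    "y2": np.array([0.4, 0.8, 0.3, 0.6, -0.5]),      # y2_l1:2, y2_l1:3, y3_l0:2, y3_l0:3, y1_l0
    "y3": np.array([0.35, 0.7, -0.4, 0.2, 0.4]),     # y3_l1:2, y3_l1:3, y1_l1, y2_l1:2, y2_l1:3
}


def _beta_x_for(channel: str) -> np.ndarray:
    beta = np.zeros(len(COVARIATE_ORDER))
    for name, per_iqr in _IQR_EFFECTS[channel].items():
        beta[COVARIATE_ORDER.index(name)] = per_iqr / APPROX_IQR[name]
    return beta


def _mean_lag_eta(channel: str) -> float:
    """Lag-term contribution at the target stationary outcome distribution."""
    p1 = _BASE_P_Y1
    p2 = (_BASE_CUM_Y2[0], _BASE_CUM_Y2[1] - _BASE_CUM_Y2[0], 1 - _BASE_CUM_Y2[1])
    p3 = (_BASE_CUM_Y3[0], _BASE_CUM_Y3[1] - _BASE_CUM_Y3[0], 1 - _BASE_CUM_Y3[1])
    means = {
        "y1": [p1],
        "y2": [p2[1], p2[2]],
        "y3": [p3[1], p3[2]],
    }
    spec = default_channel_specs()[channel]
    vals: list[float] = []
    for var, _lag in spec.parents:
        vals.extend(means[var])
    return float(np.dot(_LAG_BETAS[channel], vals))


def default_true_params(feedback_strength: float = 0.3) -> DMPMParams:
    """Documented ground-truth parameter fixture.

    Intercepts and cutpoints are placed so that, at the reference covariate
    means and the target stationary outcome distribution, sleepiness runs
    near a 30% base rate and the two ordinal channels have non-degenerate
    three-level splits.  Serial (AR) coefficients are positive: good sleep
    persists.
    """
    channels: dict[str, ChannelParams] = {}
    for c in CHANNELS:
        beta_x = _beta_x_for(c)
        mean_eta = float(np.dot(beta_x, [APPROX_MEAN[k] for k in COVARIATE_ORDER]))
        mean_eta += _mean_lag_eta(c)
        if c == "y1":
            channels[c] = ChannelParams(
                family="bernoulli-logit",
                beta_lag=_LAG_BETAS[c].copy(),
                beta_x=beta_x,
                intercept=float(logit(_BASE_P_Y1) - mean_eta),
            )
        else:
            cum = _BASE_CUM_Y2 if c == "y2" else _BASE_CUM_Y3
            channels[c] = ChannelParams(
                family="cumulative-logit-3",
                beta_lag=_LAG_BETAS[c].copy(),
                beta_x=beta_x,
                cutpoints=(float(logit(cum[0]) + mean_eta), float(logit(cum[1]) + mean_eta)),
            )
    return DMPMParams(channels=channels, feedback_strength=feedback_strength)


def null_params() -> DMPMParams:
    """All-zero coefficient variant (uniform-ish outcomes) for null testing."""
    channels = {}
    for c in CHANNELS:
        if c == "y1":
            channels[c] = ChannelParams(
                "bernoulli-logit", np.zeros(5), np.zeros(len(COVARIATE_ORDER)), intercept=0.0
            )
        else:
            channels[c] = ChannelParams(
                "cumulative-logit-3", np.zeros(5), np.zeros(len(COVARIATE_ORDER)),
                cutpoints=(float(logit(1 / 3)), float(logit(2 / 3))),
            )
    return DMPMParams(channels=channels, feedback_strength=0.0)


@dataclass
class GeneratorConfig:
    """Configuration of one synthetic subsample panel.

    ``stagger_days`` spreads subjects' diary start dates uniformly over a
    window of calendar days, the way a field study enrolls participants
    over weeks within a season: everyone shares one daily weather series
    (one study site), but diary day t maps to a different calendar day per
    subject.  Set it to 0 to give all subjects identical diary dates.
    """

    n_subjects: int = 400
    n_days: int = 6
    seed: int = 0
    subsample: str = "male-summer"
    params: DMPMParams | None = None
    covariate_model: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    burnin: int = 10
    stagger_days: int = 60

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError(f"n_subjects must be positive, got {self.n_subjects}")
        if not 2 <= self.n_days <= 6:
            raise ValueError(f"n_days must be in 2..6, got {self.n_days}")
        if self.subsample not in SUBSAMPLES:
            raise ValueError(f"unknown subsample {self.subsample!r}")
        if self.params is None:
            self.params = default_true_params()


def _badness(state: dict[str, np.ndarray]) -> np.ndarray:
    """Outcome 'badness' score in [0, 3] driving feedback into stress."""
    return state["y1"] + (3.0 - state["y2"]) / 2.0 + (3.0 - state["y3"]) / 2.0


def _draw_stress(
    rng: np.random.Generator, cfg: GeneratorConfig, prev_state: dict[str, np.ndarray]
) -> np.ndarray:
    """One day's six stress items (n_subjects, 6), cumulative-logit on {1..4}
    shifted by feedback from the previous cycle's outcomes (centered so the
    neutral state leaves the base distribution unchanged)."""
    n = cfg.n_subjects
    cum = cfg.covariate_model["stress_base_cum"]
    eta = cfg.params.feedback_strength * (_badness(prev_state) - 1.5)
    qs = [expit(logit(c) - eta)[:, None] for c in cum]  # each (n, 1)
    u = rng.random((n, 6))
    return np.select([u < qs[0], u < qs[1], u < qs[2]], [1.0, 2.0, 3.0], 4.0)


def _truncnorm(rng, mean, sd, size, lo=-np.inf, hi=np.inf):
    return np.clip(rng.normal(mean, sd, size), lo, hi)


def generate_panel(config: GeneratorConfig) -> tuple[SleepPanel, DMPMParams]:
    """Run the DAG forward and return a balanced panel plus the true params.

    Weather is drawn once per day and shared by every subject; stress items
    receive feedback from the previous cycle's outcomes; bedtime items and
    weather are exogenous.  Outcomes follow the within-cycle order
    ``y3 -> y1 -> y2`` with the model's lag alignment, via the same
    probability kernels the likelihood uses.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cm = cfg.covariate_model
    n, D = cfg.n_subjects, cfg.burnin + cfg.n_days
    season = cfg.subsample.split("-")[1]
    gender = cfg.subsample.split("-")[0]
    channel_specs = default_channel_specs()
    cov_specs = {s.name: s for s in default_covariate_specs()}

    X = np.zeros((n, D, len(COVARIATE_ORDER)))
    col = {name: j for j, name in enumerate(COVARIATE_ORDER)}

    # time-invariant covariates, constant across days
    ti: dict[str, np.ndarray] = {
        "age": _truncnorm(rng, cm["age"]["mean"], cm["age"]["sd"], n,
                          cm["age"]["min"], cm["age"]["max"]),
        "bmi": _truncnorm(rng, cm["bmi"][gender], cm["bmi"]["sd"], n,
                          cm["bmi"]["min"], cm["bmi"]["max"]),
        "sbp": _truncnorm(rng, cm["sbp"]["mean"], cm["sbp"]["sd"], n,
                          cm["sbp"]["min"], cm["sbp"]["max"]),
    }
    for i in range(1, 5):
        ti[f"exercise{i}"] = (rng.random(n) < cm["exercise_p"]).astype(float)
    for i, med in enumerate(cm["diet_median"]):
        ti[f"diet{i + 1}"] = np.exp(rng.normal(np.log(med), cm["diet_log_sd"], n))
    for name, vals in ti.items():
        X[:, :, col[name]] = vals[:, None]

    # weather: one shared daily series (same study site); subjects' diary
    # windows start at staggered calendar offsets within the season
    W = D + cfg.stagger_days
    wet = rng.random(W) < cm["precip_mm"]["p_wet"]
    weather = {
        "precip_mm": wet * rng.exponential(cm["precip_mm"]["mean"], W),
        "temp_mean": rng.normal(cm["temp_mean"][season], cm["temp_mean"]["sd"], W),
        "temp_range": _truncnorm(rng, cm["temp_range"]["mean"], cm["temp_range"]["sd"],
                                 W, cm["temp_range"]["min"]),
        "wind_mean": np.exp(rng.normal(cm["wind_mean"]["log_mean"],
                                       cm["wind_mean"]["log_sd"], W)),
        "sunshine_hr": _truncnorm(rng, cm["sunshine_hr"]["mean"], cm["sunshine_hr"]["sd"],
                                  W, cm["sunshine_hr"]["min"], cm["sunshine_hr"]["max"]),
    }
    offsets = rng.integers(0, cfg.stagger_days + 1, n)
    day_idx = offsets[:, None] + np.arange(D)[None, :]
    for name, vals in weather.items():
        X[:, :, col[name]] = vals[day_idx]

    # bedtime conditions: exogenous per subject-day
    X[:, :, col["bedtime_hr"]] = rng.normal(cm["bedtime_hr"]["mean"],
                                            cm["bedtime_hr"]["sd"], (n, D))
    X[:, :, col["time_in_bed_hr"]] = _truncnorm(
        rng, cm["time_in_bed_hr"]["mean"], cm["time_in_bed_hr"]["sd"], (n, D),
        cm["time_in_bed_hr"]["min"])
    for name in ("caffeine", "alcohol", "ict"):
        X[:, :, col[name]] = (rng.random((n, D)) < cm[name]["p"]).astype(float)

    # per-channel covariate lag index vectors
    lag_vec = {
        c: np.array([cov_specs[name].lag(c) for name in COVARIATE_ORDER])
        for c in CHANNELS
    }
    jidx = np.arange(len(COVARIATE_ORDER))

    def cov_eta(c: str, t: int) -> np.ndarray:
        tt = np.maximum(t - lag_vec[c], 0)  # clamp only reachable on burn-in day 0
        vals = X[:, tt, jidx]
        return vals @ cfg.params.channels[c].beta_x

    # initial pre-day outcomes from the target base distribution
    state = {
        "y1": (rng.random(n) < _BASE_P_Y1).astype(float),
        "y2": rng.choice([1.0, 2.0, 3.0], n,
                         p=(_BASE_CUM_Y2[0], _BASE_CUM_Y2[1] - _BASE_CUM_Y2[0],
                            1 - _BASE_CUM_Y2[1])),
        "y3": rng.choice([1.0, 2.0, 3.0], n,
                         p=(_BASE_CUM_Y3[0], _BASE_CUM_Y3[1] - _BASE_CUM_Y3[0],
                            1 - _BASE_CUM_Y3[1])),
    }
    outcomes = {c: np.zeros((n, D)) for c in CHANNELS}
    stress_cols = [col[f"stress{i}"] for i in range(1, 7)]
    for t in range(D):
        X[:, t, stress_cols] = _draw_stress(rng, cfg, state)
        prev, cur = state, {}
        for c in SIM_ORDER:
            ch = cfg.params.channels[c]
            eta = cov_eta(c, t)
            k = 0
            for var, lag in channel_specs[c].parents:
                vals = prev[var] if lag else cur[var]
                for enc in _encode_parent(var, vals):
                    eta = eta + ch.beta_lag[k] * enc
                    k += 1
            cur[c] = _draw_level(rng, ch, eta)
        state = cur
        for c in CHANNELS:
            outcomes[c][:, t] = state[c]

    # keep the last n_days as the observed diary window
    keep = slice(cfg.burnin, D)
    T = cfg.n_days
    rows = {
        "subject_id": np.repeat([f"S{i + 1:04d}" for i in range(n)], T),
        "day": np.tile(np.arange(1, T + 1), n),
        "y1": outcomes["y1"][:, keep].astype(int).ravel(),
        "y2": outcomes["y2"][:, keep].astype(int).ravel(),
        "y3": outcomes["y3"][:, keep].astype(int).ravel(),
    }
    for name in COVARIATE_ORDER:
        rows[name] = X[:, keep, col[name]].ravel()
    rows["subsample"] = cfg.subsample
    panel = SleepPanel.from_frame(pd.DataFrame(rows))
    return panel, cfg.params


def generate_all_subsamples(
    n_subjects: int = 400, n_days: int = 6, seed: int = 0,
    params: DMPMParams | None = None,
) -> dict[str, tuple[SleepPanel, DMPMParams]]:
    """One panel per gender x season subsample, with distinct sub-seeds."""
    out = {}
    for k, name in enumerate(SUBSAMPLES):
        cfg = GeneratorConfig(
            n_subjects=n_subjects, n_days=n_days,
            seed=(seed * 7919 + k) % (2**31 - 1), subsample=name, params=params,
        )
        out[name] = generate_panel(cfg)
    return out


def write_true_params(params: DMPMParams, path) -> None:
    """Sidecar file of the generating parameters (JSON) for recovery tests."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(params.to_dict(), fh, indent=1)


def read_true_params(path) -> DMPMParams:
    with open(path, encoding="utf-8") as fh:
        return DMPMParams.from_dict(json.load(fh))
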