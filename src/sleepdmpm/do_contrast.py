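"""Interquartile do-intervention contrasts on the posterior predictive.

For each covariate item ``k`` the contrast is

    |Pr(outcome | do(x_k = Q3)) - Pr(outcome | do(x_k = Q1))|

where the intervention holds the item fixed for every subject and day
(severing any feedback into it), all other covariates stay at their
observed values, outcomes are re-simulated forward from each subject's
observed day-1 values, and the probability is averaged over all subjects
and days 2..T (day 1 is the initial condition).  Category effects sum the
per-item absolute contrasts draw by draw; binary items whose IQR collapses
to zero (the pre-bed caffeine rule) use the full 0-to-1 width instead.

The "AR(1)" row contrasts clamping the previous cycle's outcome vector to
its best configuration (no sleepiness, easy onset, refreshed waking)
against its worst — the serial-dependence contribution on the same scale.

Every Monte-Carlo quantity has an exact counterpart here:
:func:`exact_contrast` enumerates the outcome state space day by day
(a forward pass over all 2x3x3 joint outcome states) and is used as the
oracle the simulator is tested against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dmpm_core import (
    CHANNELS,
    ChannelSpec,
    DMPMParams,
    default_channel_specs,
    family_probs,
    simulate_forward,
)
from .fit_bayes import PosteriorDraws
from .panel_data import (
    COVARIATE_ORDER,
    CovariateSpec,
    SleepPanel,
    attach_endpoints,
    default_covariate_specs,
)

__all__ = [
    "OUTCOME_TARGETS",
    "AR1_BEST",
    "AR1_WORST",
    "ContrastResult",
    "item_contrast",
    "category_effect",
    "ar1_effect",
    "exact_contrast",
    "contrast_analysis",
]

#: The five reported outcome targets: sleepiness present; sleep-onset and
#: waking at the bottom and top of their 3-level scales.
OUTCOME_TARGETS = (("y1", 1), ("y2", 1), ("y2", 3), ("y3", 1), ("y3", 3))

AR1_BEST = {"y1": 0.0, "y2": 3.0, "y3": 3.0}
AR1_WORST = {"y1": 1.0, "y2": 1.0, "y3": 1.0}

CATEGORY_ORDER = ("stress", "bedtime", "weather", "physical", "exercise", "dietary", "ar1")


def outcome_key(channel: str, level: int) -> str:
    return f"{channel}={level}"


def _level_index(channel: str, level: int) -> int:
    return int(level) if channel == "y1" else int(level) - 1


def _check_outcome(outcome: tuple[str, int]) -> tuple[str, int]:
    if tuple(outcome) not in OUTCOME_TARGETS:
        raise ValueError(f"outcome {outcome} not one of {OUTCOME_TARGETS}")
    return tuple(outcome)


@dataclass
class ContrastResult:
    """Machine-readable contrast table for one subsample.

    ``per_item`` and ``per_category`` map outcome keys (``"y1=1"`` ...) to
    {item/category -> posterior samples of |dPr|}; ``ar1`` holds the
    serial-dependence samples.  Per-category samples are the draw-wise sums
    of their items' samples.
    """

    subsample: str
    per_item: dict[str, dict[str, np.ndarray]]
    per_category: dict[str, dict[str, np.ndarray]]
    ar1: dict[str, np.ndarray]
    item_category: dict[str, str]
    seed: int = 0

    def summary_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (outcome, category, item); category-level
        rows carry an empty item field.  Intervals are equal-tailed 90%."""
        rows = []
        for okey in self.per_item:
            for item, s in self.per_item[okey].items():
                rows.append(self._row(okey, self.item_category[item], item, s))
            for cat, s in self.per_category[okey].items():
                rows.append(self._row(okey, cat, "", s))
            if okey in self.ar1:
                rows.append(self._row(okey, "ar1", "", self.ar1[okey]))
        df = pd.DataFrame(rows)
        df["category"] = pd.Categorical(df["category"], categories=CATEGORY_ORDER,
                                        ordered=True)
        return df.sort_values(["outcome", "category", "item"],
                              kind="stable").reset_index(drop=True)

    @staticmethod
    def _row(okey, cat, item, s):
        return {
            "outcome": okey, "category": cat, "item": item,
            "posterior_mean": float(np.mean(s)),
            "ci_low": float(np.quantile(s, 0.05)),
            "ci_high": float(np.quantile(s, 0.95)),
        }

    def to_csv(self, path) -> None:
        self.summary_frame().to_csv(path, index=False, float_format="%.6f")

    def to_json_dict(self) -> dict:
        out: dict = {"subsample": self.subsample, "seed": self.seed, "categories": {}}
        for okey in self.per_category:
            out["categories"][okey] = {
                cat: {
                    "posterior_mean": float(np.mean(s)),
                    "ci_low": float(np.quantile(s, 0.05)),
                    "ci_high": float(np.quantile(s, 0.95)),
                }
                for cat, s in self.per_category[okey].items()
            }
            if okey in self.ar1:
                s = self.ar1[okey]
                out["categories"][okey]["ar1"] = {
                    "posterior_mean": float(np.mean(s)),
                    "ci_low": float(np.quantile(s, 0.05)),
                    "ci_high": float(np.quantile(s, 0.95)),
                }
        return out


# ---------------------------------------------------------------------------
# Monte-Carlo contrasts
# ---------------------------------------------------------------------------

def _panel_sim_inputs(panel: SleepPanel):
    wide = panel.wide_arrays()
    initial = np.stack([wide[c][:, 0] for c in CHANNELS], axis=1)
    cov_path = {name: wide[name] for name in COVARIATE_ORDER}
    return initial, cov_path


def _delta_from_freqs(freq_a, freq_b, outcomes) -> dict[str, float]:
    out = {}
    for ch, level in outcomes:
        i = _level_index(ch, level)
        a = freq_a[ch][1:, i].mean()  # days 2..T
        b = freq_b[ch][1:, i].mean()
        out[outcome_key(ch, level)] = abs(a - b)
    return out


def _thin_indices(n_total: int, thin_to: int | None) -> np.ndarray:
    if thin_to is None or thin_to >= n_total:
        return np.arange(n_total)
    return np.unique(np.linspace(0, n_total - 1, thin_to).astype(int))


def _draw_seed(seed: int, d: int, j: int) -> int:
    return int((seed * 1_000_003 + d * 131 + j * 7) % (2**31 - 1))


def _mc_item_samples(
    draws: PosteriorDraws,
    panel: SleepPanel,
    item: CovariateSpec,
    outcomes,
    n_rep: int,
    seed: int,
    thin_to: int | None,
) -> dict[str, np.ndarray]:
    """Posterior samples of |dPr| for one item, all requested outcomes.

    Both intervention endpoints are simulated with common random numbers,
    so an item with zero coefficients gives exactly zero."""
    if item.name not in panel.df.columns:
        raise KeyError(f"item {item.name!r} not in panel")
    if item.shift_low is None or item.shift_high is None:
        raise ValueError(f"item {item.name!r} has no shift endpoints attached")
    j = COVARIATE_ORDER.index(item.name)
    idx = _thin_indices(draws.n_draws, thin_to)
    keys = [outcome_key(*o) for o in outcomes]
    if item.shift_low == item.shift_high:
        warnings.warn(
            f"item {item.name!r}: degenerate endpoints; contrast reported as zero",
            stacklevel=2,
        )
        return {k: np.zeros(len(idx)) for k in keys}
    initial, cov_path = _panel_sim_inputs(panel)
    samples = {k: np.empty(len(idx)) for k in keys}
    for pos, d in enumerate(idx):
        params = draws.params_at(int(d))
        s = _draw_seed(seed, int(d), j)
        f_low = simulate_forward(params, initial, cov_path,
                                 policy={item.name: item.shift_low},
                                 n_rep=n_rep, seed=s)
        f_high = simulate_forward(params, initial, cov_path,
                                  policy={item.name: item.shift_high},
                                  n_rep=n_rep, seed=s)
        delta = _delta_from_freqs(f_low, f_high, outcomes)
        for k in keys:
            samples[k][pos] = delta[k]
    return samples


def item_contrast(
    draws: PosteriorDraws,
    panel: SleepPanel,
    item: CovariateSpec,
    outcome: tuple[str, int],
    n_rep: int = 200,
    seed: int = 0,
    thin_to: int | None = None,
) -> np.ndarray:
    """Posterior samples of the item's |dPr| for one outcome target."""
    outcome = _check_outcome(outcome)
    return _mc_item_samples(draws, panel, item, [outcome], n_rep, seed, thin_to)[
        outcome_key(*outcome)
    ]


def category_effect(
    item_contrasts: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict[str, float]]:
    """Draw-wise sum over a category's items, with mean and 90% interval."""
    if not item_contrasts:
        raise ValueError("empty category")
    samples = np.sum(np.stack(list(item_contrasts.values())), axis=0)
    summary = {
        "posterior_mean": float(samples.mean()),
        "ci_low": float(np.quantile(samples, 0.05)),
        "ci_high": float(np.quantile(samples, 0.95)),
    }
    return samples, summary


def ar1_effect(
    draws: PosteriorDraws,
    panel: SleepPanel,
    outcome: tuple[str, int],
    n_rep: int = 200,
    seed: int = 0,
    thin_to: int | None = None,
) -> np.ndarray:
    """Serial-dependence contrast: best vs. worst lagged outcome vector."""
    outcome = _check_outcome(outcome)
    return _mc_ar1_samples(draws, panel, [outcome], n_rep, seed, thin_to)[
        outcome_key(*outcome)
    ]


def _mc_ar1_samples(draws, panel, outcomes, n_rep, seed, thin_to):
    initial, cov_path = _panel_sim_inputs(panel)
    idx = _thin_indices(draws.n_draws, thin_to)
    keys = [outcome_key(*o) for o in outcomes]
    samples = {k: np.empty(len(idx)) for k in keys}
    for pos, d in enumerate(idx):
        params = draws.params_at(int(d))
        s = _draw_seed(seed, int(d), len(COVARIATE_ORDER))
        f_best = simulate_forward(params, initial, cov_path, n_rep=n_rep, seed=s,
                                  lag_outcome_clamp=AR1_BEST)
        f_worst = simulate_forward(params, initial, cov_path, n_rep=n_rep, seed=s,
                                   lag_outcome_clamp=AR1_WORST)
        delta = _delta_from_freqs(f_best, f_worst, outcomes)
        for k in keys:
            samples[k][pos] = delta[k]
    return samples


# ---------------------------------------------------------------------------
# exact enumeration oracle
# ---------------------------------------------------------------------------

_STATES = [(y1, y2, y3) for y1 in (0, 1) for y2 in (1, 2, 3) for y3 in (1, 2, 3)]

MAX_EXACT_DAYS = 4
MAX_EXACT_SUBJECTS = 5


def _exact_day_marginals(
    params: DMPMParams,
    panel: SleepPanel,
    policy: dict[str, float] | None,
    channel_specs: dict[str, ChannelSpec],
    cov_specs: list[CovariateSpec],
    lag_outcome_clamp: dict[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Exact per-day outcome-level probabilities by forward summation over
    the 18 joint outcome states, one subject at a time (plain scalar loops;
    this is the verification oracle, kept independent of the vectorized
    simulator)."""
    wide = panel.wide_arrays()
    n_subj = wide["y1"].shape[0]
    T = wide["y1"].shape[1]
    by_name = {s.name: s for s in cov_specs}
    marg = {c: np.zeros((n_subj, T, 3 if c != "y1" else 2)) for c in CHANNELS}

    def cov_value(name, i, t, ch):
        if policy and name in policy:
            return float(policy[name])
        lag = by_name[name].lag(ch)
        return float(wide[name][i, t - lag])

    def ch_probs(ch, i, t, prev, cur):
        p = params.channels[ch]
        eta = 0.0
        for name, beta in zip(COVARIATE_ORDER, p.beta_x):
            if beta != 0.0:
                eta += beta * cov_value(name, i, t, ch)
        k = 0
        for var, lag in channel_specs[ch].parents:
            src = prev if lag else cur
            v = src[var]
            if var == "y1":
                eta += p.beta_lag[k] * v
                k += 1
            else:
                eta += p.beta_lag[k] * (v == 2) + p.beta_lag[k + 1] * (v == 3)
                k += 2
        return family_probs(p, np.asarray(eta))

    for i in range(n_subj):
        init = (int(wide["y1"][i, 0]), int(wide["y2"][i, 0]), int(wide["y3"][i, 0]))
        prob = {s: (1.0 if s == init else 0.0) for s in _STATES}
        for c, lvl in zip(CHANNELS, init):
            marg[c][i, 0, _level_index(c, lvl)] = 1.0
        for t in range(1, T):
            nxt = {s: 0.0 for s in _STATES}
            for sprev, pprev in prob.items():
                if pprev == 0.0:
                    continue
                if lag_outcome_clamp is not None:
                    prev = {c: lag_outcome_clamp[c] for c in CHANNELS}
                else:
                    prev = dict(zip(CHANNELS, sprev))
                for y3 in (1, 2, 3):
                    cur = {"y3": y3}
                    p3 = ch_probs("y3", i, t, prev, cur)[y3 - 1]
                    for y1 in (0, 1):
                        cur = {"y3": y3, "y1": y1}
                        p1 = ch_probs("y1", i, t, prev, cur)[y1]
                        for y2 in (1, 2, 3):
                            cur = {"y3": y3, "y1": y1, "y2": y2}
                            p2 = ch_probs("y2", i, t, prev, cur)[y2 - 1]
                            nxt[(y1, y2, y3)] += pprev * p3 * p1 * p2
            prob = nxt
            for (y1, y2, y3), p in prob.items():
                marg["y1"][i, t, y1] += p
                marg["y2"][i, t, y2 - 1] += p
                marg["y3"][i, t, y3 - 1] += p
    return marg


def _check_exact_size(panel: SleepPanel) -> None:
    counts = panel.df.groupby("subject_id").size()
    if counts.max() > MAX_EXACT_DAYS or panel.n_subjects > MAX_EXACT_SUBJECTS:
        raise ValueError(
            f"exact enumeration limited to <= {MAX_EXACT_SUBJECTS} subjects and "
            f"T <= {MAX_EXACT_DAYS}; got {panel.n_subjects} subjects, T = {counts.max()}"
        )


def exact_contrast(
    params: DMPMParams,
    panel: SleepPanel,
    item: CovariateSpec,
    outcome: tuple[str, int],
    channel_specs: dict[str, ChannelSpec] | None = None,
    cov_specs: list[CovariateSpec] | None = None,
) -> float:
    """Exact |dPr| for one item under fixed parameters (no Monte Carlo)."""
    outcome = _check_outcome(outcome)
    _check_exact_size(panel)
    channel_specs = channel_specs or default_channel_specs()
    cov_specs = cov_specs or default_covariate_specs()
    if item.shift_low is None or item.shift_high is None:
        raise ValueError(f"item {item.name!r} has no shift endpoints attached")
    ch, level = outcome
    i_lvl = _level_index(ch, level)
    means = []
    for v in (item.shift_low, item.shift_high):
        marg = _exact_day_marginals(params, panel, {item.name: v},
                                    channel_specs, cov_specs)
        means.append(marg[ch][:, 1:, i_lvl].mean())
    return float(abs(means[0] - means[1]))


def exact_ar1(
    params: DMPMParams,
    panel: SleepPanel,
    outcome: tuple[str, int],
    channel_specs: dict[str, ChannelSpec] | None = None,
    cov_specs: list[CovariateSpec] | None = None,
) -> float:
    """Exact counterpart of :func:`ar1_effect` under fixed parameters."""
    outcome = _check_outcome(outcome)
    _check_exact_size(panel)
    channel_specs = channel_specs or default_channel_specs()
    cov_specs = cov_specs or default_covariate_specs()
    ch, level = outcome
    i_lvl = _level_index(ch, level)
    means = []
    for clamp in (AR1_BEST, AR1_WORST):
        marg = _exact_day_marginals(params, panel, None, channel_specs, cov_specs,
                                    lag_outcome_clamp=clamp)
        means.append(marg[ch][:, 1:, i_lvl].mean())
    return float(abs(means[0] - means[1]))


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def contrast_analysis(
    draws: PosteriorDraws,
    panel: SleepPanel,
    cov_specs: list[CovariateSpec] | None = None,
    n_rep: int = 100,
    seed: int = 0,
    thin_to: int | None = 200,
    include_ar1: bool = True,
) -> ContrastResult:
    """All items, all five outcome targets, category sums and the AR(1) row.

    Shift endpoints are computed on the panel passed in (compute quartiles
    within the subsample by restricting the panel first).
    """
    cov_specs = cov_specs or default_covariate_specs()
    specs = attach_endpoints(panel, cov_specs)
    keys = [outcome_key(*o) for o in OUTCOME_TARGETS]
    per_item: dict[str, dict[str, np.ndarray]] = {k: {} for k in keys}
    for spec in specs:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            samples = _mc_item_samples(draws, panel, spec, OUTCOME_TARGETS,
                                       n_rep, seed, thin_to)
        for k in keys:
            per_item[k][spec.name] = samples[k]
    per_category: dict[str, dict[str, np.ndarray]] = {k: {} for k in keys}
    item_category = {s.name: s.category for s in specs}
    for k in keys:
        for cat in CATEGORY_ORDER:
            if cat == "ar1":
                continue
            members = {s.name: per_item[k][s.name] for s in specs if s.category == cat}
            per_category[k][cat], _ = category_effect(members)
    ar1 = {}
    if include_ar1:
        ar1_samples = _mc_ar1_samples(draws, panel, OUTCOME_TARGETS, n_rep, seed, thin_to)
        ar1 = {k: ar1_samples[k] for k in keys}
    subsample = panel.df["subsample"].iloc[0]
    return ContrastResult(
        subsample=subsample, per_item=per_item, per_category=per_category,
        ar1=ar1, item_category=item_category, seed=seed,
    )
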