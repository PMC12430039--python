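"""Dynamic multivariate panel model (DMPM) core.

Three outcome channels are modeled jointly with a temporal-ordering DAG:

* ``y1`` — daytime sleepiness, Bernoulli-logit;
* ``y2`` — ease of falling asleep (3 levels), cumulative-logit;
* ``y3`` — ease of waking up (3 levels), cumulative-logit.

Each channel regresses on lagged and same-cycle outcomes (serial auto- and
cross-correlation) plus the 35 covariates, whose per-channel lag alignment
comes from :mod:`sleepdmpm.panel_data`.  Within a waking-to-waking cycle the
generative order is ``y3 -> y1 -> y2`` (that morning's waking precedes the
day's sleepiness, which precedes the night's sleep onset), which together
with the lags makes the graph acyclic.

The module supplies the likelihood the Bayesian sampler targets and a
vectorized forward simulator that supports do-interventions: a covariate
held fixed for every subject and day, with any feedback into it severed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit

from .panel_data import COVARIATE_ORDER, CovariateSpec, SleepPanel, default_covariate_specs

__all__ = [
    "CHANNELS",
    "SIM_ORDER",
    "ChannelSpec",
    "ChannelParams",
    "DMPMParams",
    "default_channel_specs",
    "channel_prob",
    "log_likelihood",
    "simulate_forward",
]

CHANNELS = ("y1", "y2", "y3")
#: Within-cycle generative order (topological order of the lag-0 sub-DAG).
SIM_ORDER = ("y3", "y1", "y2")

N_LEVELS = {"y1": 2, "y2": 3, "y3": 3}


@dataclass(frozen=True)
class ChannelSpec:
    """One outcome channel: its response family and outcome parents.

    ``parents`` is an ordered list of ``(channel, lag)`` pairs; lag 0 means
    the same cycle (the parent must come earlier in :data:`SIM_ORDER`),
    lag 1 the previous cycle.  Ordinal parents enter the linear predictor
    as two indicator contrasts (levels 2 and 3 vs. level 1).
    """

    name: str
    family: str  # "bernoulli-logit" | "cumulative-logit-3"
    parents: tuple[tuple[str, int], ...]

    def parent_columns(self) -> list[str]:
        cols = []
        for var, lag in self.parents:
            if N_LEVELS[var] == 2:
                cols.append(f"{var}_l{lag}")
            else:
                cols.extend([f"{var}_l{lag}:2", f"{var}_l{lag}:3"])
        return cols

    @property
    def n_lag_terms(self) -> int:
        return len(self.parent_columns())


def default_channel_specs() -> dict[str, ChannelSpec]:
    """The temporal-ordering DAG over the three sleep-quality channels."""
    specs = {
        "y1": ChannelSpec("y1", "bernoulli-logit",
                          (("y1", 1), ("y2", 1), ("y3", 0))),
        "y2": ChannelSpec("y2", "cumulative-logit-3",
                          (("y2", 1), ("y3", 0), ("y1", 0))),
        "y3": ChannelSpec("y3", "cumulative-logit-3",
                          (("y3", 1), ("y1", 1), ("y2", 1))),
    }
    _assert_acyclic(specs)
    return specs


def _assert_acyclic(specs: dict[str, ChannelSpec]) -> None:
    """Lag-0 parent edges must form a DAG with a unique topological order."""
    g = nx.DiGraph()
    g.add_nodes_from(specs)
    for name, spec in specs.items():
        for var, lag in spec.parents:
            if lag == 0:
                g.add_edge(var, name)
    orders = list(nx.all_topological_sorts(g))
    if len(orders) != 1:
        raise ValueError(f"within-cycle order is not unique: {orders}")
    if tuple(orders[0]) != SIM_ORDER:
        raise ValueError(f"within-cycle order {orders[0]} != {SIM_ORDER}")


@dataclass
class ChannelParams:
    """Coefficients of one channel.

    ``beta_lag`` aligns with :meth:`ChannelSpec.parent_columns`; ``beta_x``
    aligns with :data:`~sleepdmpm.panel_data.COVARIATE_ORDER` (35 entries).
    Bernoulli channels carry an ``intercept``; cumulative channels carry two
    strictly ordered ``cutpoints`` (``P(y <= k) = logistic(c_k - eta)``).
    """

    family: str
    beta_lag: np.ndarray
    beta_x: np.ndarray
    intercept: float = 0.0
    cutpoints: tuple[float, float] | None = None

    def __post_init__(self):
        self.beta_lag = np.asarray(self.beta_lag, dtype=float)
        self.beta_x = np.asarray(self.beta_x, dtype=float)
        if self.beta_x.shape != (len(COVARIATE_ORDER),):
            raise ValueError(
                f"beta_x must have {len(COVARIATE_ORDER)} entries, got {self.beta_x.shape}"
            )
        if self.family == "cumulative-logit-3":
            if self.cutpoints is None:
                raise ValueError("cumulative channel needs cutpoints")
            c1, c2 = self.cutpoints
            if not c1 < c2:
                raise ValueError(f"cutpoints must be strictly ordered, got {self.cutpoints}")
        elif self.family != "bernoulli-logit":
            raise ValueError(f"unknown family {self.family!r}")


@dataclass
class DMPMParams:
    """Full parameter set: one :class:`ChannelParams` per channel.

    ``feedback_strength`` is the generator-only block: the coefficient with
    which the previous cycle's outcomes shift the current cycle's stress
    items (the DAG's feedback arrows).  It does not enter the likelihood.
    """

    channels: dict[str, ChannelParams]
    feedback_strength: float = 0.0

    def __post_init__(self):
        if set(self.channels) != set(CHANNELS):
            raise ValueError(f"channels must be exactly {CHANNELS}")

    def to_dict(self) -> dict:
        out: dict = {"feedback_strength": self.feedback_strength, "channels": {}}
        for name, ch in self.channels.items():
            d = {
                "family": ch.family,
                "beta_lag": ch.beta_lag.tolist(),
                "beta_x": ch.beta_x.tolist(),
            }
            if ch.family == "bernoulli-logit":
                d["intercept"] = ch.intercept
            else:
                d["cutpoints"] = list(ch.cutpoints)
            out["channels"][name] = d
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "DMPMParams":
        channels = {}
        for name, ch in d["channels"].items():
            channels[name] = ChannelParams(
                family=ch["family"],
                beta_lag=np.asarray(ch["beta_lag"]),
                beta_x=np.asarray(ch["beta_x"]),
                intercept=ch.get("intercept", 0.0),
                cutpoints=tuple(ch["cutpoints"]) if ch.get("cutpoints") else None,
            )
        return cls(channels=channels, feedback_strength=d.get("feedback_strength", 0.0))


# ---------------------------------------------------------------------------
# probability kernels
# ---------------------------------------------------------------------------

def _encode_parent(var: str, values: np.ndarray) -> list[np.ndarray]:
    """Indicator encoding of an outcome parent (binary: identity; ordinal:
    level-2 and level-3 dummies vs. level 1)."""
    values = np.asarray(values, dtype=float)
    if N_LEVELS[var] == 2:
        return [values]
    return [(values == 2).astype(float), (values == 3).astype(float)]


def family_probs(params: ChannelParams, eta: np.ndarray) -> np.ndarray:
    """Level probabilities given the linear predictor, stacked on the last axis."""
    eta = np.asarray(eta, dtype=float)
    if params.family == "bernoulli-logit":
        p = expit(params.intercept + eta)
        return np.stack([1.0 - p, p], axis=-1)
    c1, c2 = params.cutpoints
    q1 = expit(c1 - eta)
    q2 = expit(c2 - eta)
    return np.stack([q1, q2 - q1, 1.0 - q2], axis=-1)


def channel_prob(
    spec: ChannelSpec,
    params: DMPMParams,
    parent_values: dict[tuple[str, int], float],
    covariates,
) -> np.ndarray:
    """Probability vector over the channel's levels for one observation.

    ``parent_values`` maps each ``(channel, lag)`` parent to its value;
    ``covariates`` is the 35-vector of channel-aligned covariate values
    (the caller applies the per-channel lag when extracting them).
    """
    ch = params.channels[spec.name]
    z: list[float] = []
    for var, lag in spec.parents:
        if (var, lag) not in parent_values:
            raise KeyError(f"missing parent value for {(var, lag)}")
        z.extend(e for e in np.ravel(_encode_parent(var, np.asarray(parent_values[(var, lag)]))))
    x = np.asarray(covariates, dtype=float)
    eta = float(np.dot(ch.beta_lag, z) + np.dot(ch.beta_x, x))
    return family_probs(ch, np.asarray(eta))


# ---------------------------------------------------------------------------
# design matrices and likelihood
# ---------------------------------------------------------------------------

def build_design(
    panel: SleepPanel,
    channel: str,
    channel_specs: dict[str, ChannelSpec] | None = None,
    cov_specs: list[CovariateSpec] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix for one channel over all rows with t >= 2.

    Returns ``(X, y, column_names)`` where the columns are the channel's
    lag-parent indicators followed by the 35 covariates, each covariate
    shifted by its channel-specific lag.  Day-1 rows serve as the initial
    condition and contribute regressors only.
    """
    channel_specs = channel_specs or default_channel_specs()
    cov_specs = cov_specs or default_covariate_specs()
    spec = channel_specs[channel]
    df = panel.df.sort_values(["subject_id", "day"], kind="stable")
    grp = df.groupby("subject_id", sort=False)

    cols: list[np.ndarray] = []
    names: list[str] = []
    for var, lag in spec.parents:
        vals = grp[var].shift(lag).to_numpy() if lag else df[var].to_numpy()
        for enc, suffix in zip(
            _encode_parent(var, vals),
            ([""] if N_LEVELS[var] == 2 else [":2", ":3"]),
        ):
            cols.append(enc)
            names.append(f"{var}_l{lag}{suffix}")
    by_name = {s.name: s for s in cov_specs}
    for cov in COVARIATE_ORDER:
        lag = by_name[cov].lag(channel)
        vals = grp[cov].shift(lag).to_numpy() if lag else df[cov].to_numpy()
        cols.append(np.asarray(vals, dtype=float))
        names.append(cov)

    keep = (df["day"] >= 2).to_numpy()
    X = np.column_stack(cols)[keep]
    y = df[channel].to_numpy(dtype=float)[keep]
    if np.isnan(X).any():
        raise ValueError("design matrix contains NaN (lagged value outside panel?)")
    return X, y, names


def _row_log_probs(ch: ChannelParams, eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    probs = family_probs(ch, eta)
    if ch.family == "bernoulli-logit":
        idx = y.astype(int)
    else:
        idx = y.astype(int) - 1
    p = np.take_along_axis(probs, idx[:, None], axis=-1)[:, 0]
    with np.errstate(divide="ignore"):
        return np.log(p)


def log_likelihood(
    params: DMPMParams,
    panel: SleepPanel,
    channel_specs: dict[str, ChannelSpec] | None = None,
    cov_specs: list[CovariateSpec] | None = None,
) -> float:
    """Joint log likelihood over subjects, days t = 2..T and channels.

    Day 1 is the initial condition and is conditioned on, not modeled.
    A zero-probability observation under degenerate parameters yields
    ``-inf`` with a warning.
    """
    channel_specs = channel_specs or default_channel_specs()
    cov_specs = cov_specs or default_covariate_specs()
    total = 0.0
    for name in CHANNELS:
        X, y, _ = build_design(panel, name, channel_specs, cov_specs)
        ch = params.channels[name]
        n_lag = channel_specs[name].n_lag_terms
        eta = X[:, :n_lag] @ ch.beta_lag + X[:, n_lag:] @ ch.beta_x
        lp = _row_log_probs(ch, eta, y)
        if np.isneginf(lp).any():
            warnings.warn(
                f"channel {name}: zero-probability observation; log likelihood is -inf",
                stacklevel=2,
            )
            return -np.inf
        total += float(lp.sum())
    return total


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def _covariate_contributions(
    params: DMPMParams,
    covariate_path: dict[str, np.ndarray],
    cov_specs: list[CovariateSpec],
    policy: dict[str, float] | None,
) -> dict[str, np.ndarray]:
    """Per-channel (n_subjects, T) covariate parts of the linear predictor.

    Column t (0-based) is valid for cycles t >= 1; under a do-policy the
    named covariates are fixed at their assigned value for every subject
    and day, which also severs any feedback into them.
    """
    policy = policy or {}
    some = next(iter(covariate_path.values()))
    n_subj, T = some.shape
    by_name = {s.name: s for s in cov_specs}
    contrib = {c: np.zeros((n_subj, T)) for c in CHANNELS}
    for j, cov in enumerate(COVARIATE_ORDER):
        if cov in policy:
            x = np.full((n_subj, T), float(policy[cov]))
        else:
            x = np.asarray(covariate_path[cov], dtype=float)
        for c in CHANNELS:
            beta = params.channels[c].beta_x[j]
            if beta == 0.0:
                continue
            lag = by_name[cov].lag(c)
            shifted = np.empty_like(x)
            if lag:
                shifted[:, 1:] = x[:, :-1]
                shifted[:, 0] = np.nan
            else:
                shifted[:] = x
            contrib[c][:, 1:] += beta * shifted[:, 1:]
    return contrib


def _lag_eta(
    spec: ChannelSpec,
    ch: ChannelParams,
    prev: dict[str, np.ndarray],
    cur: dict[str, np.ndarray],
) -> np.ndarray:
    eta = 0.0
    k = 0
    for var, lag in spec.parents:
        vals = prev[var] if lag else cur[var]
        for enc in _encode_parent(var, vals):
            eta = eta + ch.beta_lag[k] * enc
            k += 1
    return eta


def _draw_level(
    rng: np.random.Generator, ch: ChannelParams, eta: np.ndarray
) -> np.ndarray:
    u = rng.random(eta.shape)
    if ch.family == "bernoulli-logit":
        return (u < expit(ch.intercept + eta)).astype(float)
    c1, c2 = ch.cutpoints
    q1 = expit(c1 - eta)
    q2 = expit(c2 - eta)
    return np.where(u < q1, 1.0, np.where(u < q2, 2.0, 3.0))


def simulate_forward(
    params: DMPMParams,
    initial_day: np.ndarray,
    covariate_path: dict[str, np.ndarray],
    policy: dict[str, float] | None = None,
    n_rep: int = 1000,
    seed: int = 0,
    lag_outcome_clamp: dict[str, float] | None = None,
    channel_specs: dict[str, ChannelSpec] | None = None,
    cov_specs: list[CovariateSpec] | None = None,
) -> dict[str, np.ndarray]:
    """Monte-Carlo forward simulation of cycles t = 2..T.

    Parameters
    ----------
    initial_day
        ``(n_subjects, 3)`` observed day-1 outcomes ``(y1, y2, y3)``.
    covariate_path
        Map covariate name -> ``(n_subjects, T)`` observed values.
    policy
        do-intervention: each named covariate is held at the given value
        for every subject and day (its incoming arrows are severed).
    lag_outcome_clamp
        If given, the lag-1 outcome values entering every channel are
        replaced by these values (used for the AR(1) contrast); same-cycle
        parents remain simulated.
    n_rep
        Replicates per subject.

    Returns
    -------
    dict
        Channel -> ``(T, n_levels)`` array of outcome-level frequencies,
        averaged over subjects and replicates.  Row 0 is the empirical
        distribution of the observed initial day.
    """
    if n_rep <= 0:
        raise ValueError(f"n_rep must be positive, got {n_rep}")
    channel_specs = channel_specs or default_channel_specs()
    cov_specs = cov_specs or default_covariate_specs()
    for cov in COVARIATE_ORDER:
        if cov not in covariate_path:
            raise KeyError(f"covariate path missing {cov!r}")
    if policy:
        unknown = set(policy) - set(COVARIATE_ORDER)
        if unknown:
            raise KeyError(f"policy names unknown covariates: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    initial_day = np.asarray(initial_day, dtype=float)
    n_subj, T = next(iter(covariate_path.values())).shape
    contrib = _covariate_contributions(params, covariate_path, cov_specs, policy)

    state = {
        c: np.repeat(initial_day[:, i][:, None], n_rep, axis=1)
        for i, c in enumerate(CHANNELS)
    }
    freqs = {c: np.zeros((T, N_LEVELS[c])) for c in CHANNELS}
    for i, c in enumerate(CHANNELS):
        levels = np.arange(N_LEVELS[c]) + (0 if c == "y1" else 1)
        freqs[c][0] = (initial_day[:, i][:, None] == levels).mean(axis=0)

    for t in range(1, T):
        if lag_outcome_clamp is not None:
            prev = {
                c: np.full((n_subj, n_rep), float(lag_outcome_clamp[c]))
                for c in CHANNELS
            }
        else:
            prev = state
        cur: dict[str, np.ndarray] = {}
        for c in SIM_ORDER:
            ch = params.channels[c]
            eta = contrib[c][:, t][:, None] + _lag_eta(channel_specs[c], ch, prev, cur)
            cur[c] = _draw_level(rng, ch, eta)
        state = cur
        for c in CHANNELS:
            levels = np.arange(N_LEVELS[c]) + (0 if c == "y1" else 1)
            freqs[c][t] = (state[c][:, :, None] == levels).mean(axis=(0, 1))
    return freqs
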