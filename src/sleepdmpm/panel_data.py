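"""Sleep-diary panel data model.

A :class:`SleepPanel` is a long-format table of subject-day records from a
sleep diary: three sleep-quality outcomes per day (binary daytime sleepiness
``y1``; 3-level ease of falling asleep ``y2``; 3-level ease of waking up
``y3``) together with 16 time-varying and 19 time-invariant covariates
grouped into six factor categories (stress, bedtime conditions, weather,
physical attributes, exercise habits, dietary habits).  Day ``t`` indexes a
waking-to-waking cycle, not a calendar day.

This module also implements the variable constructions used upstream of the
model — bedtime clock times re-expressed as signed hours relative to
midnight, monthly exercise amounts collapsed to participation dummies,
dietary intakes standardized per 1000 kcal — and the interquartile shift
endpoints that define the "improvement width" of the do-intervention
contrasts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORY_SIZES",
    "COVARIATE_ORDER",
    "BINARY_COVARIATES",
    "SUBSAMPLES",
    "CovariateSpec",
    "SleepPanel",
    "PanelSchemaError",
    "PanelValidationError",
    "DegenerateIQRError",
    "default_covariate_specs",
    "load_panel",
    "write_panel",
    "bedtime_to_relative_hours",
    "exercise_dummy",
    "standardize_diet",
    "compute_shift_endpoints",
]

#: Factor categories in report order, with their fixed item counts.
CATEGORY_SIZES = {
    "stress": 6,
    "bedtime": 5,
    "weather": 5,
    "physical": 3,
    "exercise": 4,
    "dietary": 12,
}

#: Canonical order of the 35 covariates; model coefficient vectors align to it.
COVARIATE_ORDER = (
    "stress1", "stress2", "stress3", "stress4", "stress5", "stress6",
    "bedtime_hr", "time_in_bed_hr", "caffeine", "alcohol", "ict",
    "precip_mm", "temp_mean", "temp_range", "wind_mean", "sunshine_hr",
    "age", "bmi", "sbp",
    "exercise1", "exercise2", "exercise3", "exercise4",
    "diet1", "diet2", "diet3", "diet4", "diet5", "diet6",
    "diet7", "diet8", "diet9", "diet10", "diet11", "diet12",
)

BINARY_COVARIATES = frozenset(
    {"caffeine", "alcohol", "ict", "exercise1", "exercise2", "exercise3", "exercise4"}
)

SUBSAMPLES = ("male-summer", "male-winter", "female-summer", "female-winter")

OUTCOME_COLUMNS = ("y1", "y2", "y3")
MAX_DAYS = 6


class PanelSchemaError(ValueError):
    """A required column is missing or mistyped in a panel file."""


class PanelValidationError(ValueError):
    """Panel contents violate a data-model invariant."""


class DegenerateIQRError(ValueError):
    """A non-binary covariate has zero interquartile range."""


@dataclass(frozen=True)
class CovariateSpec:
    """Metadata for one covariate of the panel.

    Parameters
    ----------
    name
        Column name in the panel.
    category
        One of the six factor categories.
    time_varying
        Whether the covariate changes day to day within a subject.
    lag_by_channel
        Per-channel lag (0 = same cycle, 1 = previous cycle) used when a
        channel's linear predictor is assembled.  Irrelevant (all zero) for
        time-invariant covariates.
    override
        If set, intervention endpoints are fixed to (0, 1) regardless of the
        sample IQR — the rule used for the pre-bed caffeine dummy, whose
        sample mean below 0.25 makes its interquartile range collapse to 0.
    """

    name: str
    category: str
    time_varying: bool
    lag_by_channel: dict[str, int] = field(default_factory=dict)
    override: bool = False
    shift_low: float | None = None
    shift_high: float | None = None

    def lag(self, channel: str) -> int:
        if not self.time_varying:
            return 0
        return self.lag_by_channel.get(channel, 0)

    def with_endpoints(self, low: float, high: float) -> "CovariateSpec":
        return replace(self, shift_low=low, shift_high=high)


# Lag conventions for the three time-varying categories, chosen to respect
# the waking-to-waking cycle: the night's bedtime conditions and the weather
# on the evening of going to bed precede that cycle's waking (lag 0 for y3)
# but are recorded one row before the following day's sleepiness and sleep
# onset (lag 1 for y1, y2).  Stress is reported during the cycle itself
# (lag 0 for y1, y2) and reaches the next morning's waking with lag 1.
_LAGS_NIGHT = {"y1": 1, "y2": 1, "y3": 0}
_LAGS_DAY = {"y1": 0, "y2": 0, "y3": 1}


def default_covariate_specs() -> list[CovariateSpec]:
    """Build the canonical 35-covariate specification.

    Category sizes are fixed at 6 stress / 5 bedtime / 5 weather /
    3 physical / 4 exercise / 12 dietary items.
    """
    specs: list[CovariateSpec] = []
    for name in COVARIATE_ORDER:
        if name.startswith("stress"):
            specs.append(CovariateSpec(name, "stress", True, dict(_LAGS_DAY)))
        elif name in ("bedtime_hr", "time_in_bed_hr", "caffeine", "alcohol", "ict"):
            specs.append(
                CovariateSpec(
                    name, "bedtime", True, dict(_LAGS_NIGHT),
                    override=(name == "caffeine"),
                )
            )
        elif name in ("precip_mm", "temp_mean", "temp_range", "wind_mean", "sunshine_hr"):
            specs.append(CovariateSpec(name, "weather", True, dict(_LAGS_NIGHT)))
        elif name in ("age", "bmi", "sbp"):
            specs.append(CovariateSpec(name, "physical", False))
        elif name.startswith("exercise"):
            specs.append(CovariateSpec(name, "exercise", False))
        else:
            specs.append(CovariateSpec(name, "dietary", False))
    counts: dict[str, int] = {}
    for s in specs:
        counts[s.category] = counts.get(s.category, 0) + 1
    assert counts == CATEGORY_SIZES
    return specs


@dataclass
class SleepPanel:
    """Validated long-format panel of sleep-diary records.

    Wraps a :class:`pandas.DataFrame` with one row per (subject, day) and
    columns ``subject_id, day, y1, y2, y3, <35 covariates>, subsample``.
    Construction validates every data-model invariant; use
    :meth:`from_frame` rather than mutating ``df`` in place.
    """

    df: pd.DataFrame

    REQUIRED = ("subject_id", "day") + OUTCOME_COLUMNS + COVARIATE_ORDER + ("subsample",)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SleepPanel":
        missing = [c for c in cls.REQUIRED if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"missing columns: {missing}")
        df = df.loc[:, list(cls.REQUIRED)].copy()
        df["day"] = df["day"].astype(int)
        panel = cls(df.reset_index(drop=True))
        panel._validate()
        return panel

    # -- invariants ------------------------------------------------------

    def _validate(self) -> None:
        df = self.df
        if df.duplicated(["subject_id", "day"]).any():
            bad = df[df.duplicated(["subject_id", "day"])]
            raise PanelValidationError(
                f"duplicated (subject, day) rows: {bad[['subject_id', 'day']].values.tolist()}"
            )
        bad_y1 = ~df["y1"].isin([0, 1])
        if bad_y1.any():
            raise PanelValidationError(
                f"y1 outside {{0,1}} at rows {list(df.index[bad_y1])}"
            )
        for col in ("y2", "y3"):
            bad = ~df[col].isin([1, 2, 3])
            if bad.any():
                raise PanelValidationError(
                    f"{col} outside {{1,2,3}} at rows {list(df.index[bad])}"
                )
        bad_sub = ~df["subsample"].isin(SUBSAMPLES)
        if bad_sub.any():
            raise PanelValidationError(
                f"unknown subsample labels: {sorted(df.loc[bad_sub, 'subsample'].unique())}"
            )
        ti_cols = [c for c in COVARIATE_ORDER if c in
                   ("age", "bmi", "sbp") or c.startswith(("exercise", "diet"))]
        for sid, grp in df.groupby("subject_id", sort=False):
            days = np.sort(grp["day"].to_numpy())
            if days[0] != 1 or not np.array_equal(days, np.arange(1, len(days) + 1)):
                raise PanelValidationError(
                    f"subject {sid!r}: days {days.tolist()} are not consecutive from 1"
                )
            if len(days) > MAX_DAYS:
                raise PanelValidationError(
                    f"subject {sid!r}: {len(days)} days exceeds the {MAX_DAYS}-day diary"
                )
            if grp[list(ti_cols)].nunique().gt(1).any():
                varying = grp[list(ti_cols)].nunique()
                raise PanelValidationError(
                    f"subject {sid!r}: time-invariant covariates vary: "
                    f"{list(varying.index[varying > 1])}"
                )

    # -- accessors -------------------------------------------------------

    @property
    def subjects(self) -> list:
        return list(dict.fromkeys(self.df["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    def n_days(self, subject) -> int:
        return int((self.df["subject_id"] == subject).sum())

    def subsample_of(self, subject) -> str:
        return self.df.loc[self.df["subject_id"] == subject, "subsample"].iloc[0]

    def restrict(self, subsample: str) -> "SleepPanel":
        if subsample not in SUBSAMPLES:
            raise ValueError(f"unknown subsample {subsample!r}")
        sub = self.df[self.df["subsample"] == subsample]
        if sub.empty:
            raise PanelValidationError(f"no rows for subsample {subsample!r}")
        return SleepPanel.from_frame(sub)

    def wide_arrays(self) -> dict[str, np.ndarray]:
        """Pivot to (n_subjects, T) arrays for outcomes and covariates.

        Requires a balanced panel (same T for every subject); the synthetic
        generator and the forward simulator both work on this layout.
        """
        counts = self.df.groupby("subject_id", sort=False).size()
        if counts.nunique() != 1:
            raise PanelValidationError(
                "balanced panel required: subjects have differing day counts "
                f"{sorted(counts.unique())}"
            )
        T = int(counts.iloc[0])
        df = self.df.sort_values(["subject_id", "day"], kind="stable")
        n = self.n_subjects
        out = {}
        for col in OUTCOME_COLUMNS + COVARIATE_ORDER:
            out[col] = df[col].to_numpy(dtype=float).reshape(n, T)
        out["subject_id"] = np.asarray(self.subjects, dtype=object)
        return out


def load_panel(path, specs: list[CovariateSpec] | None = None) -> SleepPanel:
    """Read a panel CSV and return a validated :class:`SleepPanel`.

    Rows with missing values are handled complete-case: each subject keeps
    only its maximal leading run of complete consecutive days.  Gaps already
    present in the file (not caused by missingness) raise
    :class:`PanelValidationError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in SleepPanel.REQUIRED if c not in df.columns]
    if missing:
        raise PanelSchemaError(f"{path}: missing columns {missing}")
    incomplete = df[list(SleepPanel.REQUIRED)].isna().any(axis=1)
    if incomplete.any():
        df = df[~incomplete]
        kept = []
        for sid, grp in df.groupby("subject_id", sort=False):
            grp = grp.sort_values("day")
            days = grp["day"].to_numpy()
            run = 0
            while run < len(days) and days[run] == run + 1:
                run += 1
            kept.append(grp.iloc[:run])
        df = pd.concat(kept, ignore_index=True) if kept else df.iloc[:0]
    return SleepPanel.from_frame(df)


def write_panel(panel: SleepPanel, path) -> None:
    """Write the panel to CSV (UTF-8, comma separator, header row)."""
    panel.df.to_csv(path, index=False)


_CLOCK_RE = re.compile(r"^\s*(\d{1,2}):([0-5]\d)\s*$")


def bedtime_to_relative_hours(clock: str) -> float:
    """Convert an HH:MM bedtime to signed hours relative to midnight (24:00).

    Hours after midnight are positive, before midnight negative, so a later
    bedtime is a larger value.  Accepts the 24h-extended evening range
    (``"25:30"`` is 1:30 a.m.) and plain early-morning times up to 6:00.
    """
    m = _CLOCK_RE.match(str(clock))
    if not m:
        raise ValueError(f"unparseable clock time {clock!r}; expected HH:MM")
    hh, mm = int(m.group(1)), int(m.group(2))
    if hh <= 6:
        hh += 24
    if not 18 <= hh <= 30:
        raise ValueError(f"bedtime {clock!r} outside the evening window 18:00-30:00")
    return hh + mm / 60.0 - 24.0


def exercise_dummy(monthly_hours: float) -> int:
    """Collapse a monthly activity amount to a participation dummy.

    Monthly exercise amounts are strongly right-skewed with median 0, so
    the model uses 1 iff the amount is strictly greater than zero.
    """
    if not np.isfinite(monthly_hours) or monthly_hours < 0:
        raise ValueError(f"monthly activity must be finite and >= 0, got {monthly_hours}")
    return int(monthly_hours > 0)


def standardize_diet(intake_g_per_day: float, energy_kcal_per_day: float) -> float:
    """Standardize a food-group intake per 1000 kcal of daily energy."""
    if intake_g_per_day < 0:
        raise ValueError(f"intake must be >= 0, got {intake_g_per_day}")
    if not energy_kcal_per_day > 0:
        raise ValueError(f"daily energy must be > 0, got {energy_kcal_per_day}")
    return intake_g_per_day / energy_kcal_per_day * 1000.0


def compute_shift_endpoints(
    values, override: bool = False
) -> tuple[float, float]:
    """Return the (first quartile, third quartile) intervention endpoints.

    Quartiles use linear interpolation between order statistics (type 7).
    With ``override`` set, or when a binary covariate's IQR degenerates to
    zero, the endpoints are (0, 1) — the full improvement width of a dummy.
    A zero IQR on a non-binary covariate raises :class:`DegenerateIQRError`;
    callers are expected to skip such items with a warning.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("all values missing")
    if v.size < 4:
        raise ValueError(f"need >= 4 non-missing values, got {v.size}")
    if override:
        return (0.0, 1.0)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    binary = np.isin(v, (0.0, 1.0)).all()
    if q1 == q3:
        if binary:
            return (0.0, 1.0)
        raise DegenerateIQRError(
            f"zero interquartile range on a non-binary covariate (Q1=Q3={q1})"
        )
    return (float(q1), float(q3))


def attach_endpoints(
    panel: SleepPanel, specs: list[CovariateSpec]
) -> list[CovariateSpec]:
    """Compute shift endpoints for every covariate on this panel.

    Quartiles are computed within the panel passed in (one subsample when
    the caller has already restricted it).  Items with a degenerate IQR on
    a non-binary covariate keep ``shift_low = shift_high`` and are skipped
    downstream with a warning.
    """
    out = []
    for spec in specs:
        vals = panel.df[spec.name].to_numpy(dtype=float)
        try:
            low, high = compute_shift_endpoints(vals, override=spec.override)
        except DegenerateIQRError:
            warnings.warn(
                f"covariate {spec.name!r} has a degenerate IQR; its contrast "
                "will be reported as zero",
                stacklevel=2,
            )
            low = high = float(vals[0])
        out.append(spec.with_endpoints(low, high))
    return out
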