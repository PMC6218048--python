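"""Clinical table handling: lateral motor scores, side assignment, adjusted disease duration.

The clinical quantities used throughout the package are the ones relevant to
lateralized parkinsonism:

* ``DD`` — disease duration in years since symptom onset.
* ``aDD`` — adjusted disease duration.  Mean presynaptic tracer binding decays
  approximately exponentially with DD, so DD is linearized through
  ``exp(rate * DD)`` (rate < 0) and then affinely renormalized so that the
  adjusted value increases with progression and spans the same range as DD.
* ``LMS`` — lateral motor score, the sum of seven lateralized MDS-UPDRS III
  limb items (leg rigidity, toe tapping, leg agility, arm rigidity, finger
  tapping, hand movements, pronation/supination).  Tremor items are excluded
  because tremor correlates poorly with dopaminergic deficit.
* better / worse body side — the side with the lower / higher lateralized
  motor total; the *brain* hemisphere contralateral to the worse body side is
  the "worse" hemisphere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import FitError, FormatError, ValidationError

#: The seven lateralized MDS-UPDRS III items that enter the lateral motor score.
LATERAL_ITEMS: tuple[str, ...] = (
    "leg_rigidity",
    "toe_tapping",
    "leg_agility",
    "arm_rigidity",
    "finger_tapping",
    "hand_movements",
    "pronation_supination",
)

BODY_SIDES = ("left", "right")

#: Columns that must be present in any clinical CSV.
MANDATORY_COLUMNS = ("subject_id", "group", "DD")

#: Optional covariate / metadata columns recognized by the reader.
OPTIONAL_COLUMNS = (
    "age",
    "AgLED",
    "agonist_status",
    "sex",
    "worse_body_side",
    "LMS_better",
    "LMS_worse",
)


@dataclass(frozen=True)
class ADDParams:
    """Parameters of the disease-duration adjustment.

    ``rate`` is the per-year exponential coefficient obtained from fitting the
    mean binding ratio against disease duration (default −0.17 / year);
    ``renorm_min``/``renorm_max`` bound the affine renormalization (defaults
    0 and 16 years, the observed DD range).
    """

    rate: float = -0.17
    renorm_min: float = 0.0
    renorm_max: float = 16.0

    def __post_init__(self) -> None:
        if not self.rate < 0:
            raise ValidationError(f"aDD rate must be negative, got {self.rate}")
        if not self.renorm_max > self.renorm_min:
            raise ValidationError(
                f"renorm_max ({self.renorm_max}) must exceed renorm_min ({self.renorm_min})"
            )


def compute_add(dd, params: ADDParams = ADDParams()):
    """Adjusted disease duration.

    ``raw = exp(rate * DD)`` is decreasing in DD; the affine renormalization
    fixed by the two endpoints maps it onto an increasing function with
    ``aDD(renorm_min) = renorm_min`` and ``aDD(renorm_max) = renorm_max``:

    ``aDD = min + (max - min) * (exp(rate*min) - exp(rate*DD)) / (exp(rate*min) - exp(rate*max))``

    Scalar in, scalar out; array in, array out.  Values of DD above
    ``renorm_max`` are computed by the same formula with a warning.
    """
    dd_arr = np.asarray(dd, dtype=float)
    if np.any(dd_arr < 0):
        raise ValidationError("DD must be nonnegative")
    if np.any(dd_arr > params.renorm_max):
        warnings.warn(
            f"DD exceeds renorm_max={params.renorm_max}; aDD extrapolated by the same formula",
            stacklevel=2,
        )
    lo = np.exp(params.rate * params.renorm_min)
    hi = np.exp(params.rate * params.renorm_max)
    span = params.renorm_max - params.renorm_min
    add = params.renorm_min + span * (lo - np.exp(params.rate * dd_arr)) / (lo - hi)
    return add if add.ndim else float(add)


def compute_lms(items: Mapping[str, int] | Sequence[int]) -> int:
    """Lateral motor score for one body side: integer sum of the seven items.

    ``items`` is either a mapping with the :data:`LATERAL_ITEMS` keys or a
    sequence of seven values; each item must be an integer in 0..4.
    """
    if isinstance(items, Mapping):
        missing = [k for k in LATERAL_ITEMS if k not in items]
        if missing:
            raise ValidationError(f"missing lateral motor items: {missing}")
        values = [items[k] for k in LATERAL_ITEMS]
    else:
        values = list(items)
        if len(values) != len(LATERAL_ITEMS):
            raise ValidationError(
                f"expected {len(LATERAL_ITEMS)} item scores, got {len(values)}"
            )
    total = 0
    for v in values:
        iv = int(v)
        if iv != v or not 0 <= iv <= 4:
            raise ValidationError(f"item score {v!r} outside the integer range 0-4")
        total += iv
    return total


def assign_sides(left_lateral_total: float, right_lateral_total: float) -> str:
    """Return the worse (more affected) *body* side given lateralized totals.

    Ties default to the right body side with a warning — the choice only needs
    to be deterministic and visible.
    """
    if left_lateral_total < 0 or right_lateral_total < 0:
        raise ValidationError("lateral totals must be nonnegative")
    if left_lateral_total == right_lateral_total:
        warnings.warn(
            "lateral motor totals tied; defaulting worse body side to 'right'",
            stacklevel=2,
        )
        return "right"
    return "left" if left_lateral_total > right_lateral_total else "right"


@dataclass(frozen=True)
class ExponentialFit:
    """Result of fitting BR = amplitude * exp(rate * DD)."""

    rate: float
    amplitude: float
    rate_stderr: float
    residual_rms: float


def fit_add_rate(mean_br: Sequence[float], dd: Sequence[float]) -> ExponentialFit:
    """Fit ``BR = a * exp(b * DD)`` by least squares and return the fit.

    This is how the adjustment rate is obtained from data: the mean binding
    ratio in a degenerating structure decays roughly exponentially with
    disease duration, and ``b`` becomes :attr:`ADDParams.rate`.
    """
    br_arr = np.asarray(mean_br, dtype=float)
    dd_arr = np.asarray(dd, dtype=float)
    if br_arr.shape != dd_arr.shape or br_arr.ndim != 1:
        raise ValidationError("mean_br and dd must be 1-D arrays of equal length")
    if br_arr.size < 3:
        raise ValidationError("need at least 3 subjects for an exponential fit")
    if np.any(br_arr <= 0):
        raise ValidationError("mean BR values must be positive")

    # log-linear start values; exact when the data are noiseless exponential
    slope, intercept = np.polyfit(dd_arr, np.log(br_arr), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, pcov = curve_fit(
            lambda d, a, b: a * np.exp(b * d), dd_arr, br_arr, p0=p0, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - exercised via FitError path
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    a_hat, b_hat = float(popt[0]), float(popt[1])
    resid = br_arr - a_hat * np.exp(b_hat * dd_arr)
    stderr = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("inf")
    return ExponentialFit(
        rate=b_hat,
        amplitude=a_hat,
        rate_stderr=stderr,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def item_column(item: str, body_side: str) -> str:
    """CSV column name for one lateralized item, e.g. ``leg_rigidity_left``."""
    return f"{item}_{body_side}"


class ClinicalTable:
    """Typed, validated per-subject clinical table.

    Wraps a :class:`pandas.DataFrame` with one row per subject.  Derived
    columns (``aDD``, lateral totals, ``worse_body_side``, ``LMS_better``,
    ``LMS_worse``) are filled in when the source columns allow it.
    ``absent_covariates`` records optional covariates that the source lacked.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        add_params: ADDParams = ADDParams(),
        side_items: Iterable[str] = LATERAL_ITEMS,
    ):
        df = df.copy()
        for col in MANDATORY_COLUMNS:
            if col not in df.columns:
                raise FormatError(f"clinical table missing mandatory column {col!r}")
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id values")
        bad_group = set(df["group"].unique()) - {"HC", "PD"}
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        if (df["DD"] < 0).any():
            raise ValidationError("DD must be nonnegative")

        self.side_items = tuple(side_items)
        self._validate_items(df)
        self.absent_covariates = tuple(
            c for c in OPTIONAL_COLUMNS if c not in df.columns
        )
        self.add_params = add_params

        df["aDD"] = compute_add(df["DD"].to_numpy(), add_params)
        self._derive_lateral(df)
        self.df = df.reset_index(drop=True)

    def _validate_items(self, df: pd.DataFrame) -> None:
        for item in LATERAL_ITEMS:
            for side in BODY_SIDES:
                col = item_column(item, side)
                if col in df.columns:
                    vals = df[col]
                    if ((vals < 0) | (vals > 4) | (vals != vals.astype(int))).any():
                        raise ValidationError(
                            f"column {col!r} has item scores outside the integer range 0-4"
                        )

    def _derive_lateral(self, df: pd.DataFrame) -> None:
        have_items = all(
            item_column(i, s) in df.columns for i in LATERAL_ITEMS for s in BODY_SIDES
        )
        if have_items:
            totals = {}
            for side in BODY_SIDES:
                cols = [item_column(i, side) for i in self.side_items
                        if item_column(i, side) in df.columns]
                totals[side] = df[cols].sum(axis=1)
                df[f"lateral_total_{side}"] = totals[side]
            if "worse_body_side" not in df.columns:
                df["worse_body_side"] = [
                    assign_sides(lt, rt)
                    for lt, rt in zip(totals["left"], totals["right"])
                ]
            lms = {
                side: df[[item_column(i, side) for i in LATERAL_ITEMS]].sum(axis=1)
                for side in BODY_SIDES
            }
            if "LMS_worse" not in df.columns:
                df["LMS_worse"] = [
                    lms[w].iloc[n] for n, w in enumerate(df["worse_body_side"])
                ]
            if "LMS_better" not in df.columns:
                df["LMS_better"] = [
                    lms["left" if w == "right" else "right"].iloc[n]
                    for n, w in enumerate(df["worse_body_side"])
                ]

    # -- convenience accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.df["subject_id"].astype(str))

    def has_covariate(self, name: str) -> bool:
        return name in self.df.columns

    def column(self, name: str) -> np.ndarray:
        if name not in self.df.columns:
            raise ValidationError(f"clinical table has no column {name!r}")
        return self.df[name].to_numpy()

    def worse_body_side(self, subject_id: str) -> str:
        row = self.df[self.df["subject_id"].astype(str) == str(subject_id)]
        if row.empty:
            raise ValidationError(f"no clinical row for subject {subject_id!r}")
        if "worse_body_side" not in row.columns or row["worse_body_side"].isna().any():
            raise ValidationError(f"worse_body_side unavailable for {subject_id!r}")
        return str(row["worse_body_side"].iloc[0])

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def read_clinical_table(
    path, add_params: ADDParams = ADDParams(), side_items: Iterable[str] = LATERAL_ITEMS
) -> ClinicalTable:
    """Read and validate a clinical CSV (see :class:`ClinicalTable` for schema)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise FormatError(f"could not parse clinical CSV {path}: {exc}") from exc
    return ClinicalTable(df, add_params=add_params, side_items=side_items)
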