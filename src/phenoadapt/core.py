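"""Trial data model, CSV I/O, validation, and deterministic splitting.

A :class:`TrialDataset` is the universal currency between all pipeline
stages: one row per participant carrying mixed-type baseline covariates,
the randomized arm, calendar accrual time, the right-censored primary
outcome, and an optional ordered hierarchy of safety outcomes (position 0
is the highest-priority tier, conventionally all-cause mortality).

File dialect is fixed so that round-trips are bit-exact: comma-separated,
UTF-8, "." decimal, and the literal token ``NA`` for missing covariate
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ARM_INTERVENTION = "intervention"
ARM_CONTROL = "control"
ARMS = (ARM_INTERVENTION, ARM_CONTROL)

#: literal token written for missing covariate cells
NA_TOKEN = "NA"

#: reserved (non-covariate) column names, in file order
RESERVED_COLUMNS = ("id", "arm", "accrual_time", "primary_time", "primary_event")

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"
KINDS = (CONTINUOUS, BINARY, CATEGORICAL)


class SchemaError(ValueError):
    """A file or frame does not match the declared covariate schema."""


class ValidationError(ValueError):
    """A dataset violates a structural invariant."""


@dataclass(frozen=True)
class Covariate:
    """One baseline feature: a name, a kind, and (categorical only) levels."""

    name: str
    kind: str
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise SchemaError(f"unknown covariate kind {self.kind!r}")
        if self.kind == CATEGORICAL and len(self.levels) < 2:
            raise SchemaError(f"categorical {self.name!r} needs >=2 levels")
        if self.kind != CATEGORICAL and self.levels:
            raise SchemaError(f"{self.kind} covariate {self.name!r} has levels")


def _check_schema(schema: tuple[Covariate, ...]) -> None:
    names = [c.name for c in schema]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate covariate names in schema")
    reserved = set(RESERVED_COLUMNS)
    for c in schema:
        if c.name in reserved or c.name.startswith("safety_"):
            raise SchemaError(f"covariate name {c.name!r} clashes with a reserved column")


@dataclass
class TrialDataset:
    """Participant-level two-arm trial table plus covariate type metadata.

    ``table`` holds one row per participant with the reserved columns
    (id, arm, accrual_time, primary_time, primary_event), then
    ``safety_<k>_time`` / ``safety_<k>_event`` pairs for each safety tier,
    then one column per schema covariate.  Times are floating-point days;
    day 0 is the first randomization.  ``accrual_time`` is study-calendar
    while outcome times are per-participant follow-up.
    """

    table: pd.DataFrame
    schema: tuple[Covariate, ...] = field(default_factory=tuple)
    n_safety_tiers: int = 0

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        _check_schema(self.schema)
        self.validate()

    # -- structure ---------------------------------------------------------

    def validate(self) -> None:
        t = self.table
        for col in RESERVED_COLUMNS:
            if col not in t.columns:
                raise SchemaError(f"missing reserved column {col!r}")
        if t["id"].duplicated().any():
            raise ValidationError("duplicate participant ids")
        bad_arm = set(t["arm"].unique()) - set(ARMS)
        if bad_arm:
            raise ValidationError(f"unknown arm labels {sorted(bad_arm)}")
        if len(t) and len(set(t["arm"].unique())) < 2:
            raise ValidationError("both arms must be nonempty in an analyzed dataset")
        if (t["accrual_time"].to_numpy(float) < 0).any():
            raise ValidationError("accrual_time must be >= 0")
        if (t["primary_time"].to_numpy(float) <= 0).any():
            raise ValidationError("primary_time must be > 0")
        ev = t["primary_event"].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValidationError("primary_event must be 0/1")
        for k in range(self.n_safety_tiers):
            for suffix in ("time", "event"):
                col = f"safety_{k}_{suffix}"
                if col not in t.columns:
                    raise SchemaError(f"missing safety column {col!r}")
        for c in self.schema:
            if c.name not in t.columns:
                raise SchemaError(f"missing covariate column {c.name!r}")

    # -- accessors ---------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def covariate_names(self) -> list[str]:
        return [c.name for c in self.schema]

    def covariates(self) -> pd.DataFrame:
        """Baseline covariate block, indexed by participant id."""
        out = self.table.set_index("id")[self.covariate_names].copy()
        return out

    def arm_indicator(self) -> np.ndarray:
        """1 for intervention, 0 for control."""
        return (self.table["arm"].to_numpy() == ARM_INTERVENTION).astype(int)

    def safety_outcomes(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Ordered (time, event) arrays per safety tier, priority first."""
        out = []
        for k in range(self.n_safety_tiers):
            out.append(
                (
                    self.table[f"safety_{k}_time"].to_numpy(float),
                    self.table[f"safety_{k}_event"].to_numpy(int),
                )
            )
        return out

    def subset(self, mask_or_ids) -> "TrialDataset":
        """Row subset by boolean mask or id collection (order preserved)."""
        if isinstance(mask_or_ids, (np.ndarray, pd.Series)) and np.asarray(mask_or_ids).dtype == bool:
            sub = self.table.loc[np.asarray(mask_or_ids)]
        else:
            wanted = set(mask_or_ids)
            sub = self.table[self.table["id"].isin(wanted)]
        return TrialDataset(sub.reset_index(drop=True), self.schema, self.n_safety_tiers)

    def censored_at(self, calendar_cut: float) -> "TrialDataset":
        """Administratively censor follow-up at a calendar date.

        Participants accrued after the cut are dropped; each remaining
        participant's follow-up is truncated at ``cut - accrual_time``
        (events after the cut become censorings).
        """
        t = self.table[self.table["accrual_time"] < calendar_cut].copy()
        horizon = calendar_cut - t["accrual_time"].to_numpy(float)
        cols = [("primary_time", "primary_event")] + [
            (f"safety_{k}_time", f"safety_{k}_event") for k in range(self.n_safety_tiers)
        ]
        for tcol, ecol in cols:
            time = t[tcol].to_numpy(float)
            event = t[ecol].to_numpy(int)
            # small tolerance: an event exactly at the cut (e.g. the trigger
            # event itself) stays an event despite float cancellation
            over = time > horizon + 1e-7
            time = np.where(over, horizon, time)
            event = np.where(over, 0, event)
            t[tcol] = np.maximum(time, 1e-9)
            t[ecol] = event
        return TrialDataset(t.reset_index(drop=True), self.schema, self.n_safety_tiers)


@dataclass(frozen=True)
class SplitAssignment:
    """A deterministic 50:50 partition of the analyzed ids."""

    seed: int
    train_ids: tuple
    test_ids: tuple

    def __post_init__(self) -> None:
        train, test = set(self.train_ids), set(self.test_ids)
        if train & test:
            raise ValidationError("train/test overlap")
        if abs(len(train) - len(test)) > 1:
            raise ValidationError("train/test sizes differ by more than 1")


def split_half(ds: TrialDataset, seed: int) -> SplitAssignment:
    """Random 50:50 split of participants, deterministic for a fixed seed."""
    if ds.n < 4:
        raise ValidationError("need >=4 participants to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    half = ds.n // 2
    ids = ds.ids
    return SplitAssignment(
        seed=seed,
        train_ids=tuple(ids[perm[:half]]),
        test_ids=tuple(ids[perm[half:]]),
    )


# -- I/O -------------------------------------------------------------------


def _safety_columns(n_tiers: int) -> list[str]:
    cols = []
    for k in range(n_tiers):
        cols += [f"safety_{k}_time", f"safety_{k}_event"]
    return cols


def write_trial_table(ds: TrialDataset, path) -> None:
    """Write a dataset as CSV; missing covariate cells become ``NA``."""
    cols = list(RESERVED_COLUMNS) + _safety_columns(ds.n_safety_tiers) + ds.covariate_names
    out = ds.table[cols].copy()
    # repr-based float formatting keeps round-trips bit-exact
    out.to_csv(path, index=False, na_rep=NA_TOKEN, float_format=lambda v: repr(float(v)))


def read_trial_table(path, schema, n_safety_tiers: int = 0) -> TrialDataset:
    """Read a CSV trial table under the fixed dialect.

    Unparseable covariate cells become missing; unparseable outcome or arm
    cells raise.  The header must contain every reserved column, the
    declared safety columns, and every schema covariate.
    """
    schema = tuple(schema)
    _check_schema(schema)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[NA_TOKEN])
    for col in list(RESERVED_COLUMNS) + _safety_columns(n_safety_tiers):
        if col not in raw.columns:
            raise SchemaError(f"missing reserved column {col!r}")
    t = pd.DataFrame()
    t["id"] = raw["id"].astype(str)
    t["arm"] = raw["arm"].astype(str)
    for col in ["accrual_time", "primary_time"] + [f"safety_{k}_time" for k in range(n_safety_tiers)]:
        t[col] = pd.to_numeric(raw[col], errors="raise").astype(float)
    for col in ["primary_event"] + [f"safety_{k}_event" for k in range(n_safety_tiers)]:
        t[col] = pd.to_numeric(raw[col], errors="raise").astype(int)
    for c in schema:
        if c.name not in raw.columns:
            raise SchemaError(f"missing covariate column {c.name!r}")
        col = raw[c.name]
        if c.kind == CATEGORICAL:
            vals = col.where(col.isin(c.levels))  # unknown level -> missing
            t[c.name] = vals
        else:
            t[c.name] = pd.to_numeric(col, errors="coerce").astype(float)
    return TrialDataset(t, schema, n_safety_tiers)


# -- summaries -------------------------------------------------------------


def summarize_events(ds: TrialDataset) -> pd.DataFrame:
    """Per-arm primary-event counts and proportions.

    Returns a frame indexed by arm with columns ``n``, ``events`` and
    ``proportion`` (events / n).
    """
    t = ds.table
    rows = {}
    for arm in ARMS:
        sub = t[t["arm"] == arm]
        n = len(sub)
        ev = int(sub["primary_event"].sum())
        rows[arm] = {"n": n, "events": ev, "proportion": ev / n if n else np.nan}
    return pd.DataFrame.from_dict(rows, orient="index")
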