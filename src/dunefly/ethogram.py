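"""Behavior event logs, composite-state sequences, and courtship metrics.

Courtship interactions are scored as timestamped behavior *bouts*: one record
per continuous expression of a behavior by one actor (male or female) of a
courting pair.  Behaviors of one actor may overlap in time (different body
parts act simultaneously), so an actor's timeline is re-expressed as a
sequence of *composite behavioral states* — the set of concurrently active
behaviors — which is the unit of the downstream Markov sequence analysis.

Per-pair courtship metrics are proportional, to absorb natural variation in
interaction length:

* ``duration_prop``  — mean bout duration / total interaction duration;
* ``frequency_prop`` — bouts of the behavior / total bouts of all behaviors;
* ``interval_prop``  — mean gap between consecutive bouts of the behavior /
  total interaction duration (undefined with fewer than two bouts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .presets import (
    BOUT_END,
    BOUT_START,
    ETHOGRAM_BEHAVIORS,
    EXTENDED_BEHAVIORS,
    BOTH,
    FEMALE,
    MALE,
    state_label,
)

EVENT_COLUMNS = ["pair_id", "population", "actor", "behavior", "start_s", "end_s"]

_ACTOR_ALIASES = {
    "m": MALE, "male": MALE, MALE: MALE,
    "f": FEMALE, "female": FEMALE, FEMALE: FEMALE,
}


class EventLogFormatError(ValueError):
    """Malformed event-log file (missing columns, unreadable values)."""


class EventValidationError(ValueError):
    """Structurally valid file with invalid rows; carries row numbers."""

    def __init__(self, message: str, rows: list[int]):
        super().__init__(message)
        self.rows = rows


@dataclass(frozen=True)
class EthogramDefinition:
    """Closed behavior vocabulary with sex applicability and sentinels."""

    behaviors: dict[str, str] = field(
        default_factory=lambda: dict(ETHOGRAM_BEHAVIORS)
    )
    bout_start: str = BOUT_START
    bout_end: str = BOUT_END

    def __post_init__(self):
        for label, sex in self.behaviors.items():
            if sex not in (MALE, FEMALE, BOTH):
                raise ValueError(f"bad sex applicability {sex!r} for {label!r}")

    def allowed(self, behavior: str, actor: str) -> bool:
        sex = self.behaviors.get(behavior)
        return sex is not None and (sex == BOTH or sex == actor)


DEFAULT_ETHOGRAM = EthogramDefinition()

#: Extended vocabulary for the full 41-state preset (adds the behaviors that
#: appear in observed composite states but not in the core 18-behavior list).
EXTENDED_ETHOGRAM = EthogramDefinition(behaviors=dict(EXTENDED_BEHAVIORS))


@dataclass(frozen=True)
class BehaviorEvent:
    pair_id: str
    actor: str  # "M" or "F"
    behavior: str
    start: float
    end: float

    def __post_init__(self):
        if not self.end > self.start:
            raise ValueError(
                f"event end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class StateSequence:
    """Time-ordered composite states of one actor within one pair.

    ``states`` includes the bout-start / bout-end sentinels; ``intervals``
    aligns with ``states`` and holds ``None`` for sentinels.
    """

    pair_id: str
    actor: str
    states: list[str]
    intervals: list[tuple[float, float] | None]

    @property
    def labels(self) -> list[str]:
        return list(self.states)


def load_event_log(path, ethogram: EthogramDefinition = DEFAULT_ETHOGRAM) -> pd.DataFrame:
    """Read and validate a behavior event CSV.

    Required columns: pair_id, actor, behavior, start_s, end_s (``population``
    optional).  Rejects unknown behavior labels, behaviors scored for the
    wrong sex, and non-positive bout durations, reporting offending rows.
    """
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError) as exc:
        raise EventLogFormatError(f"cannot read event log {path}: {exc}") from exc
    missing = [c for c in EVENT_COLUMNS if c not in df.columns and c != "population"]
    if missing:
        raise EventLogFormatError(f"event log {path} lacks columns {missing}")
    return validate_events(df, ethogram)


def validate_events(df: pd.DataFrame, ethogram: EthogramDefinition = DEFAULT_ETHOGRAM) -> pd.DataFrame:
    """Validate an in-memory event table; returns a normalized copy."""
    df = df.copy()
    actor = df["actor"].astype(str).str.strip().str.lower().map(_ACTOR_ALIASES)
    bad_actor = df.index[actor.isna()].tolist()
    if bad_actor:
        raise EventValidationError(
            f"unknown actor labels at rows {bad_actor}", bad_actor
        )
    df["actor"] = actor

    known = df["behavior"].isin(ethogram.behaviors)
    if not known.all():
        rows = df.index[~known].tolist()
        labels = sorted(df.loc[rows, "behavior"].unique())
        raise EventValidationError(
            f"behaviors {labels} not in the ethogram (rows {rows})", rows
        )
    ok_sex = [
        ethogram.allowed(b, a) for b, a in zip(df["behavior"], df["actor"])
    ]
    if not all(ok_sex):
        rows = df.index[~np.asarray(ok_sex)].tolist()
        raise EventValidationError(
            f"behaviors scored for the wrong sex at rows {rows}", rows
        )
    df["start_s"] = pd.to_numeric(df["start_s"])
    df["end_s"] = pd.to_numeric(df["end_s"])
    bad_time = df.index[
        ~(df["end_s"] > df["start_s"]) | (df["start_s"] < 0)
    ].tolist()
    if bad_time:
        raise EventValidationError(
            f"non-positive bout duration or negative start at rows {bad_time}",
            bad_time,
        )
    return df


def derive_state_sequence(
    events: pd.DataFrame,
    pair_id,
    actor: str,
    ethogram: EthogramDefinition = DEFAULT_ETHOGRAM,
) -> StateSequence:
    """Overlay one actor's bouts into a composite-state sequence.

    The timeline is partitioned at every bout boundary; each segment with at
    least one active behavior becomes a state labelled by the sorted active
    set; consecutive identical states are merged; sentinels are added at the
    ends.  Gaps with no active behavior separate states directly (the
    transition spans the gap).
    """
    actor = _ACTOR_ALIASES[str(actor).strip().lower()]
    sub = events[(events["pair_id"] == pair_id) & (events["actor"] == actor)]
    if sub.empty:
        return StateSequence(pair_id, actor, [ethogram.bout_start, ethogram.bout_end], [None, None])

    starts = sub["start_s"].to_numpy(float)
    ends = sub["end_s"].to_numpy(float)
    behaviors = sub["behavior"].to_numpy(object)
    bounds = np.unique(np.concatenate([starts, ends]))

    states: list[str] = [ethogram.bout_start]
    intervals: list[tuple[float, float] | None] = [None]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        active = {
            b for b, s, e in zip(behaviors, starts, ends) if s <= lo and e >= hi
        }
        if not active:
            continue
        label = state_label(actor, active)
        if states[-1] == label:
            s0, _ = intervals[-1]
            intervals[-1] = (s0, float(hi))
        else:
            states.append(label)
            intervals.append((float(lo), float(hi)))
    states.append(ethogram.bout_end)
    intervals.append(None)
    return StateSequence(pair_id, actor, states, intervals)


def _merge_bouts(starts: np.ndarray, ends: np.ndarray, gap_tol: float = 0.0):
    """Merge overlapping/abutting intervals into maximal bouts."""
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out = []
    cur_s, cur_e = starts[0], ends[0]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= cur_e + gap_tol:
            cur_e = max(cur_e, e)
        else:
            out.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    out.append((cur_s, cur_e))
    return out


def interaction_duration(events: pd.DataFrame, pair_id) -> float:
    sub = events[events["pair_id"] == pair_id]
    if sub.empty:
        raise ValueError(f"no events for pair {pair_id!r}")
    return float(sub["end_s"].max() - sub["start_s"].min())


def compute_metrics(
    events: pd.DataFrame,
    pair_id,
    gap_tol: float = 0.0,
) -> pd.DataFrame:
    """Per-(actor, behavior) proportional courtship metrics for one pair.

    Returns a DataFrame indexed by (actor, behavior) with columns
    ``n_bouts``, ``duration_prop``, ``frequency_prop``, ``interval_prop``
    and the pair's ``total_duration_s`` repeated per row.  ``interval_prop``
    is NaN for behaviors with a single bout.
    """
    sub = events[events["pair_id"] == pair_id]
    if sub.empty:
        raise ValueError(f"no events for pair {pair_id!r}")
    total = float(sub["end_s"].max() - sub["start_s"].min())
    if total <= 0:
        raise ValueError(f"zero-duration interaction for pair {pair_id!r}")

    rows = {}
    for (actor, behavior), grp in sub.groupby(["actor", "behavior"], sort=True):
        bouts = _merge_bouts(
            grp["start_s"].to_numpy(float), grp["end_s"].to_numpy(float), gap_tol
        )
        durations = np.array([e - s for s, e in bouts])
        gaps = np.array([bouts[i + 1][0] - bouts[i][1] for i in range(len(bouts) - 1)])
        rows[(actor, behavior)] = {
            "n_bouts": len(bouts),
            "duration_prop": durations.mean() / total,
            "interval_prop": gaps.mean() / total if len(gaps) else np.nan,
            "total_duration_s": total,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["actor", "behavior"])
    out["frequency_prop"] = out["n_bouts"] / out["n_bouts"].sum()
    return out[
        ["n_bouts", "duration_prop", "frequency_prop", "interval_prop", "total_duration_s"]
    ]


def compute_all_metrics(events: pd.DataFrame, gap_tol: float = 0.0) -> pd.DataFrame:
    """``compute_metrics`` for every pair, concatenated (pair_id level added)."""
    parts = {
        pid: compute_metrics(events, pid, gap_tol)
        for pid in sorted(events["pair_id"].unique())
    }
    return pd.concat(parts, names=["pair_id"])


def occurrence_proportions(
    events: pd.DataFrame,
    populations: dict | pd.Series,
    ethogram: EthogramDefinition = DEFAULT_ETHOGRAM,
) -> pd.DataFrame:
    """Proportion of pairs per population in which each behavior occurred.

    Rows are (actor, behavior) over the full applicable vocabulary — a
    behavior absent from a population reports 0, not missing.
    """
    populations = pd.Series(populations)
    pops = sorted(populations.unique())
    pair_ids = populations.index
    if not len(pair_ids):
        raise ValueError("empty population mapping")
    counts = {pop: (populations == pop).sum() for pop in pops}
    if min(counts.values()) == 0:
        raise ValueError("empty population")

    index = [
        (actor, behavior)
        for behavior, sex in sorted(ethogram.behaviors.items())
        for actor in ((MALE, FEMALE) if sex == BOTH else (sex,))
    ]
    out = pd.DataFrame(0.0, index=pd.MultiIndex.from_tuples(index, names=["actor", "behavior"]), columns=pops)
    seen = events.groupby(["actor", "behavior"])["pair_id"].apply(set)
    for (actor, behavior), pairs in seen.items():
        for pop in pops:
            members = set(pair_ids[populations == pop])
            out.loc[(actor, behavior), pop] = len(pairs & members) / counts[pop]
    return out


def prevalence_filter(
    occurrence: pd.DataFrame,
    threshold: float = 0.5,
    exclude: tuple[str, ...] = (),
) -> list[tuple[str, str]]:
    """(actor, behavior) rows exceeding ``threshold`` in *every* population.

    ``exclude`` drops behaviors by name (e.g. non-signal states excluded from
    quantitative analysis by study design) — configuration, not hard-coding.
    """
    if not 0 < threshold or not threshold < 1:
        if threshold != 0:
            raise ValueError("threshold must lie in [0, 1)")
    passing = occurrence.index[(occurrence > threshold).all(axis=1)]
    return [
        (actor, behavior)
        for actor, behavior in passing
        if behavior not in exclude
    ]
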