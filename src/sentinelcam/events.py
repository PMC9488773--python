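"""From reviewed-frame annotations to predation events and study statistics.

The manual-review stage yields one annotation row per (frame, species):
which predator species is visible, whether it is feeding on a sentinel
weevil, and how many of the two tethered weevils are still visible.  This
module clusters those rows into *appearances* (maximal runs of consecutive
frames showing one species), locates weevil *disappearances* (unit drops in
the visible-weevil count), attributes each disappearance to a predator
species — or to "unseen" when no predator shows within the attribution
window — and computes the study's summary statistics:

* predation rate: events / sentinel prey deployed;
* per-species event shares (percentages truncated at one decimal);
* predation frequency: per species, appearances involved in a predation
  event / total appearances;
* an hourly activity profile and a Poisson regression of per-hour event
  counts on first-order circular harmonics of the clock hour.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from datetime import datetime
from decimal import ROUND_FLOOR, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

UNSEEN = "unseen"

#: Frames on either side of a disappearance within which an appearance can
#: be attributed (4 frames = 2 min at the nominal 30-s interval).
DEFAULT_ATTRIBUTION_WINDOW = 4

ANNOTATION_COLUMNS = [
    "session_id",
    "frame_index",
    "timestamp",
    "species",
    "feeding_on_weevil",
    "weevils_visible",
]


class AttributionTieError(ValueError):
    """Two species are equally plausible predators; manual adjudication needed."""


@dataclass
class Appearance:
    """Maximal run of consecutive annotated frames showing one species."""

    session_id: str
    species: str
    start_index: int
    end_index: int
    start_time: datetime | None = None
    end_time: datetime | None = None
    involved_in_predation: bool = False

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("appearance start after end")

    def distance(self, index: int) -> int:
        """Frame distance from ``index`` to this appearance (0 if covered)."""
        if self.start_index <= index <= self.end_index:
            return 0
        return min(abs(self.start_index - index), abs(self.end_index - index))


@dataclass
class PredationEvent:
    """One weevil's disappearance, attributed to a predator or 'unseen'."""

    session_id: str
    plot_id: str
    disappearance_index: int
    event_time: datetime | None
    predator: str
    weevil_slot: int


def _validate_annotations(frames: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in ANNOTATION_COLUMNS if c not in frames.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if len(frames) == 0:
        return frames
    bad = ~frames["weevils_visible"].isin([0, 1, 2])
    if bad.any():
        raise ValueError("weevils_visible must be 0, 1 or 2")
    species = frames["species"].fillna("")
    feeding = frames["feeding_on_weevil"].astype(bool)
    if (feeding & (species == "")).any():
        raise ValueError("feeding_on_weevil requires a species label")
    return frames


def cluster_appearances(frames: pd.DataFrame) -> list[Appearance]:
    """Group annotated frames into appearances.

    Within a session, all consecutive frames labelled with one species form
    a single appearance; any gap of at least one frame starts a new one.
    Duplicate (session, frame, species) rows are rejected — they would
    silently double-count review work.
    """
    frames = _validate_annotations(frames)
    labelled = frames[frames["species"].fillna("") != ""]
    if labelled.duplicated(subset=["session_id", "frame_index", "species"]).any():
        raise ValueError("duplicate (session, frame, species) annotation rows")
    out: list[Appearance] = []
    for (session, species), grp in labelled.groupby(["session_id", "species"], sort=True):
        grp = grp.sort_values("frame_index")
        idx = grp["frame_index"].to_numpy()
        ts = grp["timestamp"].tolist()
        run_start = 0
        for j in range(1, len(idx) + 1):
            if j == len(idx) or idx[j] != idx[j - 1] + 1:
                out.append(
                    Appearance(
                        session_id=session,
                        species=species,
                        start_index=int(idx[run_start]),
                        end_index=int(idx[j - 1]),
                        start_time=ts[run_start],
                        end_time=ts[j - 1],
                    )
                )
                run_start = j
    out.sort(key=lambda a: (a.session_id, a.start_index, a.species))
    return out


def detect_disappearances(
    frames: pd.DataFrame, initial_count: int = 2
) -> list[tuple[int, int]]:
    """Weevil disappearances in one session: list of (frame_index, slot).

    Each unit drop of ``weevils_visible`` between consecutive annotated
    frames yields one disappearance at the later frame; a drop of two in one
    step yields two disappearances at the same index (both weevils taken
    within one 30-s interval).  Slots are numbered in order of loss.  An
    increase in the count is an annotation error: tethered weevils cannot
    reappear.
    """
    frames = _validate_annotations(frames)
    if frames["session_id"].nunique() > 1:
        raise ValueError("detect_disappearances operates on a single session")
    per_frame = (
        frames[["frame_index", "weevils_visible"]]
        .drop_duplicates()
        .sort_values("frame_index")
    )
    if per_frame["frame_index"].duplicated().any():
        raise ValueError("conflicting weevils_visible values on one frame")
    out: list[tuple[int, int]] = []
    prev = initial_count
    slot = 0
    for idx, count in per_frame.itertuples(index=False):
        if count > prev:
            raise ValueError(
                f"weevils_visible increases at frame {idx} ({prev} -> {count}); "
                "tethered weevils cannot reappear"
            )
        for _ in range(prev - count):
            slot += 1
            out.append((int(idx), slot))
        prev = count
    return out


def attribute_predation(
    disappearances: Sequence[tuple[int, int]],
    appearances: Sequence[Appearance],
    annotations: pd.DataFrame | None = None,
    frame_window: int = DEFAULT_ATTRIBUTION_WINDOW,
    session_id: str = "",
    plot_id: str = "",
    timestamps: Mapping[int, datetime] | None = None,
) -> list[PredationEvent]:
    """Attribute each disappearance to a predator species or to 'unseen'.

    A species qualifies when one of its appearances overlaps the symmetric
    window of ``frame_window`` frames around the disappearance.  Among
    qualifying species, one annotated as feeding on a weevil at the
    disappearance frame wins outright; otherwise the species whose
    appearance is nearest in frames wins.  An exact distance tie between two
    species raises :class:`AttributionTieError` so a human adjudicates, as
    in the manual-review workflow.  When no species qualifies the predator
    is recorded as ``"unseen"``.  Winning appearances are marked
    ``involved_in_predation`` in place (they feed the predation-frequency
    numerator).
    """
    feeding_lookup: set[tuple[int, str]] = set()
    ts_lookup: dict[int, datetime] = dict(timestamps or {})
    if annotations is not None:
        annotations = _validate_annotations(annotations)
        for row in annotations.itertuples(index=False):
            if getattr(row, "feeding_on_weevil"):
                feeding_lookup.add((int(row.frame_index), str(row.species)))
            ts_lookup.setdefault(int(row.frame_index), row.timestamp)

    events: list[PredationEvent] = []
    for d, slot in disappearances:
        candidates = [a for a in appearances if a.distance(d) <= frame_window]
        chosen: Appearance | None = None
        if candidates:
            feeders = [a for a in candidates if (d, a.species) in feeding_lookup]
            pool = feeders if feeders else candidates
            best = min(a.distance(d) for a in pool)
            nearest = [a for a in pool if a.distance(d) == best]
            species_at_best = sorted({a.species for a in nearest})
            if len(species_at_best) > 1:
                raise AttributionTieError(
                    f"disappearance at frame {d}: species {species_at_best} are "
                    f"equally distant ({best} frames); manual adjudication required"
                )
            chosen = nearest[0]
        predator = chosen.species if chosen is not None else UNSEEN
        if chosen is not None:
            chosen.involved_in_predation = True
        events.append(
            PredationEvent(
                session_id=session_id,
                plot_id=plot_id,
                disappearance_index=int(d),
                event_time=ts_lookup.get(int(d)),
                predator=predator,
                weevil_slot=int(slot),
            )
        )
    if len(events) > 2:
        raise ValueError(f"{len(events)} predation events in one session; at most 2 possible")
    return events


def extract_events(
    annotations: pd.DataFrame,
    sessions_meta: pd.DataFrame,
    frame_window: int = DEFAULT_ATTRIBUTION_WINDOW,
) -> tuple[list[PredationEvent], list[Appearance]]:
    """Run the full per-session event extraction over a multi-session table.

    ``sessions_meta`` needs columns ``session_id`` and ``plot_id`` (and
    optionally ``prey_deployed``).  Sessions present in the metadata but
    absent from the annotations simply contribute no appearances or events.
    """
    annotations = _validate_annotations(annotations)
    plot_of = dict(zip(sessions_meta["session_id"], sessions_meta["plot_id"]))
    all_events: list[PredationEvent] = []
    all_appearances: list[Appearance] = []
    for session, grp in annotations.groupby("session_id", sort=True):
        if session not in plot_of:
            raise ValueError(f"annotations reference unknown session {session!r}")
        apps = cluster_appearances(grp)
        disappearances = detect_disappearances(grp)
        events = attribute_predation(
            disappearances,
            apps,
            annotations=grp,
            frame_window=frame_window,
            session_id=session,
            plot_id=plot_of[session],
        )
        all_events.extend(events)
        all_appearances.extend(apps)
    return all_events, all_appearances


def share_percent(count: int, total: int) -> float:
    """Percentage truncated (floored) at one decimal place.

    Truncation rather than round-half-up is used so that printed shares are
    conservative and match the convention of the study report this package
    reproduces (e.g. 55/82 -> 67.0, 18/82 -> 21.9).
    """
    if total == 0:
        raise ZeroDivisionError("share of an empty total")
    pct = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_FLOOR
    )
    return float(pct)


@dataclass
class StudySummary:
    """Study-level tallies, rates and frequencies."""

    events_total: int
    events_by_species: dict[str, int]
    percent_by_species: dict[str, float]
    identified_events: int
    identified_percent: float
    prey_deployed: int
    predation_rate: float  # events / prey deployed, as a fraction
    predation_rate_percent: float
    predation_rate_by_plot: dict[str, float]
    predation_frequency: dict[str, float | None]
    appearances_by_species: dict[str, int]
    sessions_zero: int
    sessions_one: int
    sessions_both: int

    def to_dict(self) -> dict:
        return {
            "events_total": self.events_total,
            "events_by_species": self.events_by_species,
            "percent_by_species": self.percent_by_species,
            "identified_events": self.identified_events,
            "identified_percent": self.identified_percent,
            "prey_deployed": self.prey_deployed,
            "predation_rate": self.predation_rate,
            "predation_rate_percent": self.predation_rate_percent,
            "predation_rate_by_plot": self.predation_rate_by_plot,
            "predation_frequency": self.predation_frequency,
            "appearances_by_species": self.appearances_by_species,
            "sessions_zero": self.sessions_zero,
            "sessions_one": self.sessions_one,
            "sessions_both": self.sessions_both,
        }


def summarize_study(
    events: Sequence[PredationEvent],
    appearances: Sequence[Appearance],
    sessions_meta: pd.DataFrame,
) -> StudySummary:
    """Compute the study's summary statistics from events and appearances.

    ``sessions_meta`` needs ``session_id``, ``plot_id`` and ``prey_deployed``
    (2 tethered weevils per session in the standard design).  Percentages
    are truncated at one decimal; the predation frequency of a species with
    zero appearances is reported as ``None`` (undefined), never as 0.
    """
    required = {"session_id", "plot_id", "prey_deployed"}
    if not required <= set(sessions_meta.columns):
        raise ValueError(f"sessions_meta needs columns {sorted(required)}")
    if sessions_meta["session_id"].duplicated().any():
        raise ValueError("duplicate session_id in sessions_meta")

    prey_per_session = dict(
        zip(sessions_meta["session_id"], sessions_meta["prey_deployed"])
    )
    events_per_session: dict[str, int] = {s: 0 for s in prey_per_session}
    by_species: dict[str, int] = {}
    for e in events:
        if e.session_id not in prey_per_session:
            raise ValueError(f"event references unknown session {e.session_id!r}")
        events_per_session[e.session_id] += 1
        if events_per_session[e.session_id] > prey_per_session[e.session_id]:
            raise ValueError(
                f"session {e.session_id!r} has more events than prey deployed"
            )
        by_species[e.predator] = by_species.get(e.predator, 0) + 1

    events_total = len(events)
    identified = sum(c for s, c in by_species.items() if s != UNSEEN)
    prey_deployed = int(sessions_meta["prey_deployed"].sum())

    percent_by_species = (
        {s: share_percent(c, events_total) for s, c in sorted(by_species.items())}
        if events_total
        else {}
    )
    identified_percent = share_percent(identified, events_total) if events_total else 0.0

    rate = events_total / prey_deployed if prey_deployed else 0.0
    rate_by_plot: dict[str, float] = {}
    for plot, grp in sessions_meta.groupby("plot_id"):
        plot_prey = int(grp["prey_deployed"].sum())
        plot_events = sum(events_per_session[s] for s in grp["session_id"])
        rate_by_plot[str(plot)] = plot_events / plot_prey if plot_prey else 0.0

    app_by_species: dict[str, int] = {}
    involved_by_species: dict[str, int] = {}
    for a in appearances:
        app_by_species[a.species] = app_by_species.get(a.species, 0) + 1
        if a.involved_in_predation:
            involved_by_species[a.species] = involved_by_species.get(a.species, 0) + 1
    frequency: dict[str, float | None] = {}
    for species in sorted(set(app_by_species) | set(by_species) - {UNSEEN}):
        n_app = app_by_species.get(species, 0)
        frequency[species] = (
            involved_by_species.get(species, 0) / n_app if n_app else None
        )

    counts = list(events_per_session.values())
    sessions_zero = sum(1 for c in counts if c == 0)
    sessions_one = sum(1 for c in counts if c == 1)
    sessions_both = sum(1 for c in counts if c == 2)
    assert 2 * sessions_both + sessions_one == events_total  # accounting identity

    return StudySummary(
        events_total=events_total,
        events_by_species=dict(sorted(by_species.items())),
        percent_by_species=percent_by_species,
        identified_events=identified,
        identified_percent=identified_percent,
        prey_deployed=prey_deployed,
        predation_rate=rate,
        predation_rate_percent=share_percent(events_total, prey_deployed)
        if prey_deployed
        else 0.0,
        predation_rate_by_plot=rate_by_plot,
        predation_frequency=frequency,
        appearances_by_species=dict(sorted(app_by_species.items())),
        sessions_zero=sessions_zero,
        sessions_one=sessions_one,
        sessions_both=sessions_both,
    )


def hourly_profile(
    events: Sequence[PredationEvent], species: str | Iterable[str] | None = None
) -> np.ndarray:
    """24-vector of event counts by local clock hour (floor of the hour)."""
    if species is None:
        keep = None
    elif isinstance(species, str):
        keep = {species}
    else:
        keep = set(species)
    counts = np.zeros(24, dtype=np.int64)
    for e in events:
        if keep is not None and e.predator not in keep:
            continue
        if e.event_time is None:
            raise ValueError("event without a timestamp cannot be binned by hour")
        counts[e.event_time.hour] += 1
    return counts


@dataclass
class HourGlmFit:
    """Poisson fit of hourly event counts on first-order circular harmonics.

    The linear predictor is ``b0 + b_sin*sin(2*pi*h/24) + b_cos*cos(2*pi*h/24)``
    with a log link, i.e. ``lambda(h) = exp(b0 + A*cos(2*pi*(h - h_peak)/24))``
    with amplitude ``A = hypot(b_sin, b_cos)``.
    """

    params: np.ndarray  # (b0, b_sin, b_cos)
    bse: np.ndarray
    amplitude: float
    amplitude_se: float
    peak_hour: float
    lrt_stat: float
    p_value: float
    converged: bool
    n_events: int


def fit_hour_glm(
    data: Sequence[PredationEvent] | np.ndarray,
    species: str | None = None,
) -> HourGlmFit:
    """Test the effect of the hour of day on predation with a Poisson GLM.

    ``data`` is either a list of events (optionally filtered to one species)
    or a ready-made 24-vector of per-hour counts.  The model regresses the
    24 hourly counts on sin/cos harmonics of the clock hour; the p-value is
    a likelihood-ratio test (2 df) against the intercept-only model.  With
    every event in a single hour the harmonic fit is effectively separated;
    the fit is returned with ``converged=False`` and a warning.
    """
    counts = (
        np.asarray(data, dtype=float)
        if isinstance(data, np.ndarray)
        else hourly_profile(data, species).astype(float)
    )
    if counts.shape != (24,):
        raise ValueError("expected a 24-vector of hourly counts")
    n_events = int(counts.sum())
    if n_events == 0:
        raise ValueError("no events: the hour-of-day model is undefined")

    hours = np.arange(24)
    X = np.column_stack(
        [
            np.ones(24),
            np.sin(2 * np.pi * hours / 24),
            np.cos(2 * np.pi * hours / 24),
        ]
    )
    single_bin = int((counts > 0).sum()) == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(counts, X, family=sm.families.Poisson()).fit(maxiter=200)
        null = sm.GLM(counts, X[:, :1], family=sm.families.Poisson()).fit(maxiter=200)

    b0, b_sin, b_cos = full.params
    amplitude = float(np.hypot(b_sin, b_cos))
    if amplitude > 0:
        grad = np.array([0.0, b_sin / amplitude, b_cos / amplitude])
        cov = np.asarray(full.cov_params())
        amplitude_se = float(np.sqrt(grad @ cov @ grad))
    else:
        amplitude_se = float("nan")
    peak_hour = float((math.atan2(b_sin, b_cos) * 24 / (2 * math.pi)) % 24)
    lrt = float(2 * (full.llf - null.llf))
    p_value = float(stats.chi2.sf(max(lrt, 0.0), df=2))

    converged = bool(full.converged) and not single_bin
    if single_bin:
        warnings.warn(
            "all events fall in a single hour; harmonic fit is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return HourGlmFit(
        params=np.asarray(full.params),
        bse=np.asarray(full.bse),
        amplitude=amplitude,
        amplitude_se=amplitude_se,
        peak_hour=peak_hour,
        lrt_stat=lrt,
        p_value=p_value,
        converged=converged,
        n_events=n_events,
    )


def events_to_frame(events: Sequence[PredationEvent]) -> pd.DataFrame:
    """Events as the standard output table."""
    return pd.DataFrame(
        [
            {
                "session_id": e.session_id,
                "plot_id": e.plot_id,
                "event_time": e.event_time.isoformat() if e.event_time else "",
                "predator": e.predator,
                "weevil_slot": e.weevil_slot,
                "disappearance_index": e.disappearance_index,
            }
            for e in events
        ],
        columns=[
            "session_id",
            "plot_id",
            "event_time",
            "predator",
            "weevil_slot",
            "disappearance_index",
        ],
    )
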