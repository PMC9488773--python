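"""Synthetic time-lapse sequences and study tables with known ground truth.

The generator emulates the field setup the analysis pipeline was designed
for: a fixed camera looks straight down at a light-grey 30 x 30 cm ceramic
tile holding two tethered sentinel weevils, capturing one frame every 30 s
for 24 h.  Rendered features, in decreasing order of realism needed by the
detection math:

* a static textured background (per-pixel grain, frozen over the session);
* a slow sinusoidal illumination drift and optional per-frame Gaussian
  sensor noise;
* occasional flash failures that darken a whole frame (intensities x 0.2);
* transient animal visits rendered as flat elliptical blobs of configurable
  size and contrast;
* two small dark weevil marks that vanish from the take frame onward when a
  visit (or an off-camera, "unseen" predator) takes a weevil.

Blobs are deliberately flat ellipses, not textured animals: they exercise
every branch of the detector (size, contrast, duration, edge windows)
without pretending to photorealism.  All randomness descends from a single
seed through ``numpy.random.SeedSequence`` spawning, one child stream per
session, so any session can be re-rendered independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sentinelcam.events import UNSEEN
from sentinelcam.frames import FrameSequence

SESSION_START = datetime(2020, 9, 15, 16, 0, 0)  # sessions begin at 16:00
FULL_SESSION_FRAMES = 2880  # 24 h at one frame per 30 s


@dataclass
class SceneConfig:
    """Rendering parameters for one synthetic session.

    ``n_frames`` frames span 24 h regardless of count, so reduced sequences
    keep the full diurnal geometry.  ``background_texture`` is the half-range
    of the frozen per-pixel grain in grey levels; ``illumination_drift`` the
    amplitude of a one-cycle sinusoidal global offset; ``noise_sd`` the SD of
    per-frame Gaussian sensor noise; ``flash_failure_prob`` the per-frame
    probability that the flash fails and the frame comes out dark.
    """

    n_frames: int = FULL_SESSION_FRAMES
    frame_height: int = 300
    frame_width: int = 400
    background_level: float = 150.0
    background_texture: float = 10.0
    illumination_drift: float = 5.0
    flash_failure_prob: float = 0.002
    noise_sd: float = 2.0
    seed: int = 0
    start_time: datetime = SESSION_START

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if min(self.background_texture, self.illumination_drift, self.noise_sd) < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.flash_failure_prob <= 1:
            raise ValueError("flash_failure_prob must be in [0, 1]")

    @property
    def interval_seconds(self) -> float:
        return 86400.0 / self.n_frames

    def frame_time(self, i: int) -> datetime:
        return self.start_time + timedelta(seconds=i * self.interval_seconds)

    def frame_at(self, when_hour: float) -> int:
        """Frame index whose capture time is nearest the given clock hour."""
        delta = (when_hour - self.start_time.hour) % 24
        return int(round(delta * 3600 / self.interval_seconds)) % self.n_frames


@dataclass
class VisitSpec:
    """One animal visit: an elliptical blob, optionally taking weevils.

    ``blob_size_fraction`` is the blob area as a fraction of frame pixels
    (0 renders nothing — an off-camera predator, whose takes become
    "unseen" events).  ``contrast`` is the grey-level offset of the blob
    below the background; it may sit below the detector's pixel threshold to
    exercise the invisible regime.  ``takes_weevil`` lists the weevil slots
    (1, 2) taken at ``take_frame``.
    """

    species: str
    start_frame: int
    duration: int
    blob_size_fraction: float = 0.04
    contrast: float = 120.0
    takes_weevil: tuple[int, ...] = ()
    take_frame: int | None = None

    def __post_init__(self) -> None:
        if self.duration < 1:
            raise ValueError("duration must be >= 1")
        if not set(self.takes_weevil) <= {1, 2}:
            raise ValueError("takes_weevil slots must be in {1, 2}")
        if self.takes_weevil and self.take_frame is None:
            raise ValueError("a taking visit needs a take_frame")
        if self.take_frame is not None and not (
            self.start_frame <= self.take_frame < self.start_frame + self.duration
        ):
            raise ValueError("take_frame must lie within the visit")

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.duration - 1


@dataclass
class GroundTruth:
    """What actually happened in a generated session, in pipeline schemas."""

    session_id: str
    plot_id: str
    n_frames: int
    appearances: list[tuple[str, int, int]]  # (species, start, end)
    disappearances: list[tuple[int, int]]  # (frame, slot)
    events: list[tuple[int, int, str]]  # (frame, slot, predator)
    presence: dict[int, set[str]]  # frame -> visible species
    feeding: set[tuple[int, str]]  # (frame, species) feeding on a weevil
    timestamps: list[datetime]

    def weevils_visible(self, i: int) -> int:
        return 2 - sum(1 for f, _ in self.disappearances if f <= i)

    def visible_frames(self) -> set[int]:
        return set(self.presence)

    def annotation_table(
        self,
        selected_indices: Iterable[int],
        include_disappearance_frames: bool = True,
    ) -> pd.DataFrame:
        """Emulate the human reviewer on the given set of selected frames.

        Each selected frame gets one row per visible species (or one
        species-less row when nothing is visible, recording the weevil
        count).  With ``include_disappearance_frames`` the manual-review
        step of the field workflow is emulated too: any true disappearance
        frame missing from the selection is annotated anyway, as a reviewer
        scanning for the frame where a weevil vanished would.
        """
        indices = set(int(i) for i in selected_indices)
        if include_disappearance_frames:
            indices.update(f for f, _ in self.disappearances)
        rows = []
        for i in sorted(indices):
            visible = sorted(self.presence.get(i, ()))
            weevils = self.weevils_visible(i)
            if not visible:
                rows.append((self.session_id, i, self.timestamps[i], "", False, weevils))
            for sp in visible:
                rows.append(
                    (
                        self.session_id,
                        i,
                        self.timestamps[i],
                        sp,
                        (i, sp) in self.feeding,
                        weevils,
                    )
                )
        df = pd.DataFrame(
            rows,
            columns=[
                "session_id",
                "frame_index",
                "timestamp",
                "species",
                "feeding_on_weevil",
                "weevils_visible",
            ],
        )
        if df.empty:  # keep dtypes stable for concatenation
            df = df.astype(
                {
                    "session_id": str,
                    "frame_index": np.int64,
                    "species": str,
                    "feeding_on_weevil": bool,
                    "weevils_visible": np.int64,
                }
            )
        return df


def _ellipse_mask(
    height: int, width: int, cy: float, cx: float, area_fraction: float
) -> np.ndarray:
    """Boolean ellipse of roughly ``area_fraction`` of the frame, 2:1 aspect."""
    area = area_fraction * height * width
    # pi * a * b = area with a = 2b
    b = math.sqrt(area / (2 * math.pi))
    a = 2 * b
    yy, xx = np.ogrid[:height, :width]
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


# Weevil marks: two ~1-cm dark weevils near the tile centre (about 40 px each
# at the working resolution).
_WEEVIL_POSITIONS = ((150.0, 170.0), (150.0, 230.0))
_WEEVIL_CONTRAST = 110.0
_WEEVIL_AREA_FRACTION = 40 / 120000


def generate_sequence(
    scene: SceneConfig,
    visits: Sequence[VisitSpec],
    session_id: str = "synthetic",
    plot_id: str = "",
    tile_id: str = "",
) -> tuple[FrameSequence, GroundTruth]:
    """Render one session and return it with its ground truth.

    Deterministic for a fixed ``scene.seed``.  Overlapping blobs simply
    stack; visits extending past the last frame are rejected.
    """
    n = scene.n_frames
    h, w = scene.frame_height, scene.frame_width
    for v in visits:
        if v.start_frame < 0 or v.end_frame >= n:
            raise ValueError(f"visit {v.species!r} falls outside [0, {n})")

    rng = np.random.default_rng(scene.seed)
    texture = scene.background_level + rng.uniform(
        -scene.background_texture, scene.background_texture, size=(h, w)
    )
    weevil_masks = [
        _ellipse_mask(h, w, cy, cx, _WEEVIL_AREA_FRACTION)
        for cy, cx in _WEEVIL_POSITIONS
    ]
    # blob placement: deterministic per visit, away from the frame border
    blob_centres = rng.uniform([0.2 * h, 0.2 * w], [0.8 * h, 0.8 * w], size=(max(len(visits), 1), 2))
    blob_masks = [
        _ellipse_mask(h, w, cy, cx, v.blob_size_fraction)
        if v.blob_size_fraction > 0
        else None
        for (cy, cx), v in zip(blob_centres, visits)
    ]
    flash_fail = (
        rng.random(n) < scene.flash_failure_prob
        if scene.flash_failure_prob > 0
        else np.zeros(n, dtype=bool)
    )
    noise_rng = np.random.default_rng(rng.integers(2**31))

    # physical weevil-mark removal map (slot as deployed, not loss order)
    take_frames: dict[int, int] = {}
    for v in visits:
        for slot in v.takes_weevil:
            if slot in take_frames:
                raise ValueError(f"weevil slot {slot} taken twice")
            take_frames[slot] = int(v.take_frame)
    _, truth = _layout_truth(scene, visits, session_id, plot_id)

    timestamps = truth.timestamps
    frames = np.empty((n, h, w), dtype=np.uint8)
    # identical scene states quantise identically; cache them when the
    # render is deterministic per state (no noise, no drift)
    cacheable = scene.noise_sd == 0 and scene.illumination_drift == 0
    cache: dict[tuple, np.ndarray] = {}
    for i in range(n):
        weevil_state = tuple(
            slot
            for slot in (1, 2)
            if slot not in take_frames or i < take_frames[slot]
        )
        active = tuple(
            j
            for j, v in enumerate(visits)
            if blob_masks[j] is not None and v.start_frame <= i <= v.end_frame
        )
        key = (weevil_state, active, bool(flash_fail[i]))
        if cacheable and key in cache:
            frames[i] = cache[key]
            continue
        img = texture.copy()
        if scene.illumination_drift > 0:
            img += scene.illumination_drift * math.sin(2 * math.pi * i / n)
        for slot, mask in zip((1, 2), weevil_masks):
            if slot in weevil_state:
                img[mask] -= _WEEVIL_CONTRAST
        for j in active:
            img[blob_masks[j]] = texture[blob_masks[j]] - visits[j].contrast
        if scene.noise_sd > 0:
            img += noise_rng.normal(0.0, scene.noise_sd, size=(h, w))
        if flash_fail[i]:
            img *= 0.2
        frames[i] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        if cacheable:
            cache[key] = frames[i]

    seq = FrameSequence.from_stack(
        frames, timestamps, session_id=session_id, tile_id=tile_id, plot_id=plot_id
    )
    return seq, truth


# --------------------------------------------------------------------------
# Whole-study generation


def night_peaked_intensity(peak_hour: float = 22.0, width: float = 1.0) -> np.ndarray:
    """Relative hourly intensity exp(width*cos(...)) peaking at ``peak_hour``."""
    h = np.arange(24)
    return np.exp(width * np.cos(2 * np.pi * (h - peak_hour) / 24))


@dataclass
class StudyScenario:
    """Behavioural parameters of the simulated predator community.

    Defaults emulate the field study's community: a dominant nocturnal
    shrew, occasional nocturnal mice and toads, a diurnal lizard, plus
    off-camera ("unseen") takes.  ``visit_rate`` is the expected number of
    tile crossings per species per 24-h session; ``take_prob`` the chance a
    crossing takes a weevil while any remain; ``both_prob`` the chance a
    take removes both weevils at once; ``unseen_rate`` the expected number
    of off-camera takes per session.  With the default rates the expected
    number of predation events over a 125-session study is approximately
    82, matching the scale of the field data.
    """

    visit_rate: dict[str, float] = field(
        default_factory=lambda: {
            "S. murinus": 2.0,
            "M. musculus": 0.5,
            "C. versicolor": 0.5,
            "S. gutturalis": 0.2,
        }
    )
    hourly_intensity: dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "S. murinus": night_peaked_intensity(22.0, 1.5),
            "M. musculus": night_peaked_intensity(1.0, 1.5),
            "C. versicolor": night_peaked_intensity(13.0, 1.5),
            "S. gutturalis": night_peaked_intensity(23.0, 1.5),
        }
    )
    take_prob: float = 0.175
    both_prob: float = 0.35
    unseen_rate: float = 0.085
    duration_range: tuple[int, int] = (2, 8)
    blob_fraction_range: tuple[float, float] = (0.02, 0.08)
    contrast_range: tuple[float, float] = (90.0, 160.0)


@dataclass
class StudySession:
    session_id: str
    plot_id: str
    tile_id: str
    scene: SceneConfig
    visits: list[VisitSpec]
    truth: GroundTruth


@dataclass
class StudyTruth:
    """A full generated study: session metadata, visits and ground truth."""

    sessions: list[StudySession]

    @property
    def sessions_meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "session_id": s.session_id,
                    "plot_id": s.plot_id,
                    "tile_id": s.tile_id,
                    "prey_deployed": 2,
                    "n_frames": s.scene.n_frames,
                    "start_time": s.scene.start_time.isoformat(),
                    "seed": s.scene.seed,
                }
                for s in self.sessions
            ]
        )

    def render_session(self, session_id: str) -> tuple[FrameSequence, GroundTruth]:
        for s in self.sessions:
            if s.session_id == session_id:
                return generate_sequence(
                    s.scene, s.visits, session_id=s.session_id, plot_id=s.plot_id,
                    tile_id=s.tile_id,
                )
        raise KeyError(session_id)

    def events_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sessions:
            for f, slot, predator in s.truth.events:
                rows.append(
                    {
                        "session_id": s.session_id,
                        "plot_id": s.plot_id,
                        "event_time": s.truth.timestamps[f].isoformat(),
                        "predator": predator,
                        "weevil_slot": slot,
                        "disappearance_index": f,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "session_id",
                "plot_id",
                "event_time",
                "predator",
                "weevil_slot",
                "disappearance_index",
            ],
        )

    def annotation_table(self) -> pd.DataFrame:
        """Oracle annotations covering every frame with anything to report."""
        tables = [
            s.truth.annotation_table(s.truth.visible_frames()) for s in self.sessions
        ]
        non_empty = [t for t in tables if not t.empty]
        if non_empty:
            return pd.concat(non_empty, ignore_index=True)
        if tables:
            return tables[0]
        return GroundTruth("", "", 0, [], [], [], {}, set(), []).annotation_table([])

    def tally(self) -> dict:
        """Direct bookkeeping of the ground truth, independent of the pipeline."""
        by_species: dict[str, int] = {}
        per_session: list[int] = []
        for s in self.sessions:
            per_session.append(len(s.truth.events))
            for _, _, predator in s.truth.events:
                by_species[predator] = by_species.get(predator, 0) + 1
        total = sum(per_session)
        return {
            "events_total": total,
            "events_by_species": dict(sorted(by_species.items())),
            "sessions_zero": sum(1 for c in per_session if c == 0),
            "sessions_one": sum(1 for c in per_session if c == 1),
            "sessions_both": sum(1 for c in per_session if c == 2),
            "appearances_total": sum(len(s.truth.appearances) for s in self.sessions),
        }


def _sample_hour(rng: np.random.Generator, intensity: np.ndarray) -> float:
    lam = np.asarray(intensity, dtype=float)
    if lam.sum() <= 0:
        raise ValueError("hourly intensity must be positive somewhere")
    hour_bin = rng.choice(24, p=lam / lam.sum())
    return float(hour_bin) + float(rng.uniform(0, 1))


def _generate_session(
    rng: np.random.Generator,
    scenario: StudyScenario,
    scene: SceneConfig,
) -> list[VisitSpec]:
    """Draw one session's visits; at most two takes, non-overlapping visits."""
    lo_d, hi_d = scenario.duration_range
    visits: list[VisitSpec] = []
    occupied: set[int] = set()
    proposals: list[tuple[int, str]] = []
    for species, rate in scenario.visit_rate.items():
        for _ in range(rng.poisson(rate)):
            start = scene.frame_at(_sample_hour(rng, scenario.hourly_intensity[species]))
            proposals.append((start, species))
    proposals.sort()
    slots_left = [1, 2]
    for start, species in proposals:
        duration = int(rng.integers(lo_d, hi_d + 1))
        start = min(max(start, 0), scene.n_frames - duration)
        span = set(range(start - 5, start + duration + 5))
        if span & occupied:
            continue  # keep visits cleanly separated; ties need a human anyway
        occupied |= span
        takes: tuple[int, ...] = ()
        take_frame = None
        if slots_left and rng.random() < scenario.take_prob:
            if len(slots_left) == 2 and rng.random() < scenario.both_prob:
                takes = (slots_left[0], slots_left[1])
            else:
                takes = (slots_left[0],)
            for s in takes:
                slots_left.remove(s)
            take_frame = start + int(rng.integers(duration))
        visits.append(
            VisitSpec(
                species=species,
                start_frame=start,
                duration=duration,
                blob_size_fraction=float(rng.uniform(*scenario.blob_fraction_range)),
                contrast=float(rng.uniform(*scenario.contrast_range)),
                takes_weevil=takes,
                take_frame=take_frame,
            )
        )
    # off-camera takes
    for _ in range(rng.poisson(scenario.unseen_rate)):
        if not slots_left:
            break
        start = scene.frame_at(float(rng.uniform(0, 24)))
        start = min(start, scene.n_frames - 1)
        if set(range(start - 5, start + 5)) & occupied:
            continue
        occupied |= set(range(start - 5, start + 5))
        slot = slots_left.pop(0)
        visits.append(
            VisitSpec(
                species=UNSEEN,
                start_frame=start,
                duration=1,
                blob_size_fraction=0.0,
                contrast=0.0,
                takes_weevil=(slot,),
                take_frame=start,
            )
        )
    return visits


def generate_study(
    n_plots: int = 5,
    tiles_per_plot: int = 5,
    sessions_per_tile: int = 5,
    scenario: StudyScenario | None = None,
    seed: int = 0,
    n_frames: int = FULL_SESSION_FRAMES,
    scene_kwargs: dict | None = None,
) -> StudyTruth:
    """Generate a study layout of sessions with ground truth (lazy rendering).

    The default layout mirrors the field design: 5 plots x 5 tiles x 5
    sessions = 125 recordings of two sentinel weevils each.  Each session
    draws visits from the scenario's per-species rates and hourly intensity
    profiles through its own child random stream, so individual sessions can
    be re-rendered without generating the rest.  Frames are rendered only on
    demand (``StudyTruth.render_session``); the ground-truth tables are
    available immediately.
    """
    scenario = scenario or StudyScenario()
    scene_kwargs = dict(scene_kwargs or {})
    root = np.random.SeedSequence(seed)
    n_sessions = n_plots * tiles_per_plot * sessions_per_tile
    children = root.spawn(n_sessions)
    sessions: list[StudySession] = []
    i = 0
    for p in range(n_plots):
        plot_id = f"P{p + 1}"
        for t in range(tiles_per_plot):
            tile_id = f"{plot_id}-T{t + 1}"
            for s in range(sessions_per_tile):
                session_id = f"{tile_id}-S{s + 1}"
                child = children[i]
                i += 1
                scene_seed = int(child.generate_state(1)[0] % (2**31))
                scene = SceneConfig(n_frames=n_frames, seed=scene_seed, **scene_kwargs)
                rng = np.random.default_rng(child)
                visits = _generate_session(rng, scenario, scene)
                _, truth = _layout_truth(scene, visits, session_id, plot_id)
                sessions.append(
                    StudySession(
                        session_id=session_id,
                        plot_id=plot_id,
                        tile_id=tile_id,
                        scene=scene,
                        visits=visits,
                        truth=truth,
                    )
                )
    return StudyTruth(sessions=sessions)


def _layout_truth(
    scene: SceneConfig, visits: list[VisitSpec], session_id: str, plot_id: str
) -> tuple[None, GroundTruth]:
    """Ground truth of a session without rendering any pixels."""
    takes: list[tuple[int, int, str]] = []
    presence: dict[int, set[str]] = {}
    feeding: set[tuple[int, str]] = set()
    appearances: list[tuple[str, int, int]] = []
    for v in visits:
        label = v.species if v.blob_size_fraction > 0 else UNSEEN
        for slot in sorted(v.takes_weevil):
            takes.append((int(v.take_frame), slot, label))
        if v.blob_size_fraction > 0:
            appearances.append((v.species, v.start_frame, v.end_frame))
            for i in range(v.start_frame, v.end_frame + 1):
                presence.setdefault(i, set()).add(v.species)
            if v.takes_weevil:
                feeding.add((int(v.take_frame), v.species))
    if len(takes) > 2:
        raise ValueError("at most two weevils can be taken per session")
    takes.sort(key=lambda t: (t[0], t[1]))
    takes = [(f, i + 1, sp) for i, (f, _, sp) in enumerate(takes)]  # loss order
    appearances.sort(key=lambda a: (a[1], a[0]))
    truth = GroundTruth(
        session_id=session_id,
        plot_id=plot_id,
        n_frames=scene.n_frames,
        appearances=appearances,
        disappearances=[(f, slot) for f, slot, _ in takes],
        events=takes,
        presence=presence,
        feeding=feeding,
        timestamps=[scene.frame_time(i) for i in range(scene.n_frames)],
    )
    return None, truth


def generate_event_table(
    hourly_intensity: np.ndarray | Sequence[float],
    n_events: int,
    species: str = "S. murinus",
    seed: int = 0,
) -> pd.DataFrame:
    """Sample an events table with hours drawn proportional to an intensity.

    Used to exercise the hour-of-day model: hour bins are drawn from the
    normalised 24-bin intensity, with uniform minutes within the hour.
    Deterministic for a fixed seed.
    """
    lam = np.asarray(hourly_intensity, dtype=float)
    if lam.shape != (24,):
        raise ValueError("hourly_intensity must have 24 bins")
    if np.any(lam < 0) or lam.sum() <= 0:
        raise ValueError("hourly intensity must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    hours = rng.choice(24, size=n_events, p=lam / lam.sum())
    minutes = rng.integers(0, 60, size=n_events)
    seconds = rng.integers(0, 60, size=n_events)
    base = SESSION_START.replace(hour=0, minute=0, second=0)
    rows = []
    for j, (h, m, s) in enumerate(zip(hours, minutes, seconds)):
        when = base + timedelta(hours=int(h), minutes=int(m), seconds=int(s))
        rows.append(
            {
                "session_id": f"sim-{j}",
                "plot_id": "sim",
                "event_time": when.isoformat(),
                "predator": species,
                "weevil_slot": 1,
                "disappearance_index": 0,
            }
        )
    return pd.DataFrame(
        rows,
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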