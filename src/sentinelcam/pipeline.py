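"""Study-level orchestration: detect every session, then analyse annotations.

The pipeline mirrors the field workflow's explicit human hand-off: the
*detect* stage reduces each 24-h sequence to a short list of frames worth
reviewing (written as trace CSVs and selected-frame lists), a reviewer turns
those into an annotation table, and the *analyze* stage turns annotations
into events and summary statistics.  Species identification is deliberately
external: this package never guesses who is in a frame.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime
from pathlib import Path
from typing import Optional

import pandas as pd
from pydantic import BaseModel, Field

from sentinelcam import detect as _detect
from sentinelcam import events as _events
from sentinelcam.frames import load_sequence

logger = logging.getLogger(__name__)


class DetectionParams(BaseModel):
    window: int = Field(default=_detect.DEFAULT_WINDOW, gt=1)
    pixel_threshold: float = Field(default=_detect.DEFAULT_PIXEL_THRESHOLD, gt=0)
    stat_window: int = Field(default=_detect.DEFAULT_WINDOW, gt=1)
    k: float = Field(default=_detect.DEFAULT_K, ge=0)


class PipelineConfig(BaseModel):
    """Everything a run needs; every parameter lands in the log and summary."""

    input_dir: str
    out_dir: str
    sessions_file: Optional[str] = None
    annotations_file: Optional[str] = None
    detection: DetectionParams = Field(default_factory=DetectionParams)
    frame_window: int = Field(default=_events.DEFAULT_ATTRIBUTION_WINDOW, ge=0)
    glm_species: Optional[str] = None


class SummaryDocument(BaseModel):
    """Schema of the summary JSON written by the analyze stage."""

    events_total: int
    events_by_species: dict[str, int]
    percent_by_species: dict[str, float]
    identified_events: int
    identified_percent: float
    prey_deployed: int
    predation_rate: float
    predation_rate_percent: float
    predation_rate_by_plot: dict[str, float]
    predation_frequency: dict[str, Optional[float]]
    appearances_by_species: dict[str, int]
    sessions_zero: int
    sessions_one: int
    sessions_both: int
    parameters: dict = Field(default_factory=dict)
    n_sessions_failed: int = 0


def summary_json_schema() -> dict:
    """The published JSON schema of the summary document."""
    return SummaryDocument.model_json_schema()


def detect_session(
    source: Path,
    out_dir: Path,
    params: DetectionParams,
    session_id: str,
) -> _detect.SelectionResult:
    """Detect one session: write its trace CSV and selected-frame list."""
    seq = load_sequence(source, session_id=session_id)
    trace = _detect.difference_trace(
        seq,
        window_w=params.window,
        pixel_threshold=params.pixel_threshold,
        stat_window=params.stat_window,
    )
    selection = _detect.select_frames(trace, k=params.k)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace.to_csv(out_dir / f"{session_id}.trace.csv", selected=selection.flags)
    with open(out_dir / f"{session_id}.selected.txt", "w") as fh:
        for i in selection.selected_indices:
            fh.write(f"{i}\t{seq.frames[i].source_path}\n")
    logger.info(
        "detect session=%s frames=%d window=%d threshold=%g stat_window=%d k=%g selected=%d",
        session_id,
        len(seq),
        params.window,
        params.pixel_threshold,
        params.stat_window,
        params.k,
        len(selection),
    )
    return selection


def run_detect(input_dir: Path, out_dir: Path, params: DetectionParams) -> dict:
    """Detect every session directory under ``input_dir``.

    A failure in one session is logged and counted; the remaining sessions
    still run.
    """
    input_dir = Path(input_dir)
    sessions = sorted(p for p in input_dir.iterdir() if p.is_dir())
    if not sessions:
        raise ValueError(f"no session directories under {input_dir}")
    n_failed = 0
    selected: dict[str, list[int]] = {}
    for sess_dir in sessions:
        try:
            sel = detect_session(sess_dir, Path(out_dir), params, sess_dir.name)
            selected[sess_dir.name] = sel.selected_indices
        except Exception:
            logger.exception("detection failed for session %s", sess_dir.name)
            n_failed += 1
    return {"selected": selected, "n_failed": n_failed, "n_sessions": len(sessions)}


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    df["species"] = df["species"].astype(str)
    df["timestamp"] = df["timestamp"].map(datetime.fromisoformat)
    df["feeding_on_weevil"] = df["feeding_on_weevil"].map(
        lambda v: str(v).strip().lower() in {"true", "1"}
    )
    return df


def run_analyze(
    annotations_file: str | Path,
    sessions_file: str | Path,
    out_dir: str | Path,
    frame_window: int = _events.DEFAULT_ATTRIBUTION_WINDOW,
    glm_species: str | None = None,
    parameters: dict | None = None,
) -> SummaryDocument:
    """Analyse an annotation table: events CSV, hourly CSV, summary JSON."""
    annotations_file = Path(annotations_file)
    if not annotations_file.exists():
        raise FileNotFoundError(
            f"annotation table {annotations_file} not found; run the review "
            "step and export the reviewed frames first"
        )
    annotations = read_annotations(annotations_file)
    sessions = pd.read_csv(sessions_file)
    events, appearances = _events.extract_events(
        annotations, sessions, frame_window=frame_window
    )
    summary = _events.summarize_study(events, appearances, sessions)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    _events.events_to_frame(events).to_csv(out_dir / "events.csv", index=False)

    species_set = sorted({e.predator for e in events})
    rows = []
    for sp in species_set:
        profile = _events.hourly_profile(events, sp)
        rows.extend(
            {"hour": h, "species": sp, "count": int(c)} for h, c in enumerate(profile)
        )
    pd.DataFrame(rows, columns=["hour", "species", "count"]).to_csv(
        out_dir / "hourly_profile.csv", index=False
    )

    doc = SummaryDocument(
        **summary.to_dict(),
        parameters=dict(parameters or {}, frame_window=frame_window),
    )
    with open(out_dir / "summary.json", "w") as fh:
        fh.write(doc.model_dump_json(indent=2))

    if glm_species is not None:
        fit = _events.fit_hour_glm(events, species=glm_species)
        with open(out_dir / "hour_glm.json", "w") as fh:
            json.dump(
                {
                    "species": glm_species,
                    "n_events": fit.n_events,
                    "params": fit.params.tolist(),
                    "bse": fit.bse.tolist(),
                    "amplitude": fit.amplitude,
                    "amplitude_se": fit.amplitude_se,
                    "peak_hour": fit.peak_hour,
                    "lrt_stat": fit.lrt_stat,
                    "p_value": fit.p_value,
                    "converged": fit.converged,
                },
                fh,
                indent=2,
            )
    logger.info(
        "analyze events=%d appearances=%d sessions=%d frame_window=%d",
        len(events),
        len(appearances),
        len(sessions),
        frame_window,
    )
    return doc


def run_pipeline(config: PipelineConfig) -> SummaryDocument | dict:
    """Run detect and (when annotations are available) analyze.

    Returns the summary document, or the detect-stage report when no
    annotation table is configured (the human-review hand-off point).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("sentinelcam")
    root.addHandler(handler)
    old_level = root.level
    if root.getEffectiveLevel() > logging.INFO:
        root.setLevel(logging.INFO)
    try:
        logger.info("run_pipeline config=%s", config.model_dump_json())
        report = run_detect(Path(config.input_dir), out_dir / "detect", config.detection)
        if config.annotations_file is None:
            logger.info("no annotation table configured; stopping after detection")
            return report
        if config.sessions_file is None:
            raise ValueError("analyze requested but no sessions_file configured")
        doc = run_analyze(
            config.annotations_file,
            config.sessions_file,
            out_dir / "analysis",
            frame_window=config.frame_window,
            glm_species=config.glm_species,
            parameters=config.detection.model_dump(),
        )
        doc.n_sessions_failed = report["n_failed"]
        return doc
    finally:
        root.setLevel(old_level)
        root.removeHandler(handler)
        handler.close()
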