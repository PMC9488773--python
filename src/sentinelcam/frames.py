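"""Loading, timestamping and standardising time-lapse frames.

Every image entering the pipeline is reduced to an 8-bit grey frame of
300 x 400 pixels (height x width).  Working at this reduced resolution keeps
whole-sequence background modelling cheap and suppresses sensor-level noise;
species identification happens later, on the original high-resolution files,
by a human reviewer.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from PIL import Image, UnidentifiedImageError
from skimage.transform import resize_local_mean

logger = logging.getLogger(__name__)

#: Working resolution (height, width) of all grey frames.
TARGET_SHAPE: tuple[int, int] = (300, 400)

#: ITU-R BT.601 luminance weights used for colour -> grey conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_EXIF_DATETIME_ORIGINAL = 36867
_EXIF_DATETIME = 306
_EXIF_IFD_POINTER = 34665

_IMAGE_SUFFIXES = {".jpg", ".jpeg", ".png"}


@dataclass
class GreyFrame:
    """One standardised frame: 8-bit grey pixels at the working resolution."""

    pixels: np.ndarray
    index: int
    capture_time: datetime
    source_path: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != TARGET_SHAPE:
            raise ValueError(
                f"grey frame must be {TARGET_SHAPE}, got {self.pixels.shape}"
            )
        if self.pixels.dtype != np.uint8:
            raise ValueError("grey frame pixels must be uint8")


@dataclass
class FrameSequence:
    """Ordered grey frames with capture timestamps for one recording session."""

    frames: list[GreyFrame]
    session_id: str = ""
    tile_id: str = ""
    plot_id: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("a frame sequence needs at least one frame")
        times = [f.capture_time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("capture times must be strictly increasing")
        for i, f in enumerate(self.frames):
            f.index = i

    def __len__(self) -> int:
        return len(self.frames)

    def stack(self) -> np.ndarray:
        """All frames as one (n, 300, 400) uint8 array."""
        return np.stack([f.pixels for f in self.frames])

    def timestamps(self) -> list[datetime]:
        return [f.capture_time for f in self.frames]

    @classmethod
    def from_stack(
        cls,
        stack: np.ndarray,
        timestamps: Sequence[datetime],
        session_id: str = "",
        tile_id: str = "",
        plot_id: str = "",
    ) -> "FrameSequence":
        if len(stack) != len(timestamps):
            raise ValueError("stack and timestamps length mismatch")
        frames = [
            GreyFrame(pixels=np.asarray(p, dtype=np.uint8), index=i, capture_time=t)
            for i, (p, t) in enumerate(zip(stack, timestamps))
        ]
        return cls(frames=frames, session_id=session_id, tile_id=tile_id, plot_id=plot_id)


def preprocess_frame(
    raw: np.ndarray, target: tuple[int, int] = TARGET_SHAPE
) -> np.ndarray:
    """Convert a raw image array to an 8-bit grey frame at the target size.

    Colour images are converted to luminance (BT.601 weights) before the
    resize; the resize is an area-averaging (local-mean) interpolation so the
    operation is deterministic and acts as a low-pass filter.  Output values
    are rounded and clipped to [0, 255].  A frame already grey and at the
    target size passes through unchanged.
    """
    arr = np.asarray(raw)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        grey = arr.astype(np.float64) @ LUMA_WEIGHTS
    elif arr.ndim == 2:
        grey = arr.astype(np.float64)
    else:
        raise ValueError(f"expected a 2-D or 3-D image, got ndim={arr.ndim}")
    if grey.shape != target:
        grey = resize_local_mean(grey, target)
    return np.clip(np.rint(grey), 0, 255).astype(np.uint8)


def _parse_exif_datetime(value: str) -> datetime:
    return datetime.strptime(value.strip(), "%Y:%m:%d %H:%M:%S")


def extract_timestamp(
    path: str | Path,
    manifest: Mapping[str, datetime] | None = None,
) -> datetime:
    """Capture time of an image: EXIF DateTimeOriginal, else manifest, else error.

    File modification times are deliberately never used; they do not survive
    copying between machines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as img:
            exif = img.getexif()
            value = exif.get(_EXIF_DATETIME_ORIGINAL)
            if value is None:
                try:
                    value = exif.get_ifd(_EXIF_IFD_POINTER).get(_EXIF_DATETIME_ORIGINAL)
                except (KeyError, AttributeError):
                    value = None
            if value is None:
                value = exif.get(_EXIF_DATETIME)
            if value:
                return _parse_exif_datetime(str(value))
    except (UnidentifiedImageError, OSError):
        pass
    if manifest is not None and path.name in manifest:
        return manifest[path.name]
    raise ValueError(f"timestamp unavailable for {path.name}: no EXIF and no manifest entry")


def read_manifest(path: str | Path) -> dict[str, datetime]:
    """Read a ``filename,timestamp`` CSV (ISO-8601 timestamps)."""
    out: dict[str, datetime] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"filename", "timestamp"} <= set(
            reader.fieldnames
        ):
            raise ValueError("manifest must have columns: filename,timestamp")
        for row in reader:
            out[row["filename"]] = datetime.fromisoformat(row["timestamp"])
    return out


def _iter_image_files(directory: Path) -> Iterable[Path]:
    for p in sorted(directory.iterdir()):
        if p.is_file() and p.suffix.lower() in _IMAGE_SUFFIXES:
            yield p


def load_sequence(
    source: str | Path,
    session_id: str = "",
    tile_id: str = "",
    plot_id: str = "",
    target: tuple[int, int] = TARGET_SHAPE,
) -> FrameSequence:
    """Load a session's images into a time-ordered, preprocessed sequence.

    ``source`` is either a directory of JPEG/PNG files or a manifest CSV with
    columns ``filename,timestamp`` (filenames relative to the CSV's
    directory).  Frames are sorted by capture time with filename as the tie
    break; unreadable files are skipped with a logged warning.
    """
    source = Path(source)
    manifest: dict[str, datetime] | None = None
    if source.is_dir():
        directory = source
        candidate = source / "manifest.csv"
        if candidate.exists():
            manifest = read_manifest(candidate)
        files = list(_iter_image_files(directory))
    elif source.is_file():
        directory = source.parent
        manifest = read_manifest(source)
        files = [directory / name for name in manifest]
    else:
        raise FileNotFoundError(source)
    if not files:
        raise ValueError(f"no frames found in {source}")

    loaded: list[tuple[datetime, str, np.ndarray]] = []
    n_skipped = 0
    for path in files:
        try:
            with Image.open(path) as img:
                arr = np.asarray(img)
            ts = extract_timestamp(path, manifest)
        except (UnidentifiedImageError, OSError, ValueError) as exc:
            logger.warning("skipping unreadable frame %s: %s", path.name, exc)
            n_skipped += 1
            continue
        loaded.append((ts, path.name, preprocess_frame(arr, target)))
    if not loaded:
        raise ValueError(f"no readable frames in {source} ({n_skipped} skipped)")
    loaded.sort(key=lambda item: (item[0], item[1]))

    frames = [
        GreyFrame(pixels=px, index=i, capture_time=ts, source_path=name)
        for i, (ts, name, px) in enumerate(loaded)
    ]
    return FrameSequence(frames=frames, session_id=session_id, tile_id=tile_id, plot_id=plot_id)


def write_sequence_index(seq: FrameSequence, path: str | Path) -> None:
    """Write an ``index,filename,timestamp`` audit CSV for a loaded sequence."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "filename", "timestamp"])
        for f in seq.frames:
            writer.writerow([f.index, f.source_path, f.capture_time.isoformat()])
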