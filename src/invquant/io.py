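"""Readers and writers for the external formats the pipeline touches.

Time series travel as CSV (``time, value[, reference], trace_id``), EM
segmentations as 5-column ``object contour x y z`` whitespace text (the
``model2point -object`` dialect), images as single- or multi-page TIFF, and
ground truth / manifests as JSON sidecars.

All readers are strict by default: malformed input raises instead of being
silently coerced.  The one documented exception is the missing-value policy
of :func:`read_trace_table`, which drops incomplete rows with a warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger("invquant")

__all__ = [
    "TimedTrace",
    "SceneObject",
    "ContourScene",
    "LocalizationImage",
    "read_model2point",
    "write_model2point",
    "read_trace_table",
    "write_trace_table",
    "read_image_stack",
    "write_image_stack",
    "read_ground_truth",
    "write_ground_truth",
    "write_manifest",
]

MITOCHONDRION = "mitochondrion"
VESICLE = "vesicle"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class TimedTrace:
    """A (time, value) series with optional parallel reference series.

    ``times`` must be strictly increasing and ``values`` finite; the unit is
    ``"s"`` or ``"min"``.  ``meta`` carries provenance (trace_id, cell_id,
    condition, generator ground truth, ...).
    """

    times: np.ndarray
    values: np.ndarray
    unit: str = "s"
    reference: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if self.unit not in ("s", "min"):
            raise ValueError(f"unit must be 's' or 'min', got {self.unit!r}")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if len(self.reference) != len(self.values):
                raise ValueError("reference must have same length as values")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class SceneObject:
    """One labeled segmented object: a list of closed point contours.

    Each contour is an ``(n, 3)`` float array of (x, y, z) pixel
    coordinates; z is constant within a contour (a single section).
    """

    label: str
    contours: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        checked = []
        for c in self.contours:
            c = np.asarray(c, dtype=float)
            if c.ndim != 2 or c.shape[1] != 3:
                raise ValueError("contour must be an (n, 3) array")
            # closed-contour point counts (>= 3) are enforced by the
            # morphometry stage; the parser keeps whatever was segmented
            if not np.allclose(c[:, 2], c[0, 2]):
                raise ValueError("z must be constant within a contour")
            checked.append(c)
        self.contours = checked


@dataclass
class ContourScene:
    """A segmented EM scene: labeled objects of closed contours in pixels."""

    objects: list[SceneObject]
    scale: float  # nm per pixel
    source: str = "synthetic"
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive (nm/pixel)")

    def contours_for(self, label: str) -> list[np.ndarray]:
        return [c for obj in self.objects if obj.label == label for c in obj.contours]

    @property
    def mito_contours(self) -> list[np.ndarray]:
        return self.contours_for(MITOCHONDRION)

    @property
    def vesicle_contours(self) -> list[np.ndarray]:
        return self.contours_for(VESICLE)


@dataclass
class LocalizationImage:
    """A 2-D localization-count (or intensity) image.

    Origin top-left, x rightward, y downward, 0-based pixel centers.
    """

    pixels: np.ndarray
    pixel_size: float  # nm
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("pixel values must be non-negative")


# ---------------------------------------------------------------------------
# model2point text
# ---------------------------------------------------------------------------


def read_model2point(
    path: str | Path,
    labels: Mapping[int, str],
    scale: float,
    source: str | None = None,
) -> ContourScene:
    """Parse 5-column ``object contour x y z`` text into a :class:`ContourScene`.

    ``labels`` maps object index (as written in column 1) to a label string;
    an unmapped object index is an error.  Coordinates stay in pixels.
    """
    path = Path(path)
    rows: list[tuple[int, int, float, float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 columns, got {len(parts)}"
                )
            try:
                obj, cont = int(float(parts[0])), int(float(parts[1]))
                x, y, z = (float(p) for p in parts[2:])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: unparseable row") from exc
            rows.append((obj, cont, x, y, z))

    if not rows:
        warnings.warn(f"{path}: empty model2point file, returning empty scene")
        return ContourScene(objects=[], scale=scale, source=source or str(path))

    # group preserving encounter order of objects and contours
    objects: dict[int, dict[int, list[tuple[float, float, float]]]] = {}
    for obj, cont, x, y, z in rows:
        objects.setdefault(obj, {}).setdefault(cont, []).append((x, y, z))

    scene_objects = []
    for obj_idx, contours in objects.items():
        if obj_idx not in labels:
            raise KeyError(
                f"object index {obj_idx} has no label mapping "
                f"(known: {sorted(labels)})"
            )
        arrays = [np.array(pts, dtype=float) for pts in contours.values()]
        scene_objects.append(SceneObject(label=labels[obj_idx], contours=arrays))
    return ContourScene(
        objects=scene_objects, scale=scale, source=source or str(path)
    )


def write_model2point(scene: ContourScene, path: str | Path) -> dict[int, str]:
    """Write a scene as 5-column text; returns the object-index → label map."""
    path = Path(path)
    label_map: dict[int, str] = {}
    with open(path, "w") as fh:
        for obj_idx, obj in enumerate(scene.objects, start=1):
            label_map[obj_idx] = obj.label
            for cont_idx, contour in enumerate(obj.contours, start=1):
                for x, y, z in contour:
                    fh.write(f"{obj_idx} {cont_idx} {x:.6f} {y:.6f} {z:.6f}\n")
    return label_map


# ---------------------------------------------------------------------------
# trace tables
# ---------------------------------------------------------------------------


def read_trace_table(path: str | Path, unit: str = "s") -> list[TimedTrace]:
    """Read a trace CSV into one :class:`TimedTrace` per ``trace_id``.

    Required columns: ``time``, ``value``.  Optional: ``reference``,
    ``trace_id`` (defaults to a single anonymous trace).  Rows with a
    missing time or value are dropped with a warning reporting the count.
    """
    df = pd.read_csv(path)
    for col in ("time", "value"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    n_before = len(df)
    df = df.dropna(subset=["time", "value"])
    n_dropped = n_before - len(df)
    if n_dropped:
        warnings.warn(f"{path}: dropped {n_dropped} rows with missing time/value")
    if "trace_id" not in df.columns:
        df = df.assign(trace_id="trace")

    traces = []
    for trace_id, group in df.groupby("trace_id", sort=False):
        group = group.sort_values("time")
        times = group["time"].to_numpy(dtype=float)
        if len(times) >= 2 and np.any(np.diff(times) <= 0):
            raise ValueError(
                f"{path}: trace {trace_id!r} has duplicate or non-increasing times"
            )
        reference = None
        if "reference" in group.columns and group["reference"].notna().all():
            reference = group["reference"].to_numpy(dtype=float)
        traces.append(
            TimedTrace(
                times=times,
                values=group["value"].to_numpy(dtype=float),
                unit=unit,
                reference=reference,
                meta={"trace_id": str(trace_id)},
            )
        )
    return traces


def write_trace_table(traces: Sequence[TimedTrace], path: str | Path) -> None:
    frames = []
    for i, tr in enumerate(traces):
        data = {
            "time": tr.times,
            "value": tr.values,
            "trace_id": tr.meta.get("trace_id", f"trace_{i}"),
        }
        if tr.reference is not None:
            data["reference"] = tr.reference
        frames.append(pd.DataFrame(data))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


def read_image_stack(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF as a ``(frames, y, x)`` stack plus a metadata dict.

    A single page yields a stack of depth 1.  Pixel size found in file
    metadata is reported in the dict but never trusted silently — the
    caller's config decides.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            stack = tif.asarray()
            meta = {"n_pages": len(tif.pages), "path": str(path)}
    except (OSError, tifffile.TiffFileError) as exc:
        raise OSError(f"cannot read TIFF {path}: {exc}") from exc
    if stack.ndim == 2:
        stack = stack[None, ...]
    return stack, meta


def write_image_stack(stack: np.ndarray, path: str | Path) -> None:
    stack = np.asarray(stack)
    if stack.ndim == 2:
        stack = stack[None, ...]
    tifffile.imwrite(path, stack)


# ---------------------------------------------------------------------------
# JSON sidecars and manifests
# ---------------------------------------------------------------------------


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_ground_truth(gt: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonify(gt), fh, indent=1)


def read_ground_truth(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    path: str | Path,
    config: dict,
    inputs: Iterable[str | Path] = (),
    seed: int | None = None,
) -> None:
    """Write a reproducibility manifest: config, seed, input hashes, version."""
    from invquant import __version__

    manifest = {
        "invquant_version": __version__,
        "seed": seed,
        "config": _jsonify(config),
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if Path(p).is_file()
        },
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("wrote manifest %s", path)
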