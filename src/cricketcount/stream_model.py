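"""Detection-stream data model for duct-passage counting.

An upstream semantic-segmentation model watching the transparent duct
between two rearing boxes reports, for every video frame, zero or more
detections: a sex class (0 = male, 1 = female), the class confidence, and
the centroid of the detected cricket in pixels.  Detections within one
frame occupy *layers*: the first detection of a frame fills layer 1, the
second layer 2, and so on.  Layer identity is **not** individual identity;
making it so is the job of :mod:`cricketcount.layer_sorting`.

This module provides the in-memory container for such a stream
(:class:`InfoMatrix`, conceptually an ``n_frames x 4 x n_layers`` array
with absence encoded as missing), long-table CSV and JSON-lines readers
and writers, occupancy statistics, and the layer-truncation step that
discards the rarely populated third and higher layers.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "DetectionRecord",
    "InfoMatrix",
    "StreamStats",
    "StreamFormatError",
    "StreamValidationError",
    "read_stream",
    "write_stream",
    "truncate_layers",
    "stream_stats",
]

#: Class codes used by the upstream segmenter.
MALE = 0
FEMALE = 1

CSV_COLUMNS = ("frame", "layer", "class", "prob", "cx", "cy")


class StreamFormatError(ValueError):
    """A stream file cannot be parsed (bad columns, malformed rows)."""


class StreamValidationError(ValueError):
    """A stream parses but violates a semantic invariant."""


@dataclass(frozen=True)
class DetectionRecord:
    """One object observation in one frame.

    A record is wholly present or wholly absent: either all of
    ``sex_class``, ``prob``, ``cx``, ``cy`` are set, or all are ``None``.
    Absent records are normally not materialised at all (the
    :class:`InfoMatrix` simply has no entry), but the type supports them
    so file readers can represent frame markers.
    """

    frame: int
    layer: int
    sex_class: int | None
    prob: float | None
    cx: float | None
    cy: float | None

    def __post_init__(self) -> None:
        if self.frame < 0:
            raise StreamValidationError(f"negative frame index {self.frame}")
        if self.layer < 1:
            raise StreamValidationError(f"layer must be >= 1, got {self.layer}")
        fields = (self.sex_class, self.prob, self.cx, self.cy)
        n_missing = sum(v is None for v in fields)
        if n_missing not in (0, 4):
            raise StreamValidationError(
                f"frame {self.frame} layer {self.layer}: record must be wholly "
                "present or wholly absent"
            )
        if self.sex_class is not None and self.sex_class not in (MALE, FEMALE):
            raise StreamValidationError(
                f"frame {self.frame}: sex class must be 0 (male) or 1 (female), "
                f"got {self.sex_class}"
            )

    @property
    def present(self) -> bool:
        return self.sex_class is not None

    @property
    def position(self) -> tuple[float, float]:
        if not self.present:
            raise ValueError("absent record has no position")
        return (self.cx, self.cy)  # type: ignore[return-value]


@dataclass
class InfoMatrix:
    """Per-frame, per-layer detection store.

    Parameters
    ----------
    n_frames:
        Number of frames in the stream; frame indices are 0-based and
        contiguous, ``0 .. n_frames - 1``.  Frames with no detections are
        simply not represented in ``records``.
    fps:
        Acquisition frame rate (frames per second).
    frame_width, frame_height:
        Image size in pixels.  The x axis points in the travel direction
        from the origin box toward the destination box, so forward motion
        means increasing ``cx``.
    records:
        Mapping ``(frame, layer) -> DetectionRecord`` holding *present*
        detections only.
    """

    n_frames: int
    fps: float = 5.0
    frame_width: float = 1920.0
    frame_height: float = 1080.0
    records: dict[tuple[int, int], DetectionRecord] = field(default_factory=dict)

    # -- basic protocol -------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InfoMatrix):
            return NotImplemented
        return (
            self.n_frames == other.n_frames
            and self.fps == other.fps
            and self.frame_width == other.frame_width
            and self.frame_height == other.frame_height
            and self.records == other.records
        )

    @property
    def n_layers(self) -> int:
        """Maximum populated layer over all frames (0 for an empty stream)."""
        return max((k[1] for k in self.records), default=0)

    @property
    def dt(self) -> float:
        """Frame period in seconds (reciprocal of the frame rate)."""
        return 1.0 / self.fps

    def by_frame(self) -> dict[int, list[DetectionRecord]]:
        """Index present detections by frame, each list ordered by layer.

        Builds a fresh index in one pass over the records; prefer this to
        repeated :meth:`detections_in` calls when iterating a stream.
        """
        index: dict[int, list[DetectionRecord]] = {}
        for f, lay in sorted(self.records):
            index.setdefault(f, []).append(self.records[(f, lay)])
        return index

    def detections_in(self, frame: int) -> list[DetectionRecord]:
        """Present detections of one frame, ordered by layer."""
        recs = [rec for (f, _), rec in self.records.items() if f == frame]
        return sorted(recs, key=lambda r: r.layer)

    def occupancy(self) -> np.ndarray:
        """Number of present detections per frame, length ``n_frames``."""
        occ = np.zeros(self.n_frames, dtype=np.int64)
        for f, _ in self.records:
            occ[f] += 1
        return occ

    def layer_positions(self, layer: int) -> np.ndarray:
        """``(n_frames, 2)`` centroid array for one layer, NaN where absent."""
        pos = np.full((self.n_frames, 2), np.nan)
        for (f, lay), rec in self.records.items():
            if lay == layer:
                pos[f, 0] = rec.cx
                pos[f, 1] = rec.cy
        return pos

    def copy(self) -> "InfoMatrix":
        return replace(self, records=dict(self.records))

    # -- validation -----------------------------------------------------

    def validate(self, require_dense: bool = True) -> None:
        """Check container invariants; raise :class:`StreamValidationError`.

        With ``require_dense`` the usual detector-output invariant is
        enforced: detections fill lower layers first, so a record at
        layer ``k > 1`` implies records at layers ``1 .. k-1`` of the
        same frame.  Sorted matrices may legitimately violate density
        (an individual can keep layer 2 while layer 1 is empty), so the
        check is optional.
        """
        bad_prob: list[int] = []
        for (f, lay), rec in self.records.items():
            if f >= self.n_frames:
                raise StreamValidationError(
                    f"record at frame {f} beyond n_frames={self.n_frames}"
                )
            if (rec.frame, rec.layer) != (f, lay):
                raise StreamValidationError(
                    f"record key {(f, lay)} disagrees with record fields "
                    f"{(rec.frame, rec.layer)}"
                )
            if not rec.present:
                raise StreamValidationError(
                    f"absent record materialised at frame {f} layer {lay}"
                )
            if not (0.0 <= rec.prob <= 1.0):  # type: ignore[operator]
                bad_prob.append(f)
        if bad_prob:
            raise StreamValidationError(
                "class probability outside [0, 1] at frames "
                f"{sorted(set(bad_prob))}"
            )
        if require_dense:
            per_frame: dict[int, list[int]] = {}
            for f, lay in self.records:
                per_frame.setdefault(f, []).append(lay)
            for f, layers in per_frame.items():
                layers.sort()
                if layers != list(range(1, len(layers) + 1)):
                    raise StreamValidationError(
                        f"frame {f}: layers {layers} are not dense "
                        "(detections must fill lower layers first)"
                    )

    def compact(self) -> "InfoMatrix":
        """Return a copy with layers re-packed densely per frame."""
        new: dict[tuple[int, int], DetectionRecord] = {}
        per_frame: dict[int, list[int]] = {}
        for f, lay in self.records:
            per_frame.setdefault(f, []).append(lay)
        for f, layers in per_frame.items():
            for new_lay, old_lay in enumerate(sorted(layers), start=1):
                rec = self.records[(f, old_lay)]
                new[(f, new_lay)] = replace(rec, layer=new_lay)
        return replace(self, records=new)


# ---------------------------------------------------------------------------
# statistics


@dataclass
class StreamStats:
    """Frame-occupancy summary of a detection stream."""

    frames_with_k_detections: dict[int, int]
    total_detections: int
    detections_beyond: dict[int, int]  # layer k -> detections on layers > k

    @property
    def n_nonempty_frames(self) -> int:
        return sum(self.frames_with_k_detections.values())

    def fraction_detections_beyond(self, k: int) -> float:
        """Fraction of all detections residing on layers above ``k``."""
        if self.total_detections == 0:
            return 0.0
        return self.detections_beyond.get(k, 0) / self.total_detections

    def fraction_frames_beyond(self, k: int) -> float:
        """Fraction of non-empty frames holding more than ``k`` detections."""
        if self.n_nonempty_frames == 0:
            return 0.0
        n = sum(c for kk, c in self.frames_with_k_detections.items() if kk > k)
        return n / self.n_nonempty_frames


def stream_stats(matrix: InfoMatrix) -> StreamStats:
    """Occupancy statistics: how often do crickets share the duct?"""
    occ = matrix.occupancy()
    occ = occ[occ > 0]
    ks, counts = np.unique(occ, return_counts=True)
    per_k = {int(k): int(c) for k, c in zip(ks, counts)}
    total = int(occ.sum())
    max_k = int(ks.max()) if len(ks) else 0
    beyond = {}
    for k in range(1, max_k + 1):
        beyond[k] = int(sum((occ - k)[occ > k]))
    return StreamStats(per_k, total, beyond)


def truncate_layers(
    matrix: InfoMatrix, max_layers: int = 2
) -> tuple[InfoMatrix, int]:
    """Drop detections on layers above ``max_layers`` (Criterion 1).

    Third and higher layers hold a negligible share of detections in a
    well-designed duct, and two simultaneous trajectories are the most
    the sorting stage can disambiguate.  Returns the truncated matrix and
    the number of records dropped.
    """
    if max_layers < 1:
        raise ValueError("max_layers must be >= 1")
    kept = {k: v for k, v in matrix.records.items() if k[1] <= max_layers}
    dropped = len(matrix.records) - len(kept)
    return replace(matrix, records=kept), dropped


# ---------------------------------------------------------------------------
# I/O

_META_KEYS = ("fps", "frame_width", "frame_height")


def _float_str(x: float) -> str:
    """Shortest decimal string that round-trips the float exactly."""
    return repr(float(x))


def write_stream(matrix: InfoMatrix, path: str | Path, dialect: str = "csv") -> None:
    """Serialise an :class:`InfoMatrix`.

    ``csv`` writes a long table (one row per present detection, columns
    ``frame,layer,class,prob,cx,cy``) preceded by ``# key=value`` metadata
    comments; ``jsonl`` writes one JSON object per non-empty frame after a
    leading metadata object.  Missing values are encoded as empty cells /
    nulls, never as magic numbers.  Wholly empty frames are omitted and
    reconstructed from the frame-index range on read; a trailing frame
    marker pins the range when the last frames are empty.
    """
    path = Path(path)
    keys = sorted(matrix.records)
    last_present = keys[-1][0] if keys else -1
    need_marker = matrix.n_frames > 0 and last_present < matrix.n_frames - 1

    if dialect == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            for key in _META_KEYS:
                fh.write(f"# {key}={_float_str(getattr(matrix, key))}\n")
            w = csv.writer(fh)
            w.writerow(CSV_COLUMNS)
            for f, lay in keys:
                rec = matrix.records[(f, lay)]
                w.writerow(
                    [
                        f,
                        lay,
                        rec.sex_class,
                        _float_str(rec.prob),  # type: ignore[arg-type]
                        _float_str(rec.cx),  # type: ignore[arg-type]
                        _float_str(rec.cy),  # type: ignore[arg-type]
                    ]
                )
            if need_marker:
                w.writerow([matrix.n_frames - 1, "", "", "", "", ""])
    elif dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            meta = {key: getattr(matrix, key) for key in _META_KEYS}
            fh.write(json.dumps({"meta": meta}) + "\n")
            index = matrix.by_frame()
            for f in sorted(index):
                dets = [
                    {
                        "layer": rec.layer,
                        "class": rec.sex_class,
                        "prob": rec.prob,
                        "cx": rec.cx,
                        "cy": rec.cy,
                    }
                    for rec in index[f]
                ]
                fh.write(json.dumps({"frame": f, "detections": dets}) + "\n")
            if need_marker:
                fh.write(
                    json.dumps({"frame": matrix.n_frames - 1, "detections": []})
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'jsonl'")


def _parse_csv_row(
    row: list[str], row_no: int
) -> tuple[int, DetectionRecord | None]:
    if len(row) != len(CSV_COLUMNS):
        raise StreamFormatError(f"row {row_no}: expected 6 fields, got {len(row)}")
    try:
        frame = int(row[0])
    except ValueError as exc:
        raise StreamFormatError(f"row {row_no}: bad frame index {row[0]!r}") from exc
    rest = [cell.strip() for cell in row[1:]]
    if all(cell == "" for cell in rest):
        return frame, None  # frame marker
    try:
        layer = int(rest[0])
        sex = rest[1]
        sex_class = None if sex == "" else int(float(sex))
        prob = None if rest[2] == "" else float(rest[2])
        cx = None if rest[3] == "" else float(rest[3])
        cy = None if rest[4] == "" else float(rest[4])
    except ValueError as exc:
        raise StreamFormatError(f"row {row_no}: unparseable field ({exc})") from exc
    return frame, DetectionRecord(frame, layer, sex_class, prob, cx, cy)


def read_stream(
    path: str | Path,
    dialect: str | None = None,
    *,
    lenient: bool = False,
    fps: float = 5.0,
    frame_width: float = 1920.0,
    frame_height: float = 1080.0,
) -> InfoMatrix:
    """Read a detection stream into an :class:`InfoMatrix`.

    ``dialect`` is ``"csv"`` or ``"jsonl"``; when omitted it is inferred
    from the file suffix.  Metadata embedded in the file overrides the
    ``fps`` / frame-size arguments.  Malformed rows and non-dense layers
    raise by default; with ``lenient=True`` malformed rows are skipped
    with a warning and non-dense frames are auto-compacted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "jsonl" if path.suffix in (".jsonl", ".json", ".ndjson") else "csv"

    meta = {"fps": fps, "frame_width": frame_width, "frame_height": frame_height}
    records: dict[tuple[int, int], DetectionRecord] = {}
    max_frame = -1
    bad_rows: list[str] = []

    if dialect == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            header_seen = False
            for row_no, row in enumerate(csv.reader(fh), start=1):
                if not row:
                    continue
                if row[0].lstrip().startswith("#"):
                    text = ",".join(row).lstrip("# ").strip()
                    if "=" in text:
                        key, _, val = text.partition("=")
                        if key.strip() in _META_KEYS:
                            meta[key.strip()] = float(val)
                    continue
                if not header_seen:
                    got = tuple(c.strip().lower() for c in row)
                    if got != CSV_COLUMNS:
                        raise StreamFormatError(
                            f"bad header {got!r}; expected {CSV_COLUMNS!r}"
                        )
                    header_seen = True
                    continue
                try:
                    frame, rec = _parse_csv_row(row, row_no)
                except StreamFormatError as exc:
                    bad_rows.append(str(exc))
                    continue
                max_frame = max(max_frame, frame)
                if rec is not None and rec.present:
                    if (frame, rec.layer) in records:
                        bad_rows.append(
                            f"row {row_no}: duplicate (frame, layer) "
                            f"({frame}, {rec.layer})"
                        )
                        continue
                    records[(frame, rec.layer)] = rec
            if not header_seen:
                raise StreamFormatError(f"{path}: missing header row")
    elif dialect == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for row_no, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    obj = json.loads(line)
                except json.JSONDecodeError as exc:
                    bad_rows.append(f"line {row_no}: invalid JSON ({exc})")
                    continue
                if "meta" in obj:
                    for key in _META_KEYS:
                        if key in obj["meta"]:
                            meta[key] = float(obj["meta"][key])
                    continue
                if "frame" not in obj:
                    bad_rows.append(f"line {row_no}: missing 'frame' key")
                    continue
                frame = int(obj["frame"])
                max_frame = max(max_frame, frame)
                for i, det in enumerate(obj.get("detections", []), start=1):
                    try:
                        layer = int(det.get("layer", i))
                        rec = DetectionRecord(
                            frame,
                            layer,
                            None if det["class"] is None else int(det["class"]),
                            det["prob"],
                            det["cx"],
                            det["cy"],
                        )
                    except (KeyError, TypeError, ValueError,
                            StreamValidationError) as exc:
                        bad_rows.append(f"line {row_no}: bad detection ({exc})")
                        continue
                    if rec.present:
                        records[(frame, layer)] = rec
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'csv' or 'jsonl'")

    if bad_rows:
        if lenient:
            warnings.warn(
                f"{path}: skipped {len(bad_rows)} bad rows: " + "; ".join(bad_rows),
                stacklevel=2,
            )
        else:
            raise StreamFormatError(
                f"{path}: {len(bad_rows)} unparseable rows: " + "; ".join(bad_rows)
            )

    matrix = InfoMatrix(
        n_frames=max_frame + 1,
        fps=float(meta["fps"]),
        frame_width=float(meta["frame_width"]),
        frame_height=float(meta["frame_height"]),
        records=records,
    )
    try:
        matrix.validate(require_dense=True)
    except StreamValidationError:
        if not lenient:
            raise
        matrix = matrix.compact()
        matrix.validate(require_dense=True)
    return matrix
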