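"""Domain types and text I/O for parcellated time series, annotations and
distance matrices.

Conventions (also documented in the CLI help):

* time-series matrices are oriented rows = regions, columns = time points;
* time indices are 0-based and annotation intervals are half-open
  ``[start, end)``;
* all on-disk formats are plain delimited text (TSV/CSV) or JSON, written at
  full ``repr`` precision so read/write round-trips are bit-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationError",
    "ParseError",
    "TaskAnnotation",
    "ParentScan",
    "TaskScan",
    "DistanceMatrix",
    "read_time_series",
    "write_time_series",
    "read_annotation",
    "write_annotation",
    "read_parent_scan",
    "extract_task_scans",
    "read_distance_matrix",
    "write_distance_matrix",
]

#: printf format preserving float64 exactly through text round-trips
_FULL_PRECISION = "%.17g"


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class ParseError(ValueError):
    """A file could not be interpreted in the expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskAnnotation:
    """Ordered list of labeled, half-open ``[start, end)`` time intervals.

    Intervals are sorted by start, pairwise disjoint, and each spans at
    least 2 time points.  Cue/rest periods are simply absent from the list.
    """

    intervals: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        ivs = tuple(
            (int(s), int(e), str(lab)) for s, e, lab in self.intervals
        )
        object.__setattr__(self, "intervals", ivs)
        prev_end = None
        for start, end, label in ivs:
            if not label:
                raise ValidationError("interval labels must be nonempty")
            if start < 0:
                raise ValidationError(f"interval start {start} < 0")
            if end - start < 2:
                raise ValidationError(
                    f"interval [{start}, {end}) has length < 2"
                )
            if prev_end is not None and start < prev_end:
                raise ValidationError(
                    f"intervals overlap or are unsorted at [{start}, {end})"
                )
            prev_end = end

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for _, _, lab in self.intervals)

    @property
    def max_end(self) -> int:
        return max((e for _, e, _ in self.intervals), default=0)


@dataclass(frozen=True)
class ParentScan:
    """A full session time-series matrix (m regions x n time points) with a
    subject identifier and task annotation."""

    data: np.ndarray
    subject_id: str
    annotation: TaskAnnotation
    session_id: str = "test"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValidationError("parent scan data must be a 2-D matrix")
        m, n = data.shape
        if m < 2 or n < 2:
            raise ValidationError(
                f"parent scan must be at least 2x2, got {m}x{n}"
            )
        if not np.all(np.isfinite(data)):
            raise ValidationError("parent scan contains NaN or Inf entries")
        if self.annotation.max_end > n:
            raise ValidationError(
                f"annotation extends to {self.annotation.max_end} "
                f"but scan has only {n} time points"
            )

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class TaskScan:
    """A contiguous column block of a parent scan with (subject, task)
    labels."""

    data: np.ndarray
    subject_id: str
    task_label: str
    parent_ref: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValidationError("task scan data must be a 2-D matrix")
        if data.shape[1] < 2:
            raise ValidationError("task scan must span at least 2 time points")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def length(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative N x N matrix with zero diagonal over a list of
    identified objects.

    The dM dissimilarity may break the triangle inequality, so that is never
    part of this type's contract.
    """

    values: np.ndarray
    object_ids: tuple[str, ...]
    metric_name: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "object_ids", tuple(self.object_ids))
        n = len(self.object_ids)
        if values.shape != (n, n):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{n} object ids"
            )
        if not np.all(np.isfinite(values)):
            raise ValidationError("distance matrix contains NaN or Inf")
        if not np.array_equal(values, values.T):
            if not np.allclose(values, values.T, rtol=0, atol=1e-10):
                raise ValidationError("distance matrix is not symmetric")
            object.__setattr__(self, "values", (values + values.T) / 2.0)
        if np.any(np.diagonal(self.values) != 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValidationError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.object_ids)


# ---------------------------------------------------------------------------
# time-series matrices
# ---------------------------------------------------------------------------


def _sniff_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_time_series(path: str | Path) -> np.ndarray:
    """Read a delimited numeric matrix, rows = regions, columns = time.

    Accepts TSV or CSV, with either no header or a single header row of time
    indices; the header is detected by a numeric test on the first cell of
    the first row versus the row count consistency of the remainder.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty matrix file")
    delim = _sniff_delimiter(lines[0])
    first_cells = lines[0].split(delim)

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    start = 0
    if not all(_is_number(c) for c in first_cells):
        # header row of time indices / column names
        start = 1
        if len(lines) == 1:
            raise ParseError(f"{path}: header row but no data rows")
    rows: list[list[float]] = []
    width = None
    for r, ln in enumerate(lines[start:], start=start):
        cells = ln.split(delim)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ParseError(
                f"{path}: row {r} has {len(cells)} columns, expected {width}"
            )
        row = []
        for c, tok in enumerate(cells):
            try:
                row.append(float(tok))
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric cell at row {r}, column {c}: "
                    f"{tok!r}"
                ) from None
        rows.append(row)
    return np.asarray(rows, dtype=float)


def write_time_series(data: np.ndarray, path: str | Path) -> None:
    """Write a numeric matrix as headerless TSV at full precision."""
    data = np.asarray(data, dtype=float)
    np.savetxt(path, data, fmt=_FULL_PRECISION, delimiter="\t")


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> TaskAnnotation:
    """Read a JSON list of ``{"start": int, "end": int, "label": str}``."""
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid annotation JSON: {exc}") from exc
    if not isinstance(records, list):
        raise ParseError(f"{path}: annotation must be a JSON list")
    intervals = []
    for i, rec in enumerate(records):
        try:
            intervals.append((int(rec["start"]), int(rec["end"]), str(rec["label"])))
        except (KeyError, TypeError) as exc:
            raise ParseError(
                f"{path}: record {i} missing start/end/label"
            ) from exc
    return TaskAnnotation(tuple(intervals))


def write_annotation(annotation: TaskAnnotation, path: str | Path) -> None:
    records = [
        {"start": s, "end": e, "label": lab} for s, e, lab in annotation
    ]
    Path(path).write_text(json.dumps(records, indent=1) + "\n")


# ---------------------------------------------------------------------------
# parent scans and task extraction
# ---------------------------------------------------------------------------


def read_parent_scan(
    matrix_path: str | Path,
    annotation_path: str | Path,
    subject_id: str,
    session_id: str = "test",
) -> ParentScan:
    """Read and validate a parent scan from a matrix file and its annotation
    sidecar."""
    data = read_time_series(matrix_path)
    annotation = read_annotation(annotation_path)
    return ParentScan(
        data=data,
        subject_id=subject_id,
        annotation=annotation,
        session_id=session_id,
    )


def extract_task_scans(parent: ParentScan) -> list[TaskScan]:
    """Slice one task scan per annotated interval, in annotation order."""
    if len(parent.annotation) == 0:
        raise ValidationError("no task intervals in parent scan annotation")
    scans = []
    for start, end, label in parent.annotation:
        scans.append(
            TaskScan(
                data=parent.data[:, start:end].copy(),
                subject_id=parent.subject_id,
                task_label=label,
                parent_ref=f"{parent.subject_id}/{parent.session_id}",
            )
        )
    return scans


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------


def write_distance_matrix(D: DistanceMatrix, path: str | Path) -> None:
    """Write as TSV: header row of object ids, then one row per object with
    its id in the first column.  Round-trips bit-identically."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\t" + "\t".join(D.object_ids) + "\n")
        for oid, row in zip(D.object_ids, D.values):
            cells = "\t".join(_FULL_PRECISION % v for v in row)
            fh.write(f"{oid}\t{cells}\n")


def read_distance_matrix(
    path: str | Path, metric_name: str = ""
) -> DistanceMatrix:
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: distance matrix file too short")
    header = lines[0].split("\t")
    ids = tuple(header[1:])
    values = np.empty((len(ids), len(ids)), dtype=float)
    for r, ln in enumerate(lines[1:]):
        cells = ln.split("\t")
        if cells[0] != ids[r]:
            raise ParseError(
                f"{path}: row id {cells[0]!r} does not match header "
                f"{ids[r]!r}"
            )
        if len(cells) - 1 != len(ids):
            raise ParseError(f"{path}: row {r} has wrong column count")
        values[r] = [float(t) for t in cells[1:]]
    return DistanceMatrix(values=values, object_ids=ids, metric_name=metric_name)
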