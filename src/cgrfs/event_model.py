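"""Subject event histories and composite-endpoint derivation.

A subject's post-transplant course is recorded as the times of up to two
chronic-GVHD episodes (onset and resolution of each), an absorbing
death/relapse time, and a right-censoring time.  Follow-up starts at
transplant (t = 0) and all times share one unit.

The multistate model has ten states: even states are transient
("alive" states 0, 2, 4, 6, 8 — remission, first GVHD, first recovery,
second GVHD, second recovery) and odd states are absorbing failure
(death/relapse entered from the corresponding even state).

Five composite endpoints drive the model-free CGRFS estimator:

    T1 = first GVHD onset or failure
    T2 = second GVHD onset or failure
    T3 = first GVHD resolution or failure
    T4 = failure (death/relapse) at any time
    T5 = second GVHD resolution or failure

Each is observed as ``X_k = min(T_k, Z)`` with event indicator
``delta_k = 1{T_k <= Z}`` where Z is the censoring time.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "SubjectHistory",
    "EndpointRecord",
    "HistoryError",
    "validate_history",
    "derive_endpoints",
    "derive_all",
    "read_histories",
    "write_histories",
]

#: CSV column order for event-history tables.
CSV_COLUMNS = (
    "subject_id",
    "t_gvhd1",
    "t_res1",
    "t_gvhd2",
    "t_res2",
    "t_fail",
    "t_censor",
)

# GVHD-related fields in path order: a later event requires all earlier ones.
_PATH_FIELDS = ("t_gvhd1", "t_res1", "t_gvhd2", "t_res2")


class HistoryError(ValueError):
    """Raised when a subject history violates the multistate-path invariants."""

    def __init__(self, subject_id, message: str):
        self.subject_id = subject_id
        super().__init__(f"subject {subject_id!r}: {message}")


@dataclass(frozen=True)
class SubjectHistory:
    """Raw event times of one subject on the ten-state diagram.

    Absent events are ``None``.  Exactly one of ``t_fail`` / ``t_censor``
    terminates follow-up.
    """

    subject_id: object
    t_gvhd1: Optional[float] = None
    t_res1: Optional[float] = None
    t_gvhd2: Optional[float] = None
    t_res2: Optional[float] = None
    t_fail: Optional[float] = None
    t_censor: Optional[float] = None


@dataclass(frozen=True)
class EndpointRecord:
    """Observed times and event indicators for the five composite endpoints."""

    subject_id: object
    x: np.ndarray  # shape (5,), observed times X_1..X_5
    delta: np.ndarray  # shape (5,), 0/1 indicators


def _check_time(h: SubjectHistory, field: str) -> Optional[float]:
    t = getattr(h, field)
    if t is None:
        return None
    t = float(t)
    if not math.isfinite(t):
        raise HistoryError(h.subject_id, f"{field} is not finite")
    if t < 0:
        raise HistoryError(h.subject_id, f"negative time in {field}")
    return t


def validate_history(h: SubjectHistory) -> SubjectHistory:
    """Validate a subject history against the state-diagram invariants.

    Checks finiteness and non-negativity of all present times, the GVHD
    path order (strict, so zero-duration episodes are rejected), presence
    of earlier events for any later one, a unique follow-up terminator,
    and that no GVHD-related time exceeds the terminating time.  Failure
    may be tied with a GVHD time (failure dominates, the subject is
    placed in the corresponding absorbing state).

    Returns ``h`` unchanged if valid, raises :class:`HistoryError` otherwise.
    """
    times = {f: _check_time(h, f) for f in _PATH_FIELDS}
    t_fail = _check_time(h, "t_fail")
    t_censor = _check_time(h, "t_censor")

    if t_fail is None and t_censor is None:
        raise HistoryError(h.subject_id, "missing terminator: need t_fail or t_censor")
    if t_fail is not None and t_censor is not None:
        raise HistoryError(
            h.subject_id, "both t_fail and t_censor present; exactly one terminates follow-up"
        )

    prev_field = None
    for f in _PATH_FIELDS:
        t = times[f]
        if t is None:
            continue
        # a later event requires all earlier ones present
        for earlier in _PATH_FIELDS[: _PATH_FIELDS.index(f)]:
            if times[earlier] is None:
                raise HistoryError(
                    h.subject_id, f"later event requires earlier: {f} present but {earlier} absent"
                )
        if prev_field is not None and not times[prev_field] < t:
            raise HistoryError(
                h.subject_id,
                f"ordering violation: {prev_field}={times[prev_field]} not before {f}={t}",
            )
        prev_field = f

    terminator = t_fail if t_fail is not None else t_censor
    term_name = "t_fail" if t_fail is not None else "t_censor"
    for f in _PATH_FIELDS:
        t = times[f]
        if t is None:
            continue
        if t_fail is not None:
            if t > t_fail:
                raise HistoryError(
                    h.subject_id, f"ordering violation: {f}={t} after t_fail={t_fail}"
                )
        elif t > terminator:
            raise HistoryError(
                h.subject_id, f"ordering violation: {f}={t} after {term_name}={terminator}"
            )
    return h


def derive_endpoints(h: SubjectHistory, *, validate: bool = True) -> EndpointRecord:
    """Derive the five composite-endpoint observations for one subject.

    Latent endpoint times (absent components treated as +inf):

        T1 = min(t_gvhd1, t_fail); T2 = min(t_gvhd2, t_fail)
        T3 = min(t_res1,  t_fail); T4 = t_fail
        T5 = min(t_res2,  t_fail)

    Each is censored at ``t_censor`` when the minimum is not observed.
    """
    if validate:
        validate_history(h)
    inf = math.inf
    g1 = h.t_gvhd1 if h.t_gvhd1 is not None else inf
    r1 = h.t_res1 if h.t_res1 is not None else inf
    g2 = h.t_gvhd2 if h.t_gvhd2 is not None else inf
    r2 = h.t_res2 if h.t_res2 is not None else inf
    fail = h.t_fail if h.t_fail is not None else inf
    z = h.t_censor if h.t_censor is not None else inf

    latent = np.array(
        [min(g1, fail), min(g2, fail), min(r1, fail), fail, min(r2, fail)], dtype=float
    )
    delta = (latent <= z).astype(np.int8)
    x = np.minimum(latent, z)
    return EndpointRecord(subject_id=h.subject_id, x=x, delta=delta)


def derive_all(histories: Iterable[SubjectHistory]) -> list[EndpointRecord]:
    """Validate and derive endpoint records for a whole cohort."""
    return [derive_endpoints(h) for h in histories]


def _parse_cell(value: str, field: str, row_idx: int) -> Optional[float]:
    value = value.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValueError(f"malformed row {row_idx}: cannot parse {field}={value!r}") from exc


def read_histories(path, *, delimiter: str = ",", validate: bool = True) -> list[SubjectHistory]:
    """Read an event-history table (one subject per row, empty cell = absent).

    The header must contain the columns ``subject_id, t_gvhd1, t_res1,
    t_gvhd2, t_res2, t_fail, t_censor``; extra columns are ignored.
    Raises on malformed rows (with row index) and duplicate subject ids.
    """
    histories: list[SubjectHistory] = []
    seen: set = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return []
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        for idx, row in enumerate(reader, start=1):
            sid = row["subject_id"]
            if sid in seen:
                raise ValueError(f"duplicate subject_id {sid!r} at row {idx}")
            seen.add(sid)
            kwargs = {
                f: _parse_cell(row[f] if row[f] is not None else "", f, idx)
                for f in CSV_COLUMNS[1:]
            }
            h = SubjectHistory(subject_id=sid, **kwargs)
            if validate:
                validate_history(h)
            histories.append(h)
    return histories


def write_histories(path, histories: Sequence[SubjectHistory], *, delimiter: str = ",") -> None:
    """Write an event-history table; round-trips with :func:`read_histories`."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(CSV_COLUMNS)
        for h in histories:
            row = [h.subject_id]
            for f in CSV_COLUMNS[1:]:
                t = getattr(h, f)
                row.append("" if t is None else repr(float(t)))
            writer.writerow(row)
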