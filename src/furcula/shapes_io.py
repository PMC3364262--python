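"""Reading, writing and standardizing digitized outline curves.

Outlines arrive either as TPS digitization files (one ``LM=``/``POINTS=``
block per specimen, the dialect written by tpsDig for 2-D landmarks) or as
long-format CSV.  Curves are oriented left-to-right and resampled to a fixed
number of equally spaced pseudolandmarks before any shape analysis; optional
landmarks split a curve into homologous segments that are resampled
independently so the landmarks survive exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Curve definitions exercised by the sensitivity analysis.
CURVE_DEFINITIONS = (
    "inside",
    "inside_no_hypocleideum",
    "outside",
    "full_outline",
    "anterior_edge",
)

VIEWS = ("profile", "lateral")

DEFAULT_N_POINTS = 100

CSV_COLUMNS = ["specimen_id", "view", "point_index", "x", "y", "is_landmark"]


class OutlineFormatError(ValueError):
    """Raised when an outline file violates its declared format."""


@dataclass(frozen=True)
class OutlineCurve:
    """An ordered 2-D digitized curve for one specimen in one view.

    ``landmark_indices`` mark segment boundaries (interior points only);
    an empty tuple means the curve is a single segment.
    """

    specimen_id: str
    view: str
    points: np.ndarray  # (n, 2) float
    landmark_indices: tuple[int, ...] = ()
    curve_definition: str = "inside"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(pts) < 3:
            raise ValueError(f"{self.specimen_id}: need >=3 points, got {len(pts)}")
        seg = np.diff(pts, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError(f"{self.specimen_id}: consecutive duplicate points")
        if self.view not in VIEWS:
            raise ValueError(f"unknown view {self.view!r}")
        li = tuple(int(i) for i in self.landmark_indices)
        if any(b <= a for a, b in zip(li, li[1:])):
            raise ValueError("landmark_indices must be strictly increasing")
        if li and (li[0] < 0 or li[-1] >= len(pts)):
            raise ValueError("landmark index out of range")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "landmark_indices", li)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PseudolandmarkSet:
    """Equally spaced resampling of an outline curve."""

    specimen_id: str
    view: str
    points: np.ndarray
    n_points: int
    landmark_indices: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if len(pts) != self.n_points:
            raise ValueError("points length disagrees with n_points")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "landmark_indices", tuple(int(i) for i in self.landmark_indices))


# ---------------------------------------------------------------------------
# TPS reading


def _parse_tps_records(lines: list[str]) -> Iterable[dict]:
    rec: dict | None = None
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key = key.upper()
        if key in ("LM", "POINTS"):
            if rec is not None:
                yield rec
            rec = {"declared": int(value), "coords": [], "id": None, "image": None}
        elif rec is None:
            raise OutlineFormatError(f"coordinate or metadata line before LM=: {line!r}")
        elif key == "ID":
            rec["id"] = value.strip()
        elif key == "IMAGE":
            rec["image"] = value.strip()
        elif key in ("CURVES", "SCALE", "COMMENT", "VARIABLES"):
            # SCALE is deliberately ignored: the turning-angle transform is
            # scale-free and image scale is not available for all specimens.
            continue
        else:
            parts = line.split()
            if len(parts) == 2:
                try:
                    rec["coords"].append((float(parts[0]), float(parts[1])))
                    continue
                except ValueError:
                    pass
            raise OutlineFormatError(f"unparseable TPS line: {line!r}")
    if rec is not None:
        yield rec


def read_tps(
    path: str | Path,
    view: str = "profile",
    curve_definition: str = "inside",
    flip_y: bool = False,
) -> list[OutlineCurve]:
    """Read a TPS digitization file into a list of :class:`OutlineCurve`.

    Specimen ids come from ``ID=`` lines, falling back to ``IMAGE=`` and
    finally to the running record index.  ``flip_y`` negates y to convert
    image-origin coordinates to the mathematical y-up convention.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    if not any(ln.strip() for ln in lines):
        raise OutlineFormatError(f"{path}: empty TPS file")
    curves: list[OutlineCurve] = []
    for idx, rec in enumerate(_parse_tps_records(lines)):
        if len(rec["coords"]) != rec["declared"]:
            name = rec["id"] or rec["image"] or str(idx)
            raise OutlineFormatError(
                f"record {name!r}: declared {rec['declared']} points, "
                f"parsed {len(rec['coords'])}"
            )
        pts = np.array(rec["coords"], dtype=float)
        if flip_y:
            pts = pts * np.array([1.0, -1.0])
            logger.info("flipped y for TPS record %d", idx)
        sid = rec["id"] or rec["image"] or str(idx)
        curves.append(
            OutlineCurve(specimen_id=sid, view=view, points=pts, curve_definition=curve_definition)
        )
    return curves


# ---------------------------------------------------------------------------
# CSV round trip


def write_outlines_csv(curves: Sequence[OutlineCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        lm = set(c.landmark_indices)
        for i, (x, y) in enumerate(c.points):
            rows.append((c.specimen_id, c.view, i, x, y, int(i in lm)))
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_outlines_csv(path: str | Path, curve_definition: str = "inside") -> list[OutlineCurve]:
    df = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(df.columns)
    if missing:
        raise OutlineFormatError(f"{path}: missing columns {sorted(missing)}")
    curves = []
    for (sid, view), grp in df.groupby(["specimen_id", "view"], sort=False):
        grp = grp.sort_values("point_index")
        pts = grp[["x", "y"]].to_numpy(dtype=float)
        lms = tuple(int(i) for i in np.flatnonzero(grp["is_landmark"].to_numpy()))
        curves.append(
            OutlineCurve(
                specimen_id=str(sid),
                view=str(view),
                points=pts,
                landmark_indices=lms,
                curve_definition=curve_definition,
            )
        )
    return curves


# ---------------------------------------------------------------------------
# Orientation and resampling


def orient_standard(curve: OutlineCurve, tol: float = 1e-12) -> OutlineCurve:
    """Ensure the trace runs left to right, reversing the point order if needed.

    Degenerate (vertical) curves are tie-broken by y: the smaller-y end comes
    first.  Reversal remaps landmark index ``i`` to ``n - 1 - i``.
    """
    first, last = curve.points[0], curve.points[-1]
    dx = last[0] - first[0]
    if abs(dx) <= tol:
        logger.info("%s: vertical curve, orienting by y", curve.specimen_id)
        forward = first[1] <= last[1]
    else:
        forward = dx > 0
    if forward:
        return curve
    n = curve.n_points
    lms = tuple(sorted(n - 1 - i for i in curve.landmark_indices))
    return replace(curve, points=curve.points[::-1].copy(), landmark_indices=lms)


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    """Place n points at equal arc-length steps along a polyline."""
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise ValueError("zero total arc length")
    targets = np.linspace(0.0, total, n)
    x = np.interp(targets, cum, pts[:, 0])
    y = np.interp(targets, cum, pts[:, 1])
    out = np.column_stack([x, y])
    out[0], out[-1] = pts[0], pts[-1]
    return out


def _largest_remainder(weights: np.ndarray, total: int, minimum: int) -> np.ndarray:
    """Integer budgets proportional to weights, summing exactly to total."""
    k = len(weights)
    if total < minimum * k:
        raise ValueError(f"cannot place {total} points over {k} segments (min {minimum})")
    raw = weights / weights.sum() * total
    floors = np.maximum(np.floor(raw).astype(int), minimum)
    # shrink any overshoot from the largest allocations first
    while floors.sum() > total:
        order = np.argsort(raw - floors)  # most over-allocated first
        for i in order:
            if floors[i] > minimum and floors.sum() > total:
                floors[i] -= 1
        if np.all(floors == minimum):
            break
    rema = raw - floors
    deficit = total - floors.sum()
    for i in np.argsort(-rema)[:max(deficit, 0)]:
        floors[i] += 1
    return floors


def resample_equal_arclength(
    curve: OutlineCurve, n_points: int = DEFAULT_N_POINTS
) -> PseudolandmarkSet:
    """Resample a curve to ``n_points`` pseudolandmarks equally spaced in arc length.

    With landmarks present, each landmark-bounded segment receives a point
    budget proportional to its arc length (largest-remainder rounding,
    minimum 2) and the landmarks themselves are retained exactly.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pts = curve.points
    if not curve.landmark_indices:
        return PseudolandmarkSet(curve.specimen_id, curve.view, _resample_polyline(pts, n_points), n_points)

    bounds = [0, *curve.landmark_indices, len(pts) - 1]
    seg_pts = [pts[a : b + 1] for a, b in zip(bounds, bounds[1:])]
    lengths = np.array(
        [np.linalg.norm(np.diff(s, axis=0), axis=1).sum() for s in seg_pts]
    )
    if lengths.sum() <= 0:
        raise ValueError("zero total arc length")
    # shared boundary points counted once: budget in "own" points per segment,
    # where every segment owns its right endpoint and the first also owns its left
    budgets = _largest_remainder(lengths, n_points + len(seg_pts) - 1, 2)
    pieces = []
    new_landmarks = []
    pos = 0
    for j, (s, b) in enumerate(zip(seg_pts, budgets)):
        rs = _resample_polyline(s, int(b))
        if j == 0:
            pieces.append(rs)
            pos += len(rs)
        else:
            new_landmarks.append(pos - 1)
            pieces.append(rs[1:])
            pos += len(rs) - 1
    out = np.vstack(pieces)
    return PseudolandmarkSet(
        curve.specimen_id, curve.view, out, n_points, tuple(new_landmarks)
    )
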