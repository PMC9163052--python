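"""Template/penalty similarity score of dish snapshots.

The initial pattern defines two d x d integer filters: the *template* is +1
on the A-territory, -1 on the B-territory and 0 elsewhere; the *penalty* is
1 outside the dish.  A snapshot is encoded to the same alphabet (+1 where an
A cell sits, -1 for B, 0 otherwise), zero-padded to 2d x 2d, and both filters
are slid across it; each offset i yields the inner products t_i (template)
and p_i (penalty) and the shot's raw score is max_i (t_i - p_i).  Scores are
normalized by the raw score of the initial configuration, clamped to [0, 1],
so a value of 1 means "indistinguishable from the intended pattern".

The default sweep moves the filters along one axis through d+1 offsets with
the perpendicular offset centred — the offset count the construction above
implies for a d-wide filter in a 2d frame; ``sweep="full"`` maximizes over
all (d+1)^2 two-dimensional offsets instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dish import OUTSIDE, REGION_A, REGION_B, Dish
from .params import CellType

__all__ = [
    "FilterPair",
    "ScoreSeries",
    "build_filters",
    "encode_shot",
    "encode_and_pad",
    "score_shot",
    "normalize",
    "score_trajectory",
]


@dataclass(frozen=True)
class FilterPair:
    template: np.ndarray  # int (d, d): +1 A-territory, -1 B-territory, 0 outside
    penalty: np.ndarray   # int (d, d): 1 outside the dish, 0 inside

    @property
    def d(self) -> int:
        return self.template.shape[0]


@dataclass(frozen=True)
class ScoreSeries:
    times: np.ndarray
    raw: np.ndarray
    normalized: np.ndarray
    reference: float

    def save(self, path) -> None:
        np.savetxt(path, np.column_stack([self.times, self.raw, self.normalized]),
                   header="time raw normalized", fmt="%.6g")


def build_filters(dish: Dish) -> FilterPair:
    """Template/penalty filters of a dish's target pattern."""
    region = dish.region
    if region.shape[0] != region.shape[1]:
        raise ValueError("scoring expects a square dish frame")
    if not ((region == REGION_A) | (region == REGION_B) | (region == OUTSIDE)).all():
        raise ValueError("dish region labels must partition into A/B/outside")
    template = np.zeros(region.shape, dtype=np.int64)
    template[region == REGION_A] = 1
    template[region == REGION_B] = -1
    penalty = (region == OUTSIDE).astype(np.int64)
    return FilterPair(template=template, penalty=penalty)


def encode_shot(cells: np.ndarray) -> np.ndarray:
    """Snapshot encoding: +1 at A cells, -1 at B cells, 0 elsewhere."""
    out = np.zeros(cells.shape, dtype=np.int64)
    out[cells == CellType.A] = 1
    out[cells == CellType.B] = -1
    return out


def encode_and_pad(cells: np.ndarray) -> np.ndarray:
    """Encoded snapshot zero-padded to a 2d x 2d frame (centre block = shot)."""
    if cells.shape[0] != cells.shape[1]:
        raise ValueError("shots must be square")
    d = cells.shape[0]
    lo = d // 2
    hi = d - lo
    return np.pad(encode_shot(cells), ((lo, hi), (lo, hi)))


def score_shot(padded: np.ndarray, filters: FilterPair, sweep: str = "horizontal") -> int:
    """Raw similarity of one padded shot: max over offsets of t_i - p_i."""
    d = filters.d
    if padded.shape != (2 * d, 2 * d):
        raise ValueError(f"padded shot must be {2 * d}x{2 * d}, got {padded.shape}")
    r0 = d // 2
    best = None
    if sweep == "horizontal":
        offsets = (((r0, j) for j in range(d + 1)))
    elif sweep == "full":
        offsets = ((i, j) for i in range(d + 1) for j in range(d + 1))
    else:
        raise ValueError("sweep must be 'horizontal' or 'full'")
    for i, j in offsets:
        window = padded[i:i + d, j:j + d]
        t = int(np.sum(filters.template * window))
        p = int(np.sum(filters.penalty * window))
        if best is None or t - p > best:
            best = t - p
    return int(best)


def normalize(raw, reference: float) -> np.ndarray:
    """Normalized score: raw / reference clamped to [0, 1].

    ``reference`` is the raw score of the initial configuration, so the
    series reads as similarity to the intended pattern.
    """
    if reference <= 0:
        raise ValueError("reference score must be > 0")
    return np.clip(np.asarray(raw, dtype=float) / reference, 0.0, 1.0)


def score_trajectory(traj, filters: FilterPair | None = None,
                     sweep: str = "horizontal") -> ScoreSeries:
    """Score every snapshot of a trajectory against the initial pattern."""
    if filters is None:
        filters = build_filters(traj.final)  # region labels are time-invariant
    raw = np.array([score_shot(encode_and_pad(s), filters, sweep)
                    for s in traj.snapshots], dtype=float)
    reference = raw[0]
    return ScoreSeries(times=traj.times.copy(), raw=raw,
                       normalized=normalize(raw, reference), reference=float(reference))
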