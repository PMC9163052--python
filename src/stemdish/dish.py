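"""Dish geometry, pattern initialization, occupancy bookkeeping and injuries.

The dish is a square lattice of meshes, at most one cell per mesh.  A
validity mask marks the in-dish meshes; every valid mesh belongs to one of
two target regions (A-territory or B-territory) that define both the initial
occupancy of terminal cells and the template filter of the pattern score.
Built-in geometries: circle (inner disk + outer ring), square, rectangle and
triangle (inner region scaled by half), plus arbitrary label matrices read
from delimited text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import CellType
from .switches import BasinMap, basin_map, sample_from_basin
from .params import BistableParams, TristableParams

__all__ = [
    "Dish",
    "Cell",
    "PatternSpec",
    "InjurySpec",
    "build_dish",
    "neighbors",
    "random_empty_mesh",
    "apply_injury",
    "region_matrix",
    "load_labels",
    "save_labels",
    "save_snapshot",
    "load_snapshot",
    "circular_region",
    "rect_region",
]

#: region codes in label matrices
OUTSIDE, REGION_A, REGION_B = 0, 1, 2

#: initial signal load of a mesh in its own territory ("almost 100" molecules)
INITIAL_SIGNAL = 100


@dataclass
class Cell:
    """A snapshot view of one lattice occupant."""

    fate: CellType
    x: int = 0
    y: int = 0
    divisions: int = 0


@dataclass(frozen=True)
class PatternSpec:
    """Dish geometry and initial-pattern specification.

    ``dish_size`` is the radius (circle) or side length (polygons) in meshes;
    ``inner_size`` the radius/side of the central A-territory.  ``labels``
    overrides the built-in geometries with an explicit region matrix
    (codes 0 outside, 1 A-territory, 2 B-territory).
    """

    geometry: str = "circle"
    dish_size: int = 50
    inner_size: int = 25
    dividing_fraction_s: float = 1.0 / 30.0
    dividing_fraction_p: float = 1.0 / 15.0
    labels: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.geometry not in ("circle", "square", "rectangle", "triangle", "labelfile"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.geometry == "labelfile":
            if self.labels is None:
                raise ValueError("geometry 'labelfile' requires a labels matrix")
        else:
            if self.dish_size < 2:
                raise ValueError("dish_size must be >= 2 meshes")
            if not (0 < self.inner_size <= self.dish_size):
                raise ValueError("inner region must be non-empty and inside the dish")
        for frac in (self.dividing_fraction_s, self.dividing_fraction_p):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("dividing fractions must lie in [0, 1]")
        if self.dividing_fraction_s + self.dividing_fraction_p > 1.0:
            raise ValueError("dividing fractions must sum to <= 1")


@dataclass(frozen=True)
class InjurySpec:
    """A one-shot removal of every cell in ``region`` (a boolean mesh mask),
    fired when the mean progenitor division counter reaches ``trigger``.
    Signal molecules in the region are left in place and decay away."""

    region: np.ndarray
    trigger: float

    def __post_init__(self):
        if self.region.dtype != bool:
            object.__setattr__(self, "region", self.region.astype(bool))
        if self.trigger < 0:
            raise ValueError("injury trigger must be >= 0")


def circular_region(shape: tuple[int, int], center: tuple[float, float],
                    radius: float) -> np.ndarray:
    rows, cols = np.indices(shape)
    return (rows - center[0]) ** 2 + (cols - center[1]) ** 2 <= radius ** 2


def rect_region(shape: tuple[int, int], top_left: tuple[int, int],
                size: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    r0, c0 = top_left
    mask[r0:r0 + size[0], c0:c0 + size[1]] = True
    return mask


# ---------------------------------------------------------------------------
# region matrices for the built-in geometries

def region_matrix(spec: PatternSpec) -> np.ndarray:
    """The (d, d) region-label matrix of a pattern spec."""
    if spec.geometry == "labelfile":
        labels = np.asarray(spec.labels, dtype=np.int8)
        if labels.ndim != 2 or labels.shape[0] != labels.shape[1]:
            raise ValueError("label matrix must be square")
        if not np.isin(labels, (OUTSIDE, REGION_A, REGION_B)).all():
            raise ValueError("label matrix entries must be 0 (outside), 1 (A) or 2 (B)")
        return labels.copy()

    if spec.geometry == "circle":
        d = 2 * spec.dish_size + 1
        c = spec.dish_size
        region = np.zeros((d, d), dtype=np.int8)
        dish = circular_region((d, d), (c, c), spec.dish_size)
        inner = circular_region((d, d), (c, c), spec.inner_size)
        region[dish] = REGION_B
        region[inner & dish] = REGION_A
        return region

    d = spec.dish_size
    region = np.zeros((d, d), dtype=np.int8)
    if spec.geometry == "square":
        region[:, :] = REGION_B
        lo = (d - spec.inner_size) // 2
        region[lo:lo + spec.inner_size, lo:lo + spec.inner_size] = REGION_A
    elif spec.geometry == "rectangle":
        # a 2:1 rectangle centred in a d x d frame with a half-size inner block
        h = max(d // 2, 1)
        r0 = (d - h) // 2
        region[r0:r0 + h, :] = REGION_B
        ih, iw = max(h // 2, 1), max(spec.inner_size, 1)
        region[r0 + (h - ih) // 2: r0 + (h - ih) // 2 + ih,
               (d - iw) // 2: (d - iw) // 2 + iw] = REGION_A
    else:  # triangle: apex at the top centre, base along the bottom edge
        rows, cols = np.indices((d, d))
        half = (d - 1) / 2.0
        frac = rows / max(d - 1, 1)  # 0 at apex row, 1 at base
        inside = np.abs(cols - half) <= frac * half
        region[inside] = REGION_B
        # inner triangle: same shape, half linear size, anchored at 2/3 height
        scale = spec.inner_size / spec.dish_size
        rr = (rows - (1 - scale) * (d - 1) * 2 / 3) / max(scale * (d - 1), 1)
        inner = (np.abs(cols - half) <= rr * scale * half) & (rr >= 0) & (rr <= 1)
        region[inner & inside] = REGION_A
    return region


# ---------------------------------------------------------------------------
# the dish container

class Dish:
    """Square lattice with a validity mask, occupants and signal counts.

    Attributes are plain numpy arrays of shape (d, d): ``cell_type`` (CellType
    codes), determinant counts ``x``/``y``, per-cell division counters
    ``divisions``, signal counts ``s1``/``s2``, the boolean ``valid`` mask and
    the region labels ``region``.
    """

    def __init__(self, region: np.ndarray):
        region = np.asarray(region, dtype=np.int8)
        self.region = region
        self.valid = region != OUTSIDE
        d = region.shape[0]
        self.cell_type = np.zeros((d, region.shape[1]), dtype=np.int8)
        self.x = np.zeros_like(self.cell_type, dtype=np.int64)
        self.y = np.zeros_like(self.x)
        self.divisions = np.zeros_like(self.x)
        self.s1 = np.zeros_like(self.x)
        self.s2 = np.zeros_like(self.x)

    # -- shape ------------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_type.shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    # -- occupancy ---------------------------------------------------------
    def cell_at(self, mesh: tuple[int, int]) -> Cell | None:
        r, c = mesh
        t = self.cell_type[r, c]
        if t == CellType.EMPTY:
            return None
        return Cell(CellType(int(t)), int(self.x[r, c]), int(self.y[r, c]),
                    int(self.divisions[r, c]))

    def counts(self) -> dict[CellType, int]:
        out = {}
        for t in (CellType.S, CellType.P, CellType.A, CellType.B):
            out[t] = int(np.count_nonzero(self.cell_type == t))
        return out

    def check_invariants(self) -> None:
        """Raise if occupancy/signal bookkeeping is inconsistent."""
        bad = ~self.valid
        if self.cell_type[bad].any():
            raise AssertionError("occupant on an invalid mesh")
        if self.s1[bad].any() or self.s2[bad].any():
            raise AssertionError("signal molecules outside the dish")
        for arr, name in ((self.x, "x"), (self.y, "y"), (self.s1, "s1"),
                          (self.s2, "s2"), (self.divisions, "divisions")):
            if (arr < 0).any():
                raise AssertionError(f"negative {name} count")

    def copy(self) -> "Dish":
        clone = Dish(self.region.copy())
        for name in ("cell_type", "x", "y", "divisions", "s1", "s2"):
            setattr(clone, name, getattr(self, name).copy())
        return clone

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dish):
            return NotImplemented
        return all(np.array_equal(getattr(self, a), getattr(other, a))
                   for a in ("region", "cell_type", "x", "y", "divisions", "s1", "s2"))


def neighbors(mesh: tuple[int, int], dish: Dish, kind: str = "orthogonal4"):
    """In-dish neighbours of a mesh; 4-adjacency for diffusion, 8 for placement."""
    r, c = mesh
    if not dish.valid[r, c]:
        raise ValueError(f"mesh {mesh} is outside the dish")
    if kind == "orthogonal4":
        offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    elif kind == "full8":
        offsets = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
    else:
        raise ValueError("kind must be 'orthogonal4' or 'full8'")
    h, w = dish.shape
    out = []
    for dr, dc in offsets:
        rr, cc = r + dr, c + dc
        if 0 <= rr < h and 0 <= cc < w and dish.valid[rr, cc]:
            out.append((rr, cc))
    return out


def random_empty_mesh(dish: Dish, rng: np.random.Generator):
    """Uniform draw over empty valid meshes; None when the dish is full."""
    rows, cols = np.nonzero(dish.valid & (dish.cell_type == CellType.EMPTY))
    if rows.size == 0:
        return None
    i = rng.integers(rows.size)
    return int(rows[i]), int(cols[i])


def build_dish(spec: PatternSpec, rng: np.random.Generator,
               stem_params: BistableParams | None = None,
               prog_params: TristableParams | None = None,
               stem_basins: BasinMap | None = None,
               prog_basins: BasinMap | None = None) -> Dish:
    """Initialize a dish in its target pattern.

    Terminal cells fill their territories (A inside, B outside) and each mesh
    starts loaded with 100 molecules of its own territory's signal.  Dividing
    cells are then scattered uniformly over the dish at the spec fractions,
    their determinants drawn from the matching attractor basins of the
    signal-free switches.
    """
    region = region_matrix(spec)
    dish = Dish(region)
    dish.cell_type[region == REGION_A] = CellType.A
    dish.cell_type[region == REGION_B] = CellType.B
    dish.s1[region == REGION_A] = INITIAL_SIGNAL
    dish.s2[region == REGION_B] = INITIAL_SIGNAL

    rows, cols = np.nonzero(dish.valid)
    n_valid = rows.size
    n_s = int(round(spec.dividing_fraction_s * n_valid))
    n_p = int(round(spec.dividing_fraction_p * n_valid))
    if n_s + n_p == 0:
        return dish

    if stem_basins is None:
        stem_basins = basin_map("stem", stem_params or BistableParams())
    if prog_basins is None:
        prog_basins = basin_map("progenitor", prog_params or TristableParams())

    chosen = rng.choice(n_valid, size=n_s + n_p, replace=False)
    for i, idx in enumerate(chosen):
        r, c = int(rows[idx]), int(cols[idx])
        if i < n_s:
            dish.cell_type[r, c] = CellType.S
            x, y = sample_from_basin(stem_basins, CellType.S, rng)
        else:
            dish.cell_type[r, c] = CellType.P
            x, y = sample_from_basin(prog_basins, CellType.P, rng)
        dish.x[r, c] = x
        dish.y[r, c] = y
        dish.divisions[r, c] = 0
    return dish


def apply_injury(dish: Dish, spec: InjurySpec) -> Dish:
    """Remove every occupant in the injury region (in place).

    Signal molecules are left untouched; decay and diffusion erase them.
    """
    if spec.region.shape != dish.shape:
        raise ValueError("injury region mask must match the dish shape")
    hit = spec.region & dish.valid & (dish.cell_type != CellType.EMPTY)
    dish.cell_type[hit] = CellType.EMPTY
    dish.x[hit] = 0
    dish.y[hit] = 0
    dish.divisions[hit] = 0
    return dish


# ---------------------------------------------------------------------------
# delimited-text IO

def save_labels(path, labels: np.ndarray) -> None:
    np.savetxt(path, np.asarray(labels, dtype=int), fmt="%d")


def load_labels(path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int8, ndmin=2)


def save_snapshot(path, dish: Dish, seed: int | None = None) -> None:
    """Dish state as three stacked integer matrices (cells, s1, s2)."""
    path = Path(path)
    header = f"stemdish snapshot shape={dish.height}x{dish.width}"
    if seed is not None:
        header += f" seed={seed}"
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for name, arr in (("cells", dish.cell_type), ("s1", dish.s1), ("s2", dish.s2),
                          ("region", dish.region)):
            fh.write(f"# {name}\n")
            np.savetxt(fh, arr, fmt="%d")


def load_snapshot(path) -> Dish:
    blocks: dict[str, list[list[int]]] = {}
    current: list[list[int]] | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                tag = line[1:].strip()
                if tag in ("cells", "s1", "s2", "region"):
                    current = blocks.setdefault(tag, [])
                continue
            if current is not None:
                current.append([int(v) for v in line.split()])
    if "region" not in blocks or "cells" not in blocks:
        raise ValueError(f"{path} is not a stemdish snapshot")
    dish = Dish(np.array(blocks["region"], dtype=np.int8))
    dish.cell_type = np.array(blocks["cells"], dtype=np.int8)
    dish.s1 = np.array(blocks.get("s1", np.zeros(dish.shape)), dtype=np.int64)
    dish.s2 = np.array(blocks.get("s2", np.zeros(dish.shape)), dtype=np.int64)
    return dish
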