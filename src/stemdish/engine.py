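"""Exact stochastic simulation of the dish: 24 reaction channels.

The event loop itself is jit-compiled (:mod:`stemdish._kernel`); this module
prepares the flattened lattice state, the attractor tables used for fate
calling, and wraps the results in a :class:`Trajectory`.  It also exposes
single-event reference operations (:func:`divide_cell`, :func:`transform_cell`,
:func:`diffuse_signal`, :func:`total_propensity`, :func:`draw_event`) that act
on a :class:`~stemdish.dish.Dish` directly — the same semantics as the
compiled loop, convenient for inspection and unit testing.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .dish import Dish, InjurySpec, neighbors, random_empty_mesh
from .params import CellType, SimConfig
from .switches import (
    BasinMap,
    basin_map,
    classify_fate,
    iota_xs_of_n,
    sample_from_basin,
    signal_effect,
    _stable_fp_arrays,
)

__all__ = [
    "ReactionChannel",
    "CHANNELS",
    "EventLog",
    "Trajectory",
    "total_propensity",
    "draw_event",
    "divide_cell",
    "transform_cell",
    "diffuse_signal",
    "run",
]


# ---------------------------------------------------------------------------
# channel registry (ids follow the published rate-table rows)

@dataclass(frozen=True)
class ReactionChannel:
    id: int
    name: str
    scope: str  # per-S-cell | per-P-cell | per-A-cell | per-B-cell | per-mesh


CHANNELS: tuple[ReactionChannel, ...] = (
    ReactionChannel(1, "X_s production", "per-S-cell"),
    ReactionChannel(2, "X_s degradation", "per-S-cell"),
    ReactionChannel(3, "Y_s production", "per-S-cell"),
    ReactionChannel(4, "Y_s degradation", "per-S-cell"),
    ReactionChannel(5, "S division", "per-S-cell"),
    ReactionChannel(6, "S death", "per-S-cell"),
    ReactionChannel(7, "S transformation", "per-S-cell"),
    ReactionChannel(8, "S movement", "per-S-cell"),
    ReactionChannel(9, "X_p production", "per-P-cell"),
    ReactionChannel(10, "X_p degradation", "per-P-cell"),
    ReactionChannel(11, "Y_p production", "per-P-cell"),
    ReactionChannel(12, "Y_p degradation", "per-P-cell"),
    ReactionChannel(13, "P division", "per-P-cell"),
    ReactionChannel(14, "P death", "per-P-cell"),
    ReactionChannel(15, "P transformation", "per-P-cell"),
    ReactionChannel(16, "P movement", "per-P-cell"),
    ReactionChannel(17, "A death", "per-A-cell"),
    ReactionChannel(18, "B death", "per-B-cell"),
    ReactionChannel(19, "S1 production", "per-mesh"),
    ReactionChannel(20, "S1 degradation", "per-mesh"),
    ReactionChannel(21, "S2 production", "per-mesh"),
    ReactionChannel(22, "S2 degradation", "per-mesh"),
    ReactionChannel(23, "S1 diffusion", "per-mesh"),
    ReactionChannel(24, "S2 diffusion", "per-mesh"),
)

#: event-counter keys, in the order the kernel reports them
COUNTER_KEYS = (
    "eta", "eta_S", "eta_P", "gamma_S", "w_P", "w_S", "gamma_P",
    "lambda_P", "lambda_A", "lambda_B", "mu_d", "mu_A", "mu_B",
    "gamma_A", "gamma_B",
    "move_S", "move_P",
    "s1_prod", "s1_deg", "s2_prod", "s2_deg", "s1_diff", "s2_diff",
    "xs_prod", "xs_deg", "ys_prod", "ys_deg",
    "xp_prod", "xp_deg", "yp_prod", "yp_deg",
)


@dataclass
class EventLog:
    """Population-level event counts plus integrated cell-time exposures.

    ``counts`` holds one entry per mean-field channel (division outcomes,
    deaths, transformations, ...); ``exposure`` the time integrals of the
    S/P/A/B abundances, so count/exposure is the maximum-likelihood constant
    rate of a per-cell channel.
    """

    counts: dict[str, int] = field(default_factory=dict)
    exposure: dict[str, float] = field(default_factory=dict)


@dataclass
class Trajectory:
    """Result of one SSA run: evenly spaced snapshots plus summaries."""

    times: np.ndarray            # (n_shots,)
    snapshots: np.ndarray        # int8 (n_shots, H, W) CellType codes
    abundances: np.ndarray       # int64 (n_shots, 4) -> n_S, n_P, n_A, n_B
    mean_divisions: np.ndarray   # (n_shots,)
    log: EventLog
    final: Dish
    status: str
    t_final: float
    n_events: int
    config: SimConfig

    def abundance_table(self) -> np.ndarray:
        """Columns (time, n_S, n_P, n_A, n_B) for delimited-text export."""
        return np.column_stack([self.times, self.abundances])

    def save_abundances(self, path) -> None:
        np.savetxt(path, self.abundance_table(),
                   header="time n_S n_P n_A n_B", fmt="%.6g")


# ---------------------------------------------------------------------------
# parameter packing and cached attractor tables

def _pack_params(config: SimConfig, n0: float) -> np.ndarray:
    prm = np.zeros(_kernel.N_PRM, dtype=np.float64)
    st, pg, sg, se = config.stem, config.progenitor, config.signal, config.signal_effect
    prm[_kernel.P_IOTA_XS] = st.iota_x
    prm[_kernel.P_IOTA_YS] = st.iota_y
    prm[_kernel.P_BSN] = st.beta ** st.hill_n
    prm[_kernel.P_HN_S] = st.hill_n
    prm[_kernel.P_G_S] = st.gamma
    prm[_kernel.P_AX] = pg.alpha_x
    prm[_kernel.P_AY] = pg.alpha_y
    prm[_kernel.P_IX] = pg.iota_x
    prm[_kernel.P_IY] = pg.iota_y
    prm[_kernel.P_BPN] = pg.beta ** pg.hill_n
    prm[_kernel.P_HN_P] = pg.hill_n
    prm[_kernel.P_G_P] = pg.gamma
    prm[_kernel.P_EA] = se.a
    prm[_kernel.P_EB] = se.b
    prm[_kernel.P_AS1] = sg.alpha_1
    prm[_kernel.P_AS2] = sg.alpha_2
    prm[_kernel.P_BGN] = sg.beta ** sg.hill_n
    prm[_kernel.P_HN_G] = sg.hill_n
    prm[_kernel.P_K] = sg.k
    prm[_kernel.P_DIFF] = sg.D / sg.h ** 2
    prm[_kernel.P_RS] = config.r_s
    prm[_kernel.P_GS] = config.gamma_s
    prm[_kernel.P_WP] = config.w_p
    prm[_kernel.P_MS] = config.m_s
    prm[_kernel.P_RP] = config.r_p
    prm[_kernel.P_GP] = config.gamma_p
    prm[_kernel.P_WS] = config.w_s
    prm[_kernel.P_MP] = config.m_p
    prm[_kernel.P_GA] = config.gamma_A
    prm[_kernel.P_GB] = config.gamma_B
    prm[_kernel.P_N0] = n0
    prm[_kernel.P_TERM] = config.termination_divisions
    prm[_kernel.P_SIG_ON] = 1.0 if config.signals_enabled else 0.0
    prm[_kernel.P_DIFF_COUNT] = 1.0 if config.diffusion_scales_with_count else 0.0
    prm[_kernel.P_DIFF_WEIGHTED] = 1.0 if config.diffusion_neighbor_rule == "weighted" else 0.0
    return prm


@functools.lru_cache(maxsize=8)
def _cached_basin_map(system: str, params) -> BasinMap:
    return basin_map(system, params)


@functools.lru_cache(maxsize=8)
def _prog_fp_tables(prog, eff):
    """Stable fixed points of the progenitor switch on the quantized eps grid.

    The signal effect takes b+1 distinct values per species (integer counts
    0..b then saturation), so the table covers (b+1)^2 coefficient pairs.
    """
    nb = int(eff.b) + 1
    fps = np.zeros((nb, nb, 3, 2), dtype=np.float64)
    nfp = np.zeros((nb, nb), dtype=np.int64)
    labels = np.full((nb, nb, 3), 2, dtype=np.int8)
    for i in range(nb):
        for j in range(nb):
            p = prog.with_eps(eff.a * i / eff.b, eff.a * j / eff.b)
            f, l = _stable_fp_arrays("progenitor", p)
            k = min(f.shape[0], 3)
            fps[i, j, :k] = f[:k]
            nfp[i, j] = k
            labels[i, j, :k] = l[:k]
    return fps, nfp, labels


def _neighbor_tables(dish: Dish):
    h, w = dish.shape
    N = h * w
    valid = dish.valid.ravel().astype(np.uint8)
    nbr4 = np.full((N, 4), -1, dtype=np.int64)
    n4 = np.zeros(N, dtype=np.int64)
    nbr8 = np.full((N, 8), -1, dtype=np.int64)
    n8 = np.zeros(N, dtype=np.int64)
    off4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
    off8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))
    for r in range(h):
        for c in range(w):
            m = r * w + c
            if not dish.valid[r, c]:
                continue
            k = 0
            for dr, dc in off4:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and dish.valid[rr, cc]:
                    nbr4[m, k] = rr * w + cc
                    k += 1
            n4[m] = k
            k = 0
            for dr, dc in off8:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and dish.valid[rr, cc]:
                    nbr8[m, k] = rr * w + cc
                    k += 1
            n8[m] = k
    return valid, nbr4, n4, nbr8, n8


# ---------------------------------------------------------------------------
# reference (single-event) operations on a Dish

def _eps_at(dish: Dish, mesh, config: SimConfig):
    if not config.signals_enabled:
        return 0.0, 0.0
    r, c = mesh
    return (signal_effect(int(dish.s1[r, c]), config.signal_effect),
            signal_effect(int(dish.s2[r, c]), config.signal_effect))


def _iota_now(dish: Dish, config: SimConfig) -> float:
    cnt = dish.counts()
    nd = cnt[CellType.S] + cnt[CellType.P]
    n0 = config.iota_calibration if config.iota_calibration is not None else max(nd, 1)
    return iota_xs_of_n(nd, base=config.stem.iota_x, scale=n0)


def total_propensity(dish: Dish, config: SimConfig | None = None):
    """Sum and per-(channel, mesh) table of all active propensities."""
    config = config or SimConfig()
    st, pg, sg = config.stem, config.progenitor, config.signal
    bsn = st.beta ** st.hill_n
    bpn = pg.beta ** pg.hill_n
    bgn = sg.beta ** sg.hill_n
    iota = _iota_now(dish, config)
    table: list[tuple[int, tuple[int, int], float]] = []
    rows, cols = np.nonzero(dish.valid)
    for r, c in zip(rows, cols):
        t = dish.cell_type[r, c]
        x, y = float(dish.x[r, c]), float(dish.y[r, c])
        if t == CellType.S:
            table.append((1, (r, c), iota * bsn / (bsn + y ** st.hill_n)))
            table.append((2, (r, c), st.gamma * x))
            table.append((3, (r, c), st.iota_y * bsn / (bsn + x ** st.hill_n)))
            table.append((4, (r, c), st.gamma * y))
            if any(dish.cell_type[nr, nc] == CellType.EMPTY
                   for nr, nc in neighbors((r, c), dish, "full8")):
                table.append((5, (r, c), config.r_s))
            table.append((6, (r, c), config.gamma_s))
            table.append((7, (r, c), config.w_p))
            table.append((8, (r, c), config.m_s))
        elif t == CellType.P:
            e1, e2 = _eps_at(dish, (r, c), config)
            xn, yn = x ** pg.hill_n, y ** pg.hill_n
            table.append((9, (r, c), (pg.alpha_x + e1) * xn / (bpn + xn)
                          + pg.iota_x * bpn / (bpn + yn)))
            table.append((10, (r, c), pg.gamma * x))
            table.append((11, (r, c), (pg.alpha_y + e2) * yn / (bpn + yn)
                          + pg.iota_y * bpn / (bpn + xn)))
            table.append((12, (r, c), pg.gamma * y))
            if any(dish.cell_type[nr, nc] == CellType.EMPTY
                   for nr, nc in neighbors((r, c), dish, "full8")):
                table.append((13, (r, c), config.r_p))
            table.append((14, (r, c), config.gamma_p))
            table.append((15, (r, c), config.w_s))
            table.append((16, (r, c), config.m_p))
        elif t == CellType.A:
            table.append((17, (r, c), config.gamma_A))
        elif t == CellType.B:
            table.append((18, (r, c), config.gamma_B))
        if config.signals_enabled:
            s1, s2 = float(dish.s1[r, c]), float(dish.s2[r, c])
            if t == CellType.A:
                table.append((19, (r, c), sg.alpha_1 * bgn / (bgn + s2 ** sg.hill_n)))
            if s1 > 0:
                table.append((20, (r, c), sg.k * s1))
            if t == CellType.B:
                table.append((21, (r, c), sg.alpha_2 * bgn / (bgn + s1 ** sg.hill_n)))
            if s2 > 0:
                table.append((22, (r, c), sg.k * s2))
            d_eff = sg.D / sg.h ** 2
            if s1 > 0:
                table.append((23, (r, c), d_eff * s1 if config.diffusion_scales_with_count else d_eff))
            if s2 > 0:
                table.append((24, (r, c), d_eff * s2 if config.diffusion_scales_with_count else d_eff))
    total = float(sum(p for _, _, p in table))
    if any(p < 0 for _, _, p in table):
        raise RuntimeError("negative propensity: internal invariant violated")
    return total, table


def draw_event(total: float, table, rng: np.random.Generator):
    """Gillespie draw: (waiting time, channel id, mesh)."""
    if total <= 0:
        raise RuntimeError("total propensity is zero: simulation deadlock")
    wait = rng.exponential(1.0 / total)
    u = rng.random() * total
    acc = 0.0
    for ch, mesh, p in table:
        acc += p
        if u < acc:
            return wait, ch, mesh
    ch, mesh, _ = table[-1]
    return wait, ch, mesh


def divide_cell(dish: Dish, mesh, rng: np.random.Generator,
                config: SimConfig | None = None):
    """Execute one division at ``mesh``; returns the two daughter fates.

    The mother's determinants are split Binomial(n, 1/2) between the
    daughters; one daughter keeps the mother's mesh, the other takes a
    uniformly chosen empty 8-neighbour.  Each daughter is fate-called on its
    own counts (stem mothers via the bistable basins; progenitor mothers via
    the tristable basins with the local signal-effect coefficients), and a
    daughter that crosses systems has its determinants re-drawn from its new
    basin.
    """
    config = config or SimConfig()
    r, c = mesh
    t = CellType(int(dish.cell_type[r, c]))
    if t not in (CellType.S, CellType.P):
        raise ValueError(f"mesh {mesh} does not hold a dividing cell")
    empties = [nb for nb in neighbors(mesh, dish, "full8")
               if dish.cell_type[nb] == CellType.EMPTY]
    if not empties:
        raise RuntimeError("division drawn with no empty placement neighbour")
    target = empties[rng.integers(len(empties))]

    x1 = int(rng.binomial(int(dish.x[r, c]), 0.5))
    x2 = int(dish.x[r, c]) - x1
    y1 = int(rng.binomial(int(dish.y[r, c]), 0.5))
    y2 = int(dish.y[r, c]) - y1
    mother_div = int(dish.divisions[r, c])

    fates, coords = [], []
    for (xx, yy), dst in (((x1, y1), mesh), ((x2, y2), target)):
        if t == CellType.S:
            lab = classify_fate(xx, yy, "stem", config.stem)
        else:
            e1, e2 = _eps_at(dish, dst, config)
            lab = classify_fate(xx, yy, "progenitor",
                                config.progenitor.with_eps(e1, e2))
        if lab == CellType.P and t == CellType.S:
            xx, yy = sample_from_basin(
                _cached_basin_map("progenitor", config.progenitor), CellType.P, rng)
        elif lab == CellType.S and t == CellType.P:
            xx, yy = sample_from_basin(
                _cached_basin_map("stem", config.stem), CellType.S, rng)
        fates.append(lab)
        coords.append((xx, yy))

    for lab, (xx, yy), dst in zip(fates, coords, (mesh, target)):
        rr, cc = dst
        dish.cell_type[rr, cc] = lab
        if lab in (CellType.S, CellType.P):
            dish.x[rr, cc] = xx
            dish.y[rr, cc] = yy
            dish.divisions[rr, cc] = (mother_div + 1
                                      if (t == CellType.P and lab == CellType.P) else 0)
        else:
            dish.x[rr, cc] = 0
            dish.y[rr, cc] = 0
            dish.divisions[rr, cc] = 0
    return tuple(fates)


def transform_cell(dish: Dish, mesh, rng: np.random.Generator,
                   config: SimConfig | None = None) -> None:
    """Flip S <-> P at ``mesh``, re-drawing determinants from the new basin."""
    config = config or SimConfig()
    r, c = mesh
    t = CellType(int(dish.cell_type[r, c]))
    if t == CellType.S:
        dish.cell_type[r, c] = CellType.P
        x, y = sample_from_basin(
            _cached_basin_map("progenitor", config.progenitor), CellType.P, rng)
    elif t == CellType.P:
        dish.cell_type[r, c] = CellType.S
        x, y = sample_from_basin(
            _cached_basin_map("stem", config.stem), CellType.S, rng)
    else:
        raise ValueError("only dividing cells transform")
    dish.x[r, c] = x
    dish.y[r, c] = y
    dish.divisions[r, c] = 0


def diffuse_signal(dish: Dish, mesh, species: int, rng: np.random.Generator,
                   config: SimConfig | None = None) -> None:
    """Hop one molecule of ``species`` (1 or 2) to an orthogonal neighbour."""
    config = config or SimConfig()
    arr = dish.s1 if species == 1 else dish.s2
    r, c = mesh
    if arr[r, c] < 1:
        raise ValueError(f"no S{species} molecule at {mesh}")
    nbrs = neighbors(mesh, dish, "orthogonal4")
    if not nbrs:
        return  # isolated mesh: logged no-op
    if config.diffusion_neighbor_rule == "weighted":
        w = np.array([1.0 + arr[nb] for nb in nbrs])
        target = nbrs[rng.choice(len(nbrs), p=w / w.sum())]
    else:
        target = nbrs[rng.integers(len(nbrs))]
    arr[r, c] -= 1
    arr[target] += 1


# ---------------------------------------------------------------------------
# the full run

_STATUS_NAMES = {
    _kernel.STATUS_OK: "terminated",
    _kernel.STATUS_DEADLOCK: "deadlock",
    _kernel.STATUS_EXTINCT: "extinct",
    _kernel.STATUS_MAX_EVENTS: "max-events",
}


def run(dish: Dish, config: SimConfig | None = None,
        injuries: tuple[InjurySpec, ...] = (), seed: int | None = None) -> Trajectory:
    """Simulate the dish until the mean progenitor division counter reaches
    ``config.termination_divisions``; returns a :class:`Trajectory` with
    ``config.n_shots`` evenly spaced snapshots.

    The input dish is not modified.  Injuries fire when the mean division
    counter crosses their triggers; termination waits until every injury has
    fired.
    """
    config = config or SimConfig()
    if seed is None:
        seed = config.seed
    dish = dish.copy()
    dish.check_invariants()
    h, w = dish.shape
    N = h * w

    ctype = dish.cell_type.ravel().copy()
    cx = dish.x.ravel().astype(np.int64).copy()
    cy = dish.y.ravel().astype(np.int64).copy()
    cdiv = dish.divisions.ravel().astype(np.int64).copy()
    s1 = dish.s1.ravel().astype(np.int64).copy()
    s2 = dish.s2.ravel().astype(np.int64).copy()
    if not config.signals_enabled:
        s1[:] = 0
        s2[:] = 0
    valid, nbr4, n4, nbr8, n8 = _neighbor_tables(dish)

    counts0 = dish.counts()
    nd0 = counts0[CellType.S] + counts0[CellType.P]
    n0 = config.iota_calibration if config.iota_calibration is not None else max(nd0, 1)
    prm = _pack_params(config, float(n0))

    stem_fps, stem_labels = _stable_fp_arrays("stem", config.stem)
    prog_fps, prog_nfp, prog_labels = _prog_fp_tables(config.progenitor,
                                                      config.signal_effect)
    stem_map = _cached_basin_map("stem", config.stem).labels
    prog_map = _cached_basin_map("progenitor", config.progenitor).labels

    inj = sorted(injuries, key=lambda s: s.trigger)
    inj_mask = np.zeros((len(inj), N), dtype=np.uint8)
    inj_trigger = np.zeros(len(inj), dtype=np.float64)
    for i, spec in enumerate(inj):
        if spec.region.shape != dish.shape:
            raise ValueError("injury region mask must match the dish shape")
        inj_mask[i] = spec.region.ravel().astype(np.uint8)
        inj_trigger[i] = spec.trigger

    buf = 2 * config.n_shots
    snaps = np.zeros((buf, N), dtype=np.int8)
    snap_t = np.zeros(buf, dtype=np.float64)
    snap_ab = np.zeros((buf, 4), dtype=np.int64)
    snap_md = np.zeros(buf, dtype=np.float64)
    counts = np.zeros(_kernel.N_COUNTS, dtype=np.int64)
    exposure = np.zeros(4, dtype=np.float64)

    # initial snapshot spacing; the buffer doubles it as the run extends
    snap_dt0 = max(config.termination_divisions / (config.r_p + 1e-12), 1e-3) / config.n_shots

    status, n_snap, t_final, n_events = _kernel.run_kernel(
        int(seed) % (2 ** 31), ctype, cx, cy, cdiv, s1, s2, valid,
        nbr4, n4, nbr8, n8, prm,
        stem_fps, stem_labels, prog_fps, prog_nfp, prog_labels,
        stem_map, prog_map, inj_mask, inj_trigger,
        snaps, snap_t, snap_ab, snap_md, counts, exposure,
        snap_dt0, int(config.max_events),
    )

    idx = np.round(np.linspace(0, n_snap - 1, config.n_shots)).astype(int)
    final = Dish(dish.region.copy())
    final.cell_type = ctype.reshape(h, w)
    final.x = cx.reshape(h, w)
    final.y = cy.reshape(h, w)
    final.divisions = cdiv.reshape(h, w)
    final.s1 = s1.reshape(h, w)
    final.s2 = s2.reshape(h, w)

    log = EventLog(
        counts={k: int(v) for k, v in zip(COUNTER_KEYS, counts)},
        exposure={"S": float(exposure[0]), "P": float(exposure[1]),
                  "A": float(exposure[2]), "B": float(exposure[3])},
    )
    return Trajectory(
        times=snap_t[idx].copy(),
        snapshots=snaps[idx].reshape(-1, h, w).copy(),
        abundances=snap_ab[idx].copy(),
        mean_divisions=snap_md[idx].copy(),
        log=log,
        final=final,
        status=_STATUS_NAMES[status],
        t_final=float(t_final),
        n_events=int(n_events),
        config=config,
    )
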