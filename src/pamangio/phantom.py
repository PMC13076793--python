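"""Ground-truth 3D absorber phantoms.

Vascular networks are grown as branching persistent random walks whose
segment arc lengths follow per-day log-normal distributions calibrated so
that the printed median/maximum segment-length statistics are recoverable
by the downstream tracing pipeline.  Also provides instrument-calibration
targets (razor edge, single fiber, dispersed cell field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

__all__ = [
    "CONDITIONS",
    "CULTURE_DAYS",
    "DAY_LENGTH_CALIBRATION",
    "PhantomSpec",
    "Segment",
    "VascularPhantom",
    "lognormal_length_params",
    "grow_vascular_phantom",
    "apply_drug_effect",
    "make_calibration_target",
]

CONDITIONS = ("control", "TMZ", "SU", "combo")
CULTURE_DAYS = (4, 6, 8)

# (median µm, maximum µm) targets per culture day; the log-normal shape is
# fit per day so the 99.9th percentile sits at the maximum (the day-6
# maximum is below day-4's, so a shared shape cannot reproduce both).
DAY_LENGTH_CALIBRATION: dict[int, tuple[float, float]] = {
    4: (67.1, 602.5),
    6: (103.2, 410.4),
    8: (158.5, 1154.7),
}

_Z999 = 3.090232306167813  # standard-normal 99.9th percentile

# Per-day growth defaults.  Trees branch until they reach exactly
# `tree_segments` segments, so the per-phantom segment count is
# deterministic (sprouts x tree size); this lets the stratified length
# sampler cover its quantile grid exactly once per phantom, pinning the
# generated length statistics to the calibrated law.
_DAY_GROWTH = {
    4: {"n_sprouts": 14, "tree_segments": 7},
    6: {"n_sprouts": 12, "tree_segments": 7},
    8: {"n_sprouts": 9, "tree_segments": 7},
}

# Depth-dependent survival probability of a vessel segment under treatment.
# Qualitative calibration: monotherapies roughly halve density, the
# combination suppresses strongest, with extra suppression in the shallow
# 0-200 µm slab.  Tunable configuration, not a biological claim.
DRUG_SURVIVAL = {"control": 1.0, "TMZ": 0.55, "SU": 0.50, "combo": 0.25}
SHALLOW_SURVIVAL_FACTOR = 0.8
SHALLOW_BIN_UM = 200.0

MIN_SEGMENT_LENGTH_UM = 15.0
_STEP_UM = 6.0
_TURN_KAPPA = 0.05          # direction jitter per step (persistence)
_BRANCH_ANGLE_RAD = 1.0
_CLEARANCE_UM = 20.0        # min distance of a tip from foreign centerlines
_ANCHOR_FREE_UM = 25.0      # obstacles within this radius of the branch
                            # anchor are ignored (parent junction, sibling root)


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic specimen."""

    volume_size_um: tuple[float, float, float]
    voxel_pitch_um: tuple[float, float, float] = (2.0, 2.0, 3.0)
    culture_day: int = 8
    condition: str = "control"
    rng_seed: int = 0
    n_sprouts: int | None = None
    radius_range_um: tuple[float, float] = (4.0, 7.0)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_size_um):
            raise ValueError("volume_size_um must be strictly positive")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError("voxel_pitch_um must be strictly positive")
        if self.culture_day not in CULTURE_DAYS:
            raise ValueError(f"culture_day must be one of {CULTURE_DAYS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        lo, hi = self.radius_range_um
        if not 0 < lo <= hi:
            raise ValueError("radius_range_um must satisfy 0 < lo <= hi")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(
            int(round(s / p)) for s, p in zip(self.volume_size_um, self.voxel_pitch_um)
        )


@dataclass
class Segment:
    """One centerline polyline between two branch/end nodes."""

    points_um: np.ndarray  # (N, 3)
    radius_um: float

    @property
    def length_um(self) -> float:
        return float(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1).sum())

    @property
    def midpoint_depth_um(self) -> float:
        return float(self.points_um[:, 2].mean())


@dataclass
class VascularPhantom:
    """Absorber grid plus exact ground-truth centerline bookkeeping."""

    absorber: np.ndarray
    segments: list[Segment]
    spec: PhantomSpec

    @property
    def segment_lengths_um(self) -> np.ndarray:
        return np.array([s.length_um for s in self.segments])

    @property
    def centerline_graph(self) -> nx.Graph:
        """Graph with nodes at segment endpoints (µm coords rounded to nm)
        and edges carrying radius and arc length."""
        g = nx.Graph()
        for i, seg in enumerate(self.segments):
            a = tuple(np.round(seg.points_um[0], 3))
            b = tuple(np.round(seg.points_um[-1], 3))
            if a == b:
                continue  # degenerate; never produced by the grower
            g.add_node(a, pos=a)
            g.add_node(b, pos=b)
            g.add_edge(a, b, radius_um=seg.radius_um,
                       length_um=seg.length_um, segment_index=i)
        return g

    def total_length_um(self) -> float:
        return float(self.segment_lengths_um.sum()) if self.segments else 0.0


def lognormal_length_params(culture_day: int) -> tuple[float, float]:
    """(mu, sigma) of the log-normal segment-length law for a culture day:
    exp(mu) is the target median, sigma places the 99.9th percentile at the
    target maximum."""
    median, maximum = DAY_LENGTH_CALIBRATION[culture_day]
    mu = math.log(median)
    sigma = math.log(maximum / median) / _Z999
    return mu, sigma


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perturb(direction: np.ndarray, rng: np.random.Generator,
             kappa: float) -> np.ndarray:
    return _unit(direction + kappa * rng.normal(size=3))


def _walk_segment(
    start: np.ndarray,
    direction: np.ndarray,
    length_um: float,
    bounds_lo: np.ndarray,
    bounds_hi: np.ndarray,
    rng: np.random.Generator,
    obstacle_tree=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Persistent random-walk polyline of given arc length, reflecting off
    the volume walls and deflecting away from existing tubes.

    ``obstacle_tree`` is a KD-tree over previously laid centerline points;
    steps that would come within ``_CLEARANCE_UM`` of a foreign tube are
    re-aimed away, and the segment ends early if no clear direction is found
    (the recorded ground-truth length is always the length actually walked).
    Obstacle points within ``_ANCHOR_FREE_UM`` of the start are ignored so a
    branch can leave its own parent junction.  Returns (points, final
    direction).
    """
    points = [start.copy()]
    pos = start.copy()
    anchor = start.copy()
    d = direction.copy()
    remaining = length_um
    while remaining > 1e-9:
        step = min(_STEP_UM, remaining)
        placed = False
        d_try = _perturb(d, rng, _TURN_KAPPA)
        for _ in range(8):
            nxt = pos + d_try * step
            for ax in range(3):
                if nxt[ax] < bounds_lo[ax]:
                    nxt[ax] = 2 * bounds_lo[ax] - nxt[ax]
                    d_try[ax] = abs(d_try[ax])
                elif nxt[ax] > bounds_hi[ax]:
                    nxt[ax] = 2 * bounds_hi[ax] - nxt[ax]
                    d_try[ax] = -abs(d_try[ax])
            nxt = np.clip(nxt, bounds_lo, bounds_hi)
            # self-avoidance: keep clear of this segment's own older path
            # (the recent trail is exempt, it is always within clearance)
            if len(points) > 6:
                own = np.asarray(points[:-6])
                d_own = np.linalg.norm(own - nxt, axis=1)
                i_min = int(np.argmin(d_own))
                if d_own[i_min] < _CLEARANCE_UM:
                    away = _unit(nxt - own[i_min])
                    d_try = _unit(d_try + 0.8 * away + 0.2 * rng.normal(size=3))
                    continue
            if obstacle_tree is not None:
                dists, idxs = obstacle_tree.query(
                    nxt, k=min(8, obstacle_tree.n)
                )
                dists = np.atleast_1d(dists)
                idxs = np.atleast_1d(idxs)
                offender = None
                for dist, idx in zip(dists, idxs):
                    if dist >= _CLEARANCE_UM:
                        break
                    pt = obstacle_tree.data[idx]
                    if np.linalg.norm(pt - anchor) > _ANCHOR_FREE_UM:
                        offender = pt
                        break
                if offender is not None:
                    away = _unit(nxt - offender)
                    d_try = _unit(d_try + 0.8 * away + 0.2 * rng.normal(size=3))
                    continue
            placed = True
            break
        if not placed:
            break  # boxed in: end the segment here
        actual = np.linalg.norm(nxt - pos)
        if actual < 1e-9:
            d_try = _random_unit(rng)
            continue
        d = d_try
        remaining -= actual
        pos = nxt
        points.append(pos.copy())
    return np.array(points), d


class _LengthSampler:
    """Stratified log-normal length draws.

    A shuffled stratified pool (inverse-CDF at jittered equispaced quantiles)
    pins the per-phantom empirical length distribution to the calibrated law
    much more tightly than iid draws, so the printed median/maximum targets
    are recoverable from a modest number of segments; overflow past the pool
    falls back to iid draws.
    """

    def __init__(self, rng: np.random.Generator, mu: float, sigma: float,
                 pool_size: int = 16) -> None:
        self._rng = rng
        self._mu, self._sigma = mu, sigma
        self._pool_size = pool_size
        self._pool: list[float] = []

    def _refill(self) -> None:
        from scipy.special import ndtri

        n = self._pool_size
        u = (np.arange(n) + self._rng.uniform(size=n)) / n
        pool = np.exp(self._mu + self._sigma * ndtri(u))
        self._pool = list(pool[self._rng.permutation(n)])

    def draw(self) -> float:
        if not self._pool:
            self._refill()
        return float(max(self._pool.pop(), MIN_SEGMENT_LENGTH_UM))


def _ball_offsets(radius_um: float,
                  pitch: tuple[float, float, float]) -> np.ndarray:
    r = np.array([max(int(math.floor(radius_um / p)), 0) for p in pitch])
    ax = [np.arange(-ri, ri + 1) for ri in r]
    gx, gy, gz = np.meshgrid(*ax, indexing="ij")
    d2 = (gx * pitch[0]) ** 2 + (gy * pitch[1]) ** 2 + (gz * pitch[2]) ** 2
    keep = d2 <= radius_um**2
    return np.stack([gx[keep], gy[keep], gz[keep]], axis=1)


def _rasterize_segments(
    segments: list[Segment],
    shape: tuple[int, int, int],
    pitch: tuple[float, float, float],
) -> np.ndarray:
    """Stamp spheres along densely resampled centerlines; absorber is 1
    inside tubes, 0 elsewhere."""
    absorber = np.zeros(shape, dtype=np.float32)
    pitch_arr = np.asarray(pitch)
    offset_cache: dict[float, np.ndarray] = {}
    for seg in segments:
        pts = seg.points_um
        # resample to ~1 µm spacing so no voxel is skipped
        deltas = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(deltas)])
        total = arclen[-1]
        n = max(int(math.ceil(total)) + 1, 2)
        s = np.linspace(0.0, total, n)
        dense = np.stack(
            [np.interp(s, arclen, pts[:, ax]) for ax in range(3)], axis=1
        )
        key = round(seg.radius_um, 1)
        if key not in offset_cache:
            offset_cache[key] = _ball_offsets(key, pitch)
        offsets = offset_cache[key]
        centers = np.unique(np.round(dense / pitch_arr).astype(np.int64), axis=0)
        vox = centers[:, None, :] + offsets[None, :, :]
        vox = vox.reshape(-1, 3)
        ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
        vox = vox[ok]
        absorber[vox[:, 0], vox[:, 1], vox[:, 2]] = 1.0
    return absorber


def grow_vascular_phantom(spec: PhantomSpec) -> VascularPhantom:
    """Grow a seeded branching tube network with exact length bookkeeping.

    Every generated segment terminates either at a leaf or at a bifurcation,
    so ground-truth segments correspond one-to-one to branch-to-branch or
    branch-to-end spans of the network skeleton.
    """
    size = np.asarray(spec.volume_size_um, dtype=np.float64)
    growth = _DAY_GROWTH[spec.culture_day]
    n_sprouts = growth["n_sprouts"] if spec.n_sprouts is None else spec.n_sprouts
    if n_sprouts < 0:
        raise ValueError("n_sprouts must be nonnegative")
    margin = spec.radius_range_um[1] + 2.0
    if n_sprouts > 0 and np.any(size - 2 * margin < MIN_SEGMENT_LENGTH_UM):
        raise ValueError(
            "volume too small to contain one minimum-length segment"
        )
    rng = np.random.default_rng(spec.rng_seed)
    mu, sigma = lognormal_length_params(spec.culture_day)
    tree_segments = growth["tree_segments"]
    sampler = _LengthSampler(rng, mu, sigma,
                             pool_size=max(n_sprouts * tree_segments, 1))
    lo = np.full(3, margin)
    hi = size - margin

    from scipy.spatial import cKDTree

    segments: list[Segment] = []
    laid_points: list[np.ndarray] = []
    from collections import deque

    for _ in range(n_sprouts):
        start = rng.uniform(lo, hi)
        tips = deque([(start, _random_unit(rng), 0)])
        n_tree = 0
        # breadth-first so the budget yields complete bifurcating trees
        # (depth-first would spend it all on a single lineage chain)
        while tips and n_tree < tree_segments:
            pos, d, depth_lvl = tips.popleft()
            length = sampler.draw()
            radius = rng.uniform(*spec.radius_range_um)
            tree = cKDTree(np.concatenate(laid_points)) if laid_points else None
            pts, d_end = _walk_segment(pos, d, length, lo, hi, rng, tree)
            if len(pts) < 2:
                continue
            laid_points.append(pts)
            segments.append(Segment(points_um=pts, radius_um=radius))
            n_tree += 1
            if n_tree < tree_segments:
                axis = _random_unit(rng)
                perp = _unit(np.cross(d_end, axis))
                for sign in (+1.0, -1.0):
                    child = _unit(
                        math.cos(_BRANCH_ANGLE_RAD) * d_end
                        + sign * math.sin(_BRANCH_ANGLE_RAD) * perp
                    )
                    tips.append((pts[-1].copy(), child, depth_lvl + 1))

    absorber = _rasterize_segments(segments, spec.grid_shape, spec.voxel_pitch_um)
    phantom = VascularPhantom(
        absorber=absorber, segments=segments,
        spec=replace(spec, condition="control"),
    )
    if spec.condition != "control":
        phantom = apply_drug_effect(phantom, spec.condition)
    return phantom


def apply_drug_effect(phantom: VascularPhantom, condition: str) -> VascularPhantom:
    """Prune segments with a depth-dependent survival probability.

    Control is the identity.  Pruning is seeded from the phantom spec and the
    condition, so the result is deterministic for a given phantom.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if condition == "control":
        return phantom
    base = DRUG_SURVIVAL[condition]
    rng = np.random.default_rng(
        [phantom.spec.rng_seed, CONDITIONS.index(condition), 0xD06]
    )
    survivors = []
    for seg in phantom.segments:
        p = base
        if seg.midpoint_depth_um < SHALLOW_BIN_UM:
            p *= SHALLOW_SURVIVAL_FACTOR
        if rng.random() < p:
            survivors.append(seg)
    spec = replace(phantom.spec, condition=condition)
    absorber = _rasterize_segments(survivors, spec.grid_shape, spec.voxel_pitch_um)
    return VascularPhantom(absorber=absorber, segments=survivors, spec=spec)


def make_calibration_target(
    kind: str,
    volume_size_um: tuple[float, float, float],
    voxel_pitch_um: tuple[float, float, float] = (2.0, 2.0, 3.0),
    *,
    edge_position_um: float = 100.0,
    fiber_diameter_um: float = 6.0,
    fiber_depth_um: float = 300.0,
    cell_density_per_mm3: float = 20000.0,
    cell_radius_um: float = 8.0,
    rng_seed: int = 0,
) -> VascularPhantom:
    """Instrument-calibration phantoms.

    ``edge``: absorbing half-space x < edge_position_um.
    ``fiber``: one cylinder along y at the given depth.
    ``cell_field``: Poisson-placed spheres of the given density and radius.
    """
    if kind not in ("edge", "fiber", "cell_field"):
        raise ValueError(f"unknown calibration target kind {kind!r}")
    spec = PhantomSpec(volume_size_um=volume_size_um,
                       voxel_pitch_um=voxel_pitch_um, rng_seed=rng_seed)
    shape = spec.grid_shape
    px, py, pz = voxel_pitch_um
    absorber = np.zeros(shape, dtype=np.float32)
    segments: list[Segment] = []
    if kind == "edge":
        if edge_position_um <= 0:
            raise ValueError("edge position must be positive")
        x_um = np.arange(shape[0]) * px
        absorber[x_um < edge_position_um, :, :] = 1.0
    elif kind == "fiber":
        if fiber_diameter_um <= 0:
            raise ValueError("fiber diameter must be positive")
        x_um = np.arange(shape[0]) * px
        z_um = np.arange(shape[2]) * pz
        x0 = volume_size_um[0] / 2.0
        r = fiber_diameter_um / 2.0
        d2 = (x_um[:, None] - x0) ** 2 + (z_um[None, :] - fiber_depth_um) ** 2
        mask = d2 <= r**2
        if not mask.any():  # thin fiber: keep at least the nearest lattice line
            i = int(np.argmin(np.abs(x_um - x0)))
            k = int(np.argmin(np.abs(z_um - fiber_depth_um)))
            mask[i, k] = True
        absorber[:, :, :] = mask[:, None, :]
        p0 = np.array([x0, 0.0, fiber_depth_um])
        p1 = np.array([x0, volume_size_um[1], fiber_depth_um])
        segments.append(Segment(points_um=np.stack([p0, p1]), radius_um=r))
    else:  # cell_field
        if cell_density_per_mm3 <= 0 or cell_radius_um <= 0:
            raise ValueError("cell density and radius must be positive")
        rng = np.random.default_rng(rng_seed)
        volume_mm3 = float(np.prod(np.asarray(volume_size_um) / 1000.0))
        n_cells = rng.poisson(cell_density_per_mm3 * volume_mm3)
        offsets = _ball_offsets(cell_radius_um, voxel_pitch_um)
        for _ in range(n_cells):
            c = rng.uniform(0.0, np.asarray(volume_size_um))
            cv = np.round(c / np.array(voxel_pitch_um)).astype(np.int64)
            vox = cv[None, :] + offsets
            ok = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
            vox = vox[ok]
            absorber[vox[:, 0], vox[:, 1], vox[:, 2]] = 1.0
    return VascularPhantom(absorber=absorber, segments=segments, spec=spec)
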