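"""Off-lattice agent-based simulator of cell aggregation.

Cells are disks of fixed diameter ``d`` moving on a 2D periodic square.
One iteration corresponds to one minute.  Each iteration:

1. aggregates (connected contact components of two or more cells) are
   identified;
2. every aggregate performs a rigid random-walk step of length ``a0/N``
   (diffusion of a cluster of N cells slows as 1/N);
3. every cell, visited in a fresh random order, performs an individual
   step of length ``a0/(1+n^2)`` where ``n`` is its current number of
   neighbors, in a direction drawn uniformly, biased by the hydrodynamic
   flux (half-plane) for individual cells, or biased towards the
   aggregate's center of mass (compaction) for aggregate members; the
   step is truncated at first contact (adhesion) and cancelled if it
   would decrease the number of neighbors (no detachment);
4. after moving, each cell attempts division with probability ``kappa``;
   the daughter is placed at distance ``d`` at a uniform angle and the
   division is aborted if it would violate the superimposition limit.

Partial overlap of disks down to a center distance ``d*(1-alpha_max)``
models deformability and 3D stacking within a 2D simulation.

All randomness flows through a single seeded ``numpy`` generator in a
fixed draw order, so trajectories are bit-reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .clusters import CONTACT_TOL, contact_pairs, connected_components
from .space import BoxSpec, DirectionLaw, min_image_vector, sample_direction, wrap_position

__all__ = [
    "CellState",
    "FluxSpec",
    "AbmConfig",
    "WorldState",
    "Snapshot",
    "Trajectory",
    "min_center_distance",
    "intra_step_length",
    "aggregate_step_length",
    "compaction_halfwidth_deg",
    "propose_direction",
    "truncated_move",
    "no_detach_accept",
    "attempt_division",
    "init_world",
    "step_world",
    "run_simulation",
]

#: back-off subtracted from the contact travel so roundoff never drives a
#: center pair below the superimposition limit
_CONTACT_BACKOFF = 1e-9

#: default pixel pitch of the experimental camera frame, µm per pixel
PIXEL_SIZE_UM = 0.658


@dataclass(frozen=True)
class CellState:
    """One disk agent: stable integer id and wrapped center position (µm)."""

    id: int
    position: np.ndarray


@dataclass(frozen=True)
class FluxSpec:
    """Hydrodynamic drift bias restricting motion to a half-plane.

    ``scope`` selects which movers feel the bias: ``individuals_only``,
    ``individuals_and_aggregates`` (default) or
    ``individuals_and_small_aggregates`` (aggregates up to
    ``small_threshold`` cells).
    """

    enabled: bool = False
    direction: float = 0.0
    scope: str = "individuals_and_aggregates"
    small_threshold: int = 10

    def __post_init__(self) -> None:
        if self.scope not in (
            "individuals_only",
            "individuals_and_aggregates",
            "individuals_and_small_aggregates",
        ):
            raise ValueError(f"unknown flux scope {self.scope!r}")
        if not (0.0 <= self.direction < 360.0):
            object.__setattr__(self, "direction", float(np.mod(self.direction, 360.0)))
        if self.small_threshold < 2:
            raise ValueError("small_threshold must be >= 2")

    def applies_to_aggregate(self, size: int) -> bool:
        if not self.enabled:
            return False
        if self.scope == "individuals_and_aggregates":
            return True
        if self.scope == "individuals_and_small_aggregates":
            return size <= self.small_threshold
        return False


@dataclass(frozen=True)
class AbmConfig:
    """Full parameter set of one simulation.

    Lengths are in µm; ``step_length`` may be built from pixel units with
    :meth:`px`.  ``proliferation_rate`` is a probability per one-minute
    iteration.
    """

    n_initial: int
    cell_diameter: float = 13.2
    step_length: float = PIXEL_SIZE_UM * 6
    pixel_size: float = PIXEL_SIZE_UM
    proliferation_rate: float = 7e-4
    alpha_max: float = 0.7
    compaction_enabled: bool = True
    flux: FluxSpec = field(default_factory=FluxSpec)
    box: BoxSpec = field(default_factory=BoxSpec)
    iteration_minutes: float = 1.0
    n_iterations: int = 720
    seed: int = 0
    #: truncate the step at first contact (default); if False the whole
    #: step is cancelled instead when it would break the overlap limit
    truncate_on_contact: bool = True

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise ValueError("n_initial must be >= 1")
        if self.cell_diameter <= 0:
            raise ValueError("cell_diameter must be positive")
        if self.step_length < 0:
            raise ValueError("step_length must be >= 0")
        if not (0.0 <= self.proliferation_rate <= 1.0):
            raise ValueError("proliferation_rate must be in [0, 1]")
        if not (0.0 <= self.alpha_max < 1.0):
            raise ValueError("alpha_max must be in [0, 1)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def px(self, n_pixels: float) -> float:
        """Convert a length in pixel units to µm with this config's pitch."""
        return n_pixels * self.pixel_size

    @property
    def dmin(self) -> float:
        """Minimum allowed center-center distance d*(1-alpha_max), µm."""
        return min_center_distance(self)


@dataclass
class WorldState:
    """Mutable state of a running simulation."""

    time: float
    positions: np.ndarray  # (n, 2) µm, wrapped
    ids: np.ndarray  # (n,) stable integer ids
    next_id: int
    rng: np.random.Generator

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    @property
    def cells(self) -> list[CellState]:
        return [CellState(int(i), p.copy()) for i, p in zip(self.ids, self.positions)]


@dataclass(frozen=True)
class Snapshot:
    time: float
    positions: np.ndarray
    ids: np.ndarray


@dataclass(frozen=True)
class Trajectory:
    config: AbmConfig
    snapshots: list[Snapshot]

    def __len__(self) -> int:
        return len(self.snapshots)


# ---------------------------------------------------------------------------
# elementary rules


def min_center_distance(config: AbmConfig) -> float:
    """Smallest allowed distance between two cell centers, d*(1-alpha_max)."""
    return config.cell_diameter * (1.0 - config.alpha_max)


def intra_step_length(a0: float, n: int) -> float:
    """Step length of a cell with ``n`` neighbors: a0 / (1 + n^2)."""
    if n < 0:
        raise ValueError("neighbor count must be >= 0")
    return a0 / (1.0 + n * n)


def aggregate_step_length(a0: float, n_cells: int) -> float:
    """Rigid-step length of an aggregate of ``n_cells`` cells: a0 / N."""
    if n_cells < 1:
        raise ValueError("aggregate size must be >= 1")
    return a0 / n_cells


def compaction_halfwidth_deg(n: float) -> float:
    """Half-width (degrees) of the compaction-biased sector: 90*(1+e^(-n/40)).

    Decreases from 180° (no bias, tiny aggregate) to 90° (half-plane
    towards the center of mass) as the aggregate grows.
    """
    return 90.0 * (1.0 + np.exp(-np.asarray(n, dtype=float) / 40.0))


def propose_direction(
    position,
    cluster_size: int,
    com,
    config: AbmConfig,
    rng: np.random.Generator,
) -> float:
    """Draw the motion direction (degrees) for one cell.

    Aggregate members (cluster_size >= 2) are biased towards the
    aggregate's center of mass when compaction is enabled; individual
    cells feel the half-plane flux bias when the flux is on.
    """
    if cluster_size >= 2:
        if com is None:
            raise ValueError("center of mass required for an aggregate member")
        if config.compaction_enabled:
            v = min_image_vector(position, com, config.box)
            center = np.degrees(np.arctan2(v[1], v[0]))
            hw = compaction_halfwidth_deg(cluster_size)
            law = DirectionLaw(mode="sector", center_angle=center, half_width=hw)
        else:
            law = DirectionLaw(mode="uniform")
    elif config.flux.enabled:
        law = DirectionLaw(mode="halfplane", center_angle=config.flux.direction)
    else:
        law = DirectionLaw(mode="uniform")
    return float(sample_direction(law, rng))


def _first_contact_travel(p, u, others, dmin: float, box: BoxSpec) -> float:
    """Smallest travel along unit vector ``u`` at which the center moving
    from ``p`` reaches distance ``dmin`` of any center in ``others``.

    Returns ``inf`` when no contact occurs for any travel >= 0.
    """
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.size == 0:
        return np.inf
    w = min_image_vector(p, others, box)  # (m, 2) vectors p -> q
    b = w @ u  # projection on the motion direction
    c = np.einsum("ij,ij->i", w, w) - dmin * dmin
    # already at (or numerically inside) contact and approaching -> stuck
    approaching = b > 0.0
    at_contact = c <= 0.0
    if np.any(at_contact & approaching):
        return 0.0
    disc = b * b - c
    hit = approaching & (disc >= 0.0) & ~at_contact
    if not np.any(hit):
        return np.inf
    t = b[hit] - np.sqrt(disc[hit])
    return float(max(t.min(), 0.0))


def truncated_move(position, angle_deg: float, step: float, others, dmin: float, box: BoxSpec):
    """Move along ``angle_deg`` by at most ``step``, stopping prematurely
    at first contact (center distance ``dmin``) with any other cell.

    Returns the wrapped end position; travel 0 (cell stays) is allowed.
    """
    p = np.asarray(position, dtype=float)
    u = np.array(
        [np.cos(np.radians(angle_deg)), np.sin(np.radians(angle_deg))], dtype=float
    )
    t_hit = _first_contact_travel(p, u, others, dmin, box)
    travel = min(step, max(t_hit - _CONTACT_BACKOFF, 0.0))
    return wrap_position(p + travel * u, box)


def _count_contacts(p, others, contact_dist: float, box: BoxSpec) -> int:
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.size == 0:
        return 0
    v = min_image_vector(p, others, box)
    d2 = np.einsum("ij,ij->i", v, v)
    r = contact_dist + CONTACT_TOL
    return int(np.count_nonzero(d2 <= r * r))


def no_detach_accept(position, proposed, others, contact_dist: float, box: BoxSpec) -> bool:
    """Adhesion rule: accept a move only if the cell ends with at least as
    many neighbors as before (cells never detach from an aggregate)."""
    n_before = _count_contacts(np.asarray(position, float), others, contact_dist, box)
    if n_before == 0:
        return True
    n_after = _count_contacts(np.asarray(proposed, float), others, contact_dist, box)
    return n_after >= n_before


def attempt_division(position, others, config: AbmConfig, rng: np.random.Generator):
    """With probability ``proliferation_rate``, try to place a daughter at
    distance ``d`` from the mother at a uniform random angle.

    Returns the daughter position, or None if no division was attempted or
    the single drawn position violates the superimposition limit (the
    division is then aborted, not retried).
    """
    if rng.uniform() >= config.proliferation_rate:
        return None
    ang = np.radians(rng.uniform(0.0, 360.0))
    p = np.asarray(position, dtype=float)
    daughter = wrap_position(
        p + config.cell_diameter * np.array([np.cos(ang), np.sin(ang)]), config.box
    )
    others = np.atleast_2d(np.asarray(others, dtype=float))
    if others.size:
        v = min_image_vector(daughter, others, config.box)
        d2 = np.einsum("ij,ij->i", v, v)
        if np.any(d2 < config.dmin**2):
            return None
    return daughter


# ---------------------------------------------------------------------------
# world construction and iteration


def init_world(config: AbmConfig, rng: np.random.Generator | None = None, max_attempts: int = 1_000_000) -> WorldState:
    """Seed ``n_initial`` cells i.i.d. uniformly in the box, resampling any
    cell violating the hard-core distance until the configuration is valid.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.box.side_length
    n = config.n_initial
    dmin = config.dmin
    pos = rng.uniform(0.0, L, size=(n, 2))
    attempts = n
    while True:
        if n < 2:
            break
        tree = cKDTree(pos, boxsize=L)
        bad_pairs = tree.query_pairs(dmin * (1.0 - 1e-12), output_type="ndarray")
        if len(bad_pairs) == 0:
            break
        offenders = np.unique(bad_pairs[:, 1])
        attempts += len(offenders)
        if attempts > max_attempts:
            density = n * np.pi * (config.cell_diameter / 2) ** 2 / L**2
            raise RuntimeError(
                f"could not place {n} cells with hard-core distance {dmin:.3g} µm "
                f"(area fraction {density:.2f}); lower the density"
            )
        pos[offenders] = rng.uniform(0.0, L, size=(len(offenders), 2))
    return WorldState(
        time=0.0,
        positions=pos,
        ids=np.arange(n, dtype=np.intp),
        next_id=n,
        rng=rng,
    )


def step_world(world: WorldState, config: AbmConfig) -> WorldState:
    """Advance the world by one iteration (one minute). Mutates and returns
    ``world``.

    The loop body inlines the elementary rules (direction sampling,
    contact truncation, neighbor counting) for speed; the standalone
    operations above define the contract it must match.
    """
    pos = world.positions
    n = len(pos)
    rng = world.rng
    box = config.box
    L = box.side_length
    hL = 0.5 * L
    d = config.cell_diameter
    dmin = config.dmin
    dmin2 = dmin * dmin
    r_contact = d + CONTACT_TOL
    r_contact2 = r_contact * r_contact
    a0 = config.step_length

    # (1) aggregate identification; membership frozen for this iteration
    pairs = contact_pairs(pos, d, box)
    lab = connected_components(pairs, n, pos, box)
    labels = lab.labels
    sizes = lab.sizes
    coms = lab.coms.copy()

    # (2) collective rigid moves of aggregates, ascending cluster id
    if a0 > 0 and np.any(sizes >= 2):
        pre_tree = cKDTree(pos, boxsize=L)
        search_r = d + a0 + 1.0
        flux_dir = config.flux.direction
        for cid in np.flatnonzero(sizes >= 2):
            size = int(sizes[cid])
            if config.flux.applies_to_aggregate(size):
                theta = flux_dir + rng.uniform(-90.0, 90.0)
            else:
                theta = rng.uniform(0.0, 360.0)
            step = aggregate_step_length(a0, size)
            th = np.radians(theta)
            u = np.array([np.cos(th), np.sin(th)])
            members = np.flatnonzero(labels == cid)
            cand: set[int] = set()
            for hits in pre_tree.query_ball_point(pos[members], search_r):
                cand.update(hits)
            outsiders = np.fromiter(
                (j for j in cand if labels[j] != cid), dtype=np.intp
            )
            travel = step
            if outsiders.size:
                # first contact over all member-outsider pairs
                w = np.mod(
                    pos[outsiders][None, :, :] - pos[members][:, None, :] + hL, L
                ) - hL
                b = w @ u
                c = w[..., 0] ** 2 + w[..., 1] ** 2 - dmin2
                approaching = b > 0.0
                if np.any((c <= 0.0) & approaching):
                    t_hit = 0.0
                else:
                    disc = b * b - c
                    hit = approaching & (disc >= 0.0)
                    t_hit = (
                        float(np.min(b[hit] - np.sqrt(disc[hit]))) if np.any(hit) else np.inf
                    )
                travel = min(step, max(t_hit - _CONTACT_BACKOFF, 0.0))
            if travel > 0:
                pos[members] = np.mod(pos[members] + travel * u, L)
                coms[cid] = np.mod(coms[cid] + travel * u, L)

    # (3) individual moves in a fresh random order; neighbor counts are
    # recomputed on the fly since cells move sequentially
    order = rng.permutation(n)
    phase_tree = cKDTree(pos, boxsize=L)
    search_r = d + 2.0 * a0 + 1.0
    cand_lists = phase_tree.query_ball_point(pos, search_r)
    born_pos: list[np.ndarray] = []
    kappa = config.proliferation_rate
    compaction = config.compaction_enabled
    flux_on = config.flux.enabled
    flux_dir = config.flux.direction
    truncate = config.truncate_on_contact

    for i in order:
        cand = [j for j in cand_lists[i] if j != i]
        if born_pos:
            others = np.concatenate([pos[cand].reshape(-1, 2), np.asarray(born_pos)])
        else:
            others = pos[cand]
        p = pos[i]
        m = len(others)
        if m:
            w = np.mod(others - p + hL, L) - hL
            d2 = w[:, 0] ** 2 + w[:, 1] ** 2
            n_before = int(np.count_nonzero(d2 <= r_contact2))
        else:
            n_before = 0
        size = int(sizes[labels[i]])
        # direction draw (one uniform variate in every branch)
        if size >= 2:
            if compaction:
                com = coms[labels[i]]
                vx = np.mod(com[0] - p[0] + hL, L) - hL
                vy = np.mod(com[1] - p[1] + hL, L) - hL
                center = np.degrees(np.arctan2(vy, vx))
                hw = 90.0 * (1.0 + np.exp(-size / 40.0))
                theta = center + rng.uniform(-hw, hw)
            else:
                theta = rng.uniform(0.0, 360.0)
        elif flux_on:
            theta = flux_dir + rng.uniform(-90.0, 90.0)
        else:
            theta = rng.uniform(0.0, 360.0)
        step = a0 / (1.0 + n_before * n_before)
        if step > 0:
            th = np.radians(theta)
            u0, u1 = np.cos(th), np.sin(th)
            if m:
                b = w[:, 0] * u0 + w[:, 1] * u1
                c = d2 - dmin2
                approaching = b > 0.0
                if np.any((c <= 0.0) & approaching):
                    t_hit = 0.0
                else:
                    disc = b * b - c
                    hit = approaching & (disc >= 0.0)
                    t_hit = (
                        float(np.min(b[hit] - np.sqrt(disc[hit]))) if np.any(hit) else np.inf
                    )
            else:
                t_hit = np.inf
            if truncate:
                travel = min(step, max(t_hit - _CONTACT_BACKOFF, 0.0))
            else:
                travel = step if t_hit > step else 0.0
            if travel > 0:
                proposed = np.mod(p + travel * np.array([u0, u1]), L)
                if n_before == 0:
                    pos[i] = proposed
                    p = proposed
                else:
                    w2 = np.mod(others - proposed + hL, L) - hL
                    n_after = int(
                        np.count_nonzero(w2[:, 0] ** 2 + w2[:, 1] ** 2 <= r_contact2)
                    )
                    if n_after >= n_before:
                        pos[i] = proposed
                        p = proposed
        # (4) proliferation attempt after the move
        if kappa > 0 and rng.uniform() < kappa:
            ang = np.radians(rng.uniform(0.0, 360.0))
            daughter = np.mod(p + d * np.array([np.cos(ang), np.sin(ang)]), L)
            blockers = phase_tree.query_ball_point(daughter, d + a0 + 1.0)
            blockers = [j for j in blockers if j != i]
            check = [pos[blockers].reshape(-1, 2), p.reshape(1, 2)]
            if born_pos:
                check.append(np.asarray(born_pos))
            allpts = np.concatenate(check)
            v = np.mod(allpts - daughter + hL, L) - hL
            if np.all(v[:, 0] ** 2 + v[:, 1] ** 2 >= dmin2):
                born_pos.append(daughter)

    if born_pos:
        k = len(born_pos)
        world.positions = np.concatenate([pos, np.asarray(born_pos)])
        world.ids = np.concatenate(
            [world.ids, np.arange(world.next_id, world.next_id + k, dtype=np.intp)]
        )
        world.next_id += k
    world.time += config.iteration_minutes
    return world


def run_simulation(
    config: AbmConfig,
    stride: int = 10,
    rng: np.random.Generator | None = None,
    validate: bool = False,
) -> Trajectory:
    """Run ``n_iterations`` updates from a fresh initial state, recording a
    snapshot every ``stride`` iterations (the initial and final states are
    always recorded).

    With ``validate=True`` the hard-core invariant (no center pair below
    d*(1-alpha_max) - 1e-9) is asserted at every snapshot.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    world = init_world(config, rng=rng)
    snaps = [Snapshot(world.time, world.positions.copy(), world.ids.copy())]
    for it in range(1, config.n_iterations + 1):
        step_world(world, config)
        if it % stride == 0 or it == config.n_iterations:
            if validate:
                _assert_hardcore(world.positions, config)
            snaps.append(Snapshot(world.time, world.positions.copy(), world.ids.copy()))
    return Trajectory(config=config, snapshots=snaps)


def _assert_hardcore(pos: np.ndarray, config: AbmConfig) -> None:
    if len(pos) < 2:
        return
    tree = cKDTree(pos, boxsize=config.box.side_length)
    bad = tree.query_pairs(config.dmin - 1e-9)
    assert not bad, f"hard-core violation for pairs {sorted(bad)[:5]}"
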