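"""Discontinuous (event-driven) molecular dynamics with replica exchange.

The engine propagates a square-well Go model exactly between potential
discontinuities: hard-core bounces, well captures/escapes and bond-wall
reflections, each conserving linear momentum exactly and total energy
exactly (well events exchange +-eps between kinetic and potential energy).
Temperature is measured in units of eps/k_B; masses are 1, lengths in
Angstrom.  An Andersen thermostat (Poisson ghost collisions that redraw one
atom's velocity from the Maxwell-Boltzmann distribution) provides NVT
sampling; with the thermostat off the dynamics is NVE and drift-free.

Equilibrium sampling across the folding transition uses standard replica
exchange: neighbour temperature swaps accepted with the Metropolis
probability ``min(1, exp[(1/T_i - 1/T_j)(E_i - E_j)])``, velocities rescaled
by ``sqrt(T_new/T_old)`` on exchange.  The temperature grid is calibrated on
pilot runs until every neighbour pair exceeds a target acceptance (the
conventional choice here is >90%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _dmd_core as core
from .go_model import GoModel, HardCoreViolation, MIN_BACKBONE_SEP

__all__ = [
    "SimState",
    "Event",
    "Trajectory",
    "PairTables",
    "ReplicaSet",
    "build_pair_tables",
    "maxwell_velocities",
    "next_pair_event",
    "resolve_pair_velocities",
    "run_dmd",
    "attempt_replica_swap",
    "run_re_dmd",
    "calibrate_temperature_grid",
]


@dataclass
class SimState:
    """Instantaneous mechanical state of one replica."""

    coordinates: np.ndarray
    velocities: np.ndarray
    clock: float = 0.0
    potential_energy: float = 0.0
    temperature: float | None = None

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float((self.velocities**2).sum())

    @property
    def total_energy(self) -> float:
        return self.kinetic_energy + self.potential_energy


@dataclass(frozen=True)
class Event:
    """A scheduled pair discontinuity."""

    time: float
    pair: tuple[int, int]
    kind: str  # hard_core_bounce | well_entry | well_exit_escape | ...


@dataclass
class Trajectory:
    """Sampled observables of one fixed-temperature run."""

    times: np.ndarray
    potential: np.ndarray  # eps
    kinetic: np.ndarray
    q: np.ndarray  # fraction of native contacts
    temperature: float
    coords: np.ndarray | None = None  # (S, N, 3) when recorded

    @property
    def total(self) -> np.ndarray:
        return self.potential + self.kinetic

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PairTables:
    """Flat interaction tables consumed by the event kernel."""

    pi: np.ndarray
    pj: np.ndarray
    kind: np.ndarray  # 0 hard, 1 well, 2 bond
    rin2: np.ndarray
    rout2: np.ndarray
    ap_start: np.ndarray  # CSR: pairs touching each atom
    ap_idx: np.ndarray
    n_atoms: int
    n_native: int


def build_pair_tables(model: GoModel) -> PairTables:
    """Enumerate every interacting pair of the model.

    Pairs with backbone separation >= 3 are square wells (native) or bare
    hard spheres (non-native); bonded 1-2/1-3 pairs are bond wells; local
    non-bonded pairs carry no interaction (their geometry is maintained by
    the bond network).
    """
    res = model.structure.residue_numbers
    radii = model.radii
    n = len(radii)
    native = {
        (int(i), int(j)) if i < j else (int(j), int(i))
        for i, j in zip(model.pair_i, model.pair_j)
    }
    native_geom = {
        (min(int(i), int(j)), max(int(i), int(j))): (float(s), float(w))
        for i, j, s, w in zip(
            model.pair_i, model.pair_j, model.sigma, model.well_edge
        )
    }
    bonds = {
        (min(int(i), int(j)), max(int(i), int(j))): (float(lo), float(hi))
        for i, j, lo, hi in zip(
            model.bond_i, model.bond_j, model.bond_min, model.bond_max
        )
    }
    pi, pj, kind, rin2, rout2 = [], [], [], [], []
    for i in range(n):
        for j in range(i + 1, n):
            key = (i, j)
            if key in bonds:
                lo, hi = bonds[key]
                pi.append(i); pj.append(j); kind.append(2)
                rin2.append(lo * lo); rout2.append(hi * hi)
            elif abs(int(res[i]) - int(res[j])) >= MIN_BACKBONE_SEP:
                sigma = model.alpha * (radii[i] + radii[j])
                if key in native:
                    s, w = native_geom[key]
                    pi.append(i); pj.append(j); kind.append(1)
                    rin2.append(s * s); rout2.append(w * w)
                else:
                    pi.append(i); pj.append(j); kind.append(0)
                    rin2.append(sigma * sigma); rout2.append(-1.0)
    pi = np.array(pi, dtype=np.int64)
    pj = np.array(pj, dtype=np.int64)
    touching: list[list[int]] = [[] for _ in range(n)]
    for p, (i, j) in enumerate(zip(pi, pj)):
        touching[int(i)].append(p)
        touching[int(j)].append(p)
    ap_start = np.zeros(n + 1, dtype=np.int64)
    for i in range(n):
        ap_start[i + 1] = ap_start[i] + len(touching[i])
    ap_idx = np.array(
        [p for lst in touching for p in lst], dtype=np.int64
    )
    return PairTables(
        pi=pi,
        pj=pj,
        kind=np.array(kind, dtype=np.int8),
        rin2=np.array(rin2),
        rout2=np.array(rout2),
        ap_start=ap_start,
        ap_idx=ap_idx,
        n_atoms=n,
        n_native=len(native),
    )


def _init_in_well(
    tables: PairTables, coords: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """Classify well pairs and validate cores/bonds for an initial state."""
    d = np.linalg.norm(coords[tables.pj] - coords[tables.pi], axis=1)
    in_well = np.zeros(len(d), dtype=np.int8)
    for p in range(len(d)):
        k = tables.kind[p]
        rin = math.sqrt(tables.rin2[p])
        if k == 2:
            rout = math.sqrt(tables.rout2[p])
            if not (rin - tol <= d[p] <= rout + tol):
                raise ValueError(
                    f"bond pair ({tables.pi[p]}, {tables.pj[p]}) at "
                    f"{d[p]:.4f} A outside its well [{rin:.4f}, {rout:.4f}]"
                )
            continue
        if d[p] < rin - tol:
            raise HardCoreViolation(
                f"initial state: atoms ({tables.pi[p]}, {tables.pj[p]}) at "
                f"{d[p]:.4f} A inside hard core {rin:.4f} A"
            )
        if k == 1 and d[p] <= math.sqrt(tables.rout2[p]):
            in_well[p] = 1
    return in_well


def maxwell_velocities(
    n_atoms: int, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Maxwell-Boltzmann velocities at *temperature*, COM motion removed."""
    v = rng.normal(0.0, math.sqrt(temperature), size=(n_atoms, 3))
    return v - v.mean(axis=0)


# ---------------------------------------------------------------------------
# Reference single-pair kinematics (used directly by tests and docs; the
# compiled kernel implements the identical rules).


def next_pair_event(
    rel_position: np.ndarray,
    rel_velocity: np.ndarray,
    sigma: float,
    well_edge: float | None,
    in_well: bool,
    now: float = 0.0,
) -> Event | None:
    """Earliest discontinuity of one pair; None if the pair is diverging."""
    r = np.asarray(rel_position, float)
    v = np.asarray(rel_velocity, float)
    rr = float(r @ r)
    if rr < sigma * sigma * (1 - 1e-12):
        raise ValueError("pair starts inside its hard core")
    a = float(v @ v)
    if a == 0.0:
        return None
    b = float(r @ v)
    if in_well:
        if well_edge is None:
            raise ValueError("in_well requires a finite well_edge")
        if b < 0.0:
            disc = b * b - a * (rr - sigma * sigma)
            if disc > 0.0:
                return Event(
                    now + (-b - math.sqrt(disc)) / a, (0, 1), "hard_core_bounce"
                )
        disc = max(b * b - a * (rr - well_edge * well_edge), 0.0)
        return Event(now + (-b + math.sqrt(disc)) / a, (0, 1), "well_exit")
    boundary = sigma if well_edge is None else well_edge
    label = "hard_core_bounce" if well_edge is None else "well_entry"
    if b < 0.0:
        disc = b * b - a * (rr - boundary * boundary)
        if disc > 0.0:
            return Event(
                now + max((-b - math.sqrt(disc)) / a, 0.0), (0, 1), label
            )
    return None


def resolve_pair_velocities(
    v_i: np.ndarray,
    v_j: np.ndarray,
    normal: np.ndarray,
    kind: str,
    epsilon: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, str]:
    """Velocity update of a pair event (unit masses, reduced mass 1/2).

    ``normal`` is the unit vector from atom i to atom j at the
    discontinuity.  Returns the updated velocities and the realized kind
    (``well_exit`` resolves to ``well_exit_escape`` or ``well_exit_bounce``
    depending on the radial kinetic energy).
    """
    n = np.asarray(normal, float)
    n = n / np.linalg.norm(n)
    vi = np.asarray(v_i, float).copy()
    vj = np.asarray(v_j, float).copy()
    vr = float((vj - vi) @ n)
    if kind == "well_entry":
        vr_new, realized = -math.sqrt(vr * vr + 4 * epsilon), "well_entry"
    elif kind == "well_exit":
        if vr * vr > 4 * epsilon:
            vr_new, realized = math.sqrt(vr * vr - 4 * epsilon), "well_exit_escape"
        else:
            vr_new, realized = -vr, "well_exit_bounce"
    elif kind in ("hard_core_bounce", "bond_min", "bond_max"):
        vr_new, realized = -vr, kind
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    half = 0.5 * (vr_new - vr)
    return vi - half * n, vj + half * n, realized


# ---------------------------------------------------------------------------
# Fixed-temperature runs


def run_dmd(
    model: GoModel,
    init: SimState | np.ndarray,
    temperature: float,
    n_events: int,
    thermostat_rate: float = 0.1,
    seed: int = 0,
    sample_every: int = 1000,
    record_coords: bool = False,
    tables: PairTables | None = None,
) -> tuple[Trajectory, SimState]:
    """Evolve the model for *n_events* events at one temperature.

    *init* may be a coordinate array (velocities are then drawn from the
    Maxwell-Boltzmann distribution at *temperature*) or a full
    :class:`SimState`.  ``thermostat_rate`` is ghost collisions per atom per
    unit time; 0 disables the thermostat (NVE).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    tables = tables or build_pair_tables(model)
    rng = np.random.default_rng(seed)
    if isinstance(init, SimState):
        pos = np.ascontiguousarray(init.coordinates, dtype=float).copy()
        vel = np.ascontiguousarray(init.velocities, dtype=float).copy()
    else:
        pos = np.ascontiguousarray(init, dtype=float).copy()
        vel = maxwell_velocities(len(pos), temperature, rng)
    if pos.shape != (tables.n_atoms, 3):
        raise ValueError("initial coordinates incompatible with the model")
    in_well = _init_in_well(tables, pos)
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    (err, clock, n_formed, s_t, s_epot, s_kin, s_coords, n_s) = core.run_events(
        pos, vel,
        tables.pi, tables.pj, tables.kind, tables.rin2, tables.rout2,
        in_well, tables.ap_start, tables.ap_idx,
        model.epsilon, n_events, temperature, thermostat_rate,
        sample_every, record_coords, kernel_seed,
    )
    if err != core.ERR_OK:
        raise RuntimeError(
            f"event queue inconsistency (code {err}) at clock {clock}"
        )
    traj = Trajectory(
        times=s_t[:n_s].copy(),
        potential=s_epot[:n_s].copy(),
        kinetic=s_kin[:n_s].copy(),
        q=(-s_epot[:n_s] / model.epsilon) / max(tables.n_native, 1),
        temperature=temperature,
        coords=s_coords[:n_s].copy() if record_coords else None,
    )
    state = SimState(
        coordinates=pos,
        velocities=vel,
        clock=clock,
        potential_energy=-model.epsilon * n_formed,
        temperature=temperature,
    )
    return traj, state


# ---------------------------------------------------------------------------
# Replica exchange


def attempt_replica_swap(
    E_i: float, E_j: float, T_i: float, T_j: float, rng: np.random.Generator
) -> bool:
    """Metropolis neighbour swap: accept with min(1, e^{(1/Ti-1/Tj)(Ei-Ej)})."""
    if T_i <= 0 or T_j <= 0:
        raise ValueError("temperatures must be positive")
    log_p = (1.0 / T_i - 1.0 / T_j) * (E_i - E_j)
    return log_p >= 0 or math.log(rng.random()) < log_p


@dataclass
class ReplicaSet:
    """Temperature ladder with swap statistics and per-replica samples."""

    temperatures: np.ndarray
    swap_attempts: np.ndarray  # per neighbour pair
    swap_accepts: np.ndarray
    energy_samples: list[np.ndarray] = field(default_factory=list)
    q_samples: list[np.ndarray] = field(default_factory=list)
    coord_samples: list[np.ndarray] | None = None
    round_trip_times: list[int] = field(default_factory=list)
    states: list[SimState] = field(default_factory=list)

    @property
    def pair_acceptance(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.swap_accepts / np.maximum(self.swap_attempts, 1)

    @property
    def mean_acceptance(self) -> float:
        if self.swap_attempts.sum() == 0:
            return float("nan")
        return float(self.swap_accepts.sum() / self.swap_attempts.sum())

    @property
    def mean_round_trip(self) -> float:
        """Mean bottom-to-top-and-back cycle time, in RE moves."""
        if not self.round_trip_times:
            return float("nan")
        return float(np.mean(self.round_trip_times))


class _RoundTripTracker:
    """Counts replica round trips (bottom -> top -> bottom) in RE moves."""

    def __init__(self, n: int):
        self.slot_of_walker = list(range(n))
        self.n = n
        self.phase = [0] * n  # 0: heading to top, 1: heading back down
        self.start_round = [0] * n
        self.times: list[int] = []

    def swap(self, k: int):
        a = self.slot_of_walker.index(k)
        b = self.slot_of_walker.index(k + 1)
        self.slot_of_walker[a], self.slot_of_walker[b] = k + 1, k

    def update(self, round_no: int):
        for w in range(self.n):
            slot = self.slot_of_walker[w]
            if self.phase[w] == 0 and slot == self.n - 1:
                self.phase[w] = 1
            elif self.phase[w] == 1 and slot == 0:
                self.phase[w] = 0
                self.times.append(round_no - self.start_round[w])
                self.start_round[w] = round_no


def run_re_dmd(
    model: GoModel,
    grid: Sequence[float],
    events_per_replica: int,
    swap_interval: int,
    seed: int = 0,
    thermostat_rate: float = 0.1,
    sample_every: int = 500,
    record_coords: bool = False,
    init_coords: np.ndarray | None = None,
    discard_fraction: float = 0.5,
) -> ReplicaSet:
    """Replica-exchange DMD over a temperature grid.

    Each replica runs *swap_interval* events between swap rounds;
    neighbour pairs alternate even/odd parity across rounds.  Samples and
    swap statistics from the first ``discard_fraction`` of rounds are
    dropped as equilibration (swaps are still performed there, so the
    ladder mixes, but replicas start from a common configuration and the
    early acceptance rate is not representative of equilibrium).
    """
    grid = np.asarray(sorted(float(t) for t in grid))
    if len(grid) == 0 or (len(grid) > 1 and np.any(np.diff(grid) <= 0)):
        raise ValueError("temperature grid must be strictly ascending")
    k = len(grid)
    rng = np.random.default_rng(seed)
    tables = build_pair_tables(model)
    coords0 = (
        model.structure.coords if init_coords is None else np.asarray(init_coords)
    )
    pos = [coords0.copy() for _ in range(k)]
    vel = [maxwell_velocities(tables.n_atoms, t, rng) for t in grid]
    in_well = [_init_in_well(tables, p) for p in pos]
    epot = [
        -model.epsilon * float(w[tables.kind == 1].sum()) for w in in_well
    ]

    n_rounds = max(events_per_replica // swap_interval, 1)
    first_kept = int(discard_fraction * n_rounds)
    attempts = np.zeros(max(k - 1, 1), dtype=int)
    accepts = np.zeros(max(k - 1, 1), dtype=int)
    e_samples: list[list[np.ndarray]] = [[] for _ in range(k)]
    q_samples: list[list[np.ndarray]] = [[] for _ in range(k)]
    c_samples: list[list[np.ndarray]] = [[] for _ in range(k)]
    tracker = _RoundTripTracker(k)

    for rnd in range(n_rounds):
        for m in range(k):
            kernel_seed = int(rng.integers(0, 2**31 - 1))
            (err, _, n_formed, _, s_epot, _, s_coords, n_s) = core.run_events(
                pos[m], vel[m],
                tables.pi, tables.pj, tables.kind, tables.rin2, tables.rout2,
                in_well[m], tables.ap_start, tables.ap_idx,
                model.epsilon, swap_interval, float(grid[m]),
                thermostat_rate, sample_every, record_coords, kernel_seed,
            )
            if err != core.ERR_OK:
                raise RuntimeError(
                    f"event queue inconsistency (code {err}) in replica {m}"
                )
            epot[m] = -model.epsilon * n_formed
            if rnd >= first_kept and n_s:
                e_samples[m].append(s_epot[:n_s].copy())
                q_samples[m].append(
                    (-s_epot[:n_s] / model.epsilon) / max(tables.n_native, 1)
                )
                if record_coords:
                    c_samples[m].append(s_coords[:n_s].copy())
        for m in range(rnd % 2, k - 1, 2):
            if rnd >= first_kept:
                attempts[m] += 1
            if attempt_replica_swap(
                epot[m], epot[m + 1], float(grid[m]), float(grid[m + 1]), rng
            ):
                if rnd >= first_kept:
                    accepts[m] += 1
                scale_up = math.sqrt(grid[m + 1] / grid[m])
                pos[m], pos[m + 1] = pos[m + 1], pos[m]
                in_well[m], in_well[m + 1] = in_well[m + 1], in_well[m]
                vel[m], vel[m + 1] = (
                    vel[m + 1] / scale_up,
                    vel[m] * scale_up,
                )
                epot[m], epot[m + 1] = epot[m + 1], epot[m]
                tracker.swap(m)
        tracker.update(rnd + 1)

    states = [
        SimState(pos[m], vel[m], 0.0, epot[m], float(grid[m]))
        for m in range(k)
    ]
    return ReplicaSet(
        temperatures=grid,
        swap_attempts=attempts,
        swap_accepts=accepts,
        energy_samples=[
            np.concatenate(s) if s else np.zeros(0) for s in e_samples
        ],
        q_samples=[
            np.concatenate(s) if s else np.zeros(0) for s in q_samples
        ],
        coord_samples=(
            [np.concatenate(s) if s else np.zeros((0, tables.n_atoms, 3))
             for s in c_samples]
            if record_coords
            else None
        ),
        round_trip_times=tracker.times,
        states=states,
    )


def calibrate_temperature_grid(
    model: GoModel,
    t_range: tuple[float, float],
    target_acceptance: float = 0.9,
    pilot_events: int = 60_000,
    seed: int = 0,
    n_initial: int = 8,
    max_points: int = 40,
    swap_interval: int = 300,
    min_pair_slack: float = 0.05,
) -> tuple[np.ndarray, ReplicaSet]:
    """Grow a geometric temperature grid until every neighbour-pair swap
    acceptance on a pilot RE run reaches *target_acceptance*.

    Pilot acceptances are finite-sample estimates, so the stopping rule
    requires the mean acceptance to reach the target and every individual
    pair to reach ``target - min_pair_slack`` (the slack absorbs binomial
    noise of the per-pair estimates at pilot sample sizes).

    Returns the calibrated grid and the final pilot's :class:`ReplicaSet`
    (whose ``mean_round_trip`` reports the replica cycle time in RE moves).
    """
    lo, hi = t_range
    if not 0 < lo < hi:
        raise ValueError("need 0 < T_low < T_high")
    n = max(n_initial, 2)
    while True:
        grid = np.geomspace(lo, hi, n)
        pilot = run_re_dmd(
            model,
            grid,
            events_per_replica=pilot_events,
            swap_interval=swap_interval,
            seed=seed,
            discard_fraction=0.5,
        )
        acc = pilot.pair_acceptance
        n_att = int(pilot.swap_attempts.min()) if len(grid) > 1 else 1
        slack = max(
            min_pair_slack,
            2.0 * math.sqrt(target_acceptance * (1 - target_acceptance)
                            / max(n_att, 1)),
        )
        # the pilot mean must clear the target by ~2 standard errors so the
        # calibrated grid still meets the target on independent production
        # runs, not merely on the pilot that selected it
        total_att = max(int(pilot.swap_attempts.sum()), 1)
        mean_margin = 2.0 * math.sqrt(
            target_acceptance * (1 - target_acceptance) / total_att
        )
        if len(grid) == 1 or (
            pilot.mean_acceptance >= target_acceptance + mean_margin
            and float(acc.min()) >= target_acceptance - slack
        ):
            return grid, pilot
        if n >= max_points:
            raise RuntimeError(
                f"target acceptance {target_acceptance} unreachable with "
                f"{max_points} replicas (worst pair: {acc.min():.3f})"
            )
        n = min(n + 4, max_points)
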