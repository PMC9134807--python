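"""Ground-truthed synthetic fixtures for contact-topology analysis.

Three generators, each returning machine-readable ground truth alongside the
data so that every downstream computation can be checked against a known
answer:

* :func:`generate_bead_chain` — a planar self-avoiding bead chain whose
  *engineered* residue pairs are pulled into genuine spatial contact
  (centres ~3.5 Å apart, every atom pair below the 4.5 Å cutoff) while all
  other non-neighbour pairs stay far beyond detection range.  The detected
  contact map equals the engineered set exactly.
* :func:`generate_contact_trajectory` — a telegraph (two-state on/off)
  process per contact pair with configurable dwell-time laws (constant,
  exponential, truncated power law P(tau) = A tau^-gamma), discretised onto
  a uniform frame grid.  The truth records both continuous on-intervals and
  their discretised runs.
* :func:`canonical_topology_map` — contact sets with a forced pure topology:
  serial (all pairs S), nested (all P), crossed (all X).

The telegraph process is a statistical stand-in for contact kinetics in a
molecular-dynamics ensemble, not a physical polymer model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contact_mapping import (
    Contact,
    ContactMap,
    ContactParams,
    ContactTrajectory,
    contact_map_from_frame,
)
from .dynamic_ct import LifetimeTable
from .structure_io import Frame

__all__ = [
    "ChainSpec",
    "KineticSpec",
    "ConstantLaw",
    "ExponentialLaw",
    "PowerLawLaw",
    "PairTruth",
    "TelegraphTruth",
    "generate_bead_chain",
    "generate_contact_trajectory",
    "canonical_topology_map",
    "sample_truncated_power_law",
]


# ---------------------------------------------------------------------------
# dwell-time laws


@dataclass(frozen=True)
class ConstantLaw:
    """Degenerate dwell law: every dwell lasts exactly ``value`` ns."""

    value: float

    def sample(self, rng: np.random.Generator) -> float:
        return self.value


@dataclass(frozen=True)
class ExponentialLaw:
    """Memoryless dwell law with the given mean (ns)."""

    mean: float

    def sample(self, rng: np.random.Generator) -> float:
        return float(rng.exponential(self.mean))


def sample_truncated_power_law(
    rng: np.random.Generator,
    gamma: float,
    tau_min: float,
    tau_max: float,
    size: int | None = None,
):
    """Inverse-transform samples from P(tau) ∝ tau^-gamma on [tau_min, tau_max]."""
    if not 0 < tau_min < tau_max:
        raise ValueError("need 0 < tau_min < tau_max")
    u = rng.random(size)
    if abs(gamma - 1.0) < 1e-12:
        return tau_min * (tau_max / tau_min) ** u
    a = 1.0 - gamma
    return (tau_min**a + u * (tau_max**a - tau_min**a)) ** (1.0 / a)


@dataclass(frozen=True)
class PowerLawLaw:
    """Truncated scale-free dwell law P(tau) ∝ tau^-gamma on [tau_min, tau_max]."""

    gamma: float
    tau_min: float
    tau_max: float

    def __post_init__(self) -> None:
        if not 0 < self.tau_min < self.tau_max:
            raise ValueError("need 0 < tau_min < tau_max")

    def sample(self, rng: np.random.Generator) -> float:
        return float(
            sample_truncated_power_law(rng, self.gamma, self.tau_min, self.tau_max)
        )


# ---------------------------------------------------------------------------
# bead chains with engineered contacts


@dataclass(frozen=True)
class ChainSpec:
    """Bead-chain geometry: N residues, atoms per residue, bond length (Å)."""

    N: int
    atoms_per_residue: int = 8
    bond_length: float = 3.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("chain needs at least 2 residues")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.atoms_per_residue < 1:
            raise ValueError("atoms_per_residue must be >= 1")


# geometry constants chosen so contact detection is unambiguous:
# atom clouds of radius 0.3 Å around each centre; engineered centres at
# 3.5 Å (all atom pairs in [2.9, 4.1] < 4.5); any other centre pair kept
# > 5.1 Å so no atom pair can come below 4.5.
_CLOUD_RADIUS = 0.3
_PULL_DISTANCE = 3.5
_FAR_MIN = 7.0  # planar separation for |i-j| > 3
_MID_MIN = 4.0  # planar separation for 2 <= |i-j| <= 3


def _cloud_offsets(n: int) -> np.ndarray:
    """n deterministic points on a sphere of radius _CLOUD_RADIUS (golden spiral)."""
    if n == 1:
        return np.zeros((1, 3))
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return _CLOUD_RADIUS * pts


def _planar_walk(n: int, step: float, rng: np.random.Generator) -> np.ndarray:
    """Self-avoiding persistent walk in the z=0 plane.

    Enforces planar centre separations > _MID_MIN for |i-j| in {2, 3} and
    > _FAR_MIN for |i-j| > 3.  Raises RuntimeError when no placement is
    found within the retry budget.
    """
    for _ in range(60):  # walk restarts
        pts = np.zeros((n, 2))
        heading = rng.uniform(0, 2 * math.pi)
        ok = True
        for k in range(1, n):
            placed = False
            for _try in range(80):
                turn = rng.uniform(-0.45, 0.45)
                cand_heading = heading + turn
                cand = pts[k - 1] + step * np.array(
                    [math.cos(cand_heading), math.sin(cand_heading)]
                )
                d = np.linalg.norm(pts[:k] - cand, axis=1)
                sep = k - np.arange(k)
                if np.all(d[sep > 3] > _FAR_MIN) and np.all(
                    d[(sep >= 2) & (sep <= 3)] > _MID_MIN
                ):
                    pts[k] = cand
                    heading = cand_heading
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return pts
    raise RuntimeError(f"could not place a self-avoiding chain of {n} residues")


def generate_bead_chain(
    spec: ChainSpec,
    engineered_contacts: Sequence[Contact] = (),
    *,
    residue_names: Sequence[str] | None = None,
    params: ContactParams | None = None,
) -> tuple[Frame, list[Contact]]:
    """Bead chain whose detected contact map equals the engineered set.

    The chain backbone is a planar self-avoiding walk; for every engineered
    pair (i, j) residue j is lifted out of the plane to ~3.5 Å above (or
    below) residue i, so the pair is in unambiguous contact while every
    other non-neighbour pair stays beyond detection range.  Geometric limits
    of the scheme: each residue may be the *moved* endpoint of at most one
    engineered pair and the *anchor* of at most two; violations raise
    ``RuntimeError`` (generation error).

    Returns the Frame and the ground-truth contact list (sorted).  The
    generator verifies recovery with :func:`contact_map_from_frame` under
    ``params`` (default detection rules) before returning.
    """
    params = params or ContactParams()
    engineered = sorted({(min(i, j), max(i, j)) for i, j in engineered_contacts})
    for i, j in engineered:
        if not (1 <= i < j <= spec.N):
            raise ValueError(f"engineered contact ({i}, {j}) outside chain 1..{spec.N}")
        if j - i <= params.neighbor_exclusion:
            raise ValueError(
                f"engineered contact ({i}, {j}) violates the "
                f"{params.neighbor_exclusion}-neighbour exclusion"
            )
    if engineered and spec.atoms_per_residue**2 <= params.min_close_pairs:
        raise ValueError(
            "atoms_per_residue too small to exceed the close-pair threshold: "
            f"{spec.atoms_per_residue}^2 <= {params.min_close_pairs}"
        )
    moved = [j for _, j in engineered]
    if len(moved) != len(set(moved)):
        raise RuntimeError("infeasible engineered set: a residue would be moved twice")
    anchor_count: dict[int, int] = {}
    for i, _ in engineered:
        anchor_count[i] = anchor_count.get(i, 0) + 1
        if anchor_count[i] > 2:
            raise RuntimeError(f"infeasible engineered set: residue {i} anchors > 2 contacts")
    if set(moved) & set(anchor_count):
        raise RuntimeError(
            "infeasible engineered set: a residue is both moved and an anchor"
        )

    rng = np.random.default_rng(spec.seed)
    plane = _planar_walk(spec.N, spec.bond_length, rng)
    centers = np.concatenate([plane, np.zeros((spec.N, 1))], axis=1)
    # Lift each moved residue to +/- _PULL_DISTANCE above its anchor, picking
    # the side greedily so lifted residues on the same side stay > 5.2 Å apart
    # (sequence-excluded pairs need no clearance).
    anchor_side: dict[int, float] = {}
    lifted: list[tuple[np.ndarray, int]] = []
    last_side = -_PULL_DISTANCE
    for i, j in engineered:
        if i in anchor_side:
            candidates = [-anchor_side[i]]
        else:
            candidates = [-last_side, last_side]
        chosen = None
        for z in candidates:
            cand = centers[i - 1] + np.array([0.0, 0.0, z])
            if all(
                abs(j - r) <= params.neighbor_exclusion
                or np.linalg.norm(cand - c) > 5.2
                for c, r in lifted
            ):
                chosen = z
                break
        if chosen is None:
            raise RuntimeError(
                f"infeasible engineered set: no clash-free placement for ({i}, {j})"
            )
        anchor_side.setdefault(i, chosen)
        last_side = chosen
        centers[j - 1] = centers[i - 1] + np.array([0.0, 0.0, chosen])
        lifted.append((centers[j - 1].copy(), j))

    offsets = _cloud_offsets(spec.atoms_per_residue)
    positions = (centers[:, None, :] + offsets[None, :, :]).reshape(-1, 3)
    atom_residues = np.repeat(np.arange(1, spec.N + 1), spec.atoms_per_residue)
    atom_names = np.tile(
        np.array([f"C{k+1}" for k in range(spec.atoms_per_residue)], dtype=object),
        spec.N,
    )
    names = (
        np.asarray(list(residue_names), dtype=object)
        if residue_names is not None
        else np.asarray(["ALA"] * spec.N, dtype=object)
    )
    if len(names) != spec.N:
        raise ValueError("residue_names length must equal N")
    frame = Frame(
        residue_names=names,
        positions=positions,
        atom_residues=atom_residues,
        atom_names=atom_names,
    )
    detected = contact_map_from_frame(frame, params)
    if set(detected.contacts) != set(engineered):
        raise RuntimeError(
            "bead-chain generation failed to reproduce the engineered contacts "
            f"(expected {engineered}, detected {sorted(detected.contacts)})"
        )
    return frame, engineered


# ---------------------------------------------------------------------------
# telegraph contact-map trajectories


@dataclass(frozen=True)
class KineticSpec:
    """Telegraph-process specification for a synthetic contact trajectory.

    Each listed pair alternates off/on with dwell times drawn from the two
    laws; the process starts in the off state with a first off-dwell drawn
    from ``off_law``.  ``delta_t`` must divide ``total_time`` (both ns).
    """

    pairs: tuple[Contact, ...]
    on_law: ConstantLaw | ExponentialLaw | PowerLawLaw
    off_law: ConstantLaw | ExponentialLaw | PowerLawLaw
    total_time: float
    delta_t: float = 5.0
    seed: int = 0
    N: int | None = None

    def __post_init__(self) -> None:
        if self.delta_t <= 0 or self.total_time <= 0:
            raise ValueError("times must be positive")
        n = self.total_time / self.delta_t
        if abs(n - round(n)) > 1e-9:
            raise ValueError("delta_t must divide total_time")
        object.__setattr__(self, "pairs", tuple((min(i, j), max(i, j)) for i, j in self.pairs))

    @property
    def n_frames(self) -> int:
        return int(round(self.total_time / self.delta_t))

    @property
    def chain_length(self) -> int:
        return self.N if self.N is not None else max(j for _, j in self.pairs)


@dataclass(frozen=True)
class PairTruth:
    """Ground truth for one pair: continuous on-intervals and discrete runs."""

    pair: Contact
    intervals: tuple[tuple[float, float], ...]  # continuous (t_on, t_off), ns
    discrete_runs: tuple[int, ...]  # run lengths in frames, after merging
    merged: bool  # True if discretisation merged two continuous intervals

    def max_continuous(self) -> float:
        return max((t1 - t0 for t0, t1 in self.intervals), default=0.0)

    def max_discrete(self, delta_t: float) -> float:
        return max(self.discrete_runs, default=0) * delta_t

    def cumulative_discrete(self, delta_t: float) -> float:
        return sum(self.discrete_runs) * delta_t


@dataclass(frozen=True)
class TelegraphTruth:
    """Ground truth for a generated trajectory, keyed by pair."""

    records: dict[Contact, PairTruth]
    delta_t: float
    N: int

    def to_lifetime_table(self) -> LifetimeTable:
        """LifetimeTable over the pairs that are present in >= 1 frame."""
        pairs = tuple(sorted(p for p, r in self.records.items() if r.discrete_runs))
        runs = tuple(
            tuple(n * self.delta_t for n in self.records[p].discrete_runs) for p in pairs
        )
        return LifetimeTable(pairs=pairs, runs=runs, delta_t=self.delta_t, N=self.N)


def _discretize_intervals(
    intervals: Sequence[tuple[float, float]], delta_t: float, n_frames: int
) -> tuple[list[tuple[int, int]], bool]:
    """Map continuous on-intervals to merged half-open frame ranges.

    Interval endpoints are rounded to the nearest frame boundary; ranges that
    touch or overlap after rounding are merged (flagged).
    """
    spans: list[tuple[int, int]] = []
    for t0, t1 in intervals:
        f0 = int(round(t0 / delta_t))
        f1 = int(round(t1 / delta_t))
        f0, f1 = max(0, f0), min(n_frames, f1)
        if f1 > f0:
            spans.append((f0, f1))
    spans.sort()
    merged_flag = False
    merged: list[list[int]] = []
    for f0, f1 in spans:
        if merged and f0 <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], f1)
            merged_flag = True
        else:
            merged.append([f0, f1])
    return [(a, b) for a, b in merged], merged_flag


def generate_contact_trajectory(spec: KineticSpec) -> tuple[ContactTrajectory, TelegraphTruth]:
    """Simulate per-pair on/off telegraph kinetics on a uniform frame grid.

    Returns the binary contact-map trajectory and a :class:`TelegraphTruth`
    recording, for every pair, the continuous on-intervals and the
    discretised runs actually realised on the frame grid.
    """
    rng = np.random.default_rng(spec.seed)
    n_frames = spec.n_frames
    n_chain = spec.chain_length
    presence: dict[Contact, np.ndarray] = {}
    records: dict[Contact, PairTruth] = {}
    for pair in spec.pairs:
        t = 0.0
        on = False
        intervals: list[tuple[float, float]] = []
        while t < spec.total_time:
            law = spec.on_law if on else spec.off_law
            dwell = law.sample(rng)
            if on:
                intervals.append((t, min(t + dwell, spec.total_time)))
            t += dwell
            on = not on
        spans, merged = _discretize_intervals(intervals, spec.delta_t, n_frames)
        row = np.zeros(n_frames, dtype=np.uint8)
        for f0, f1 in spans:
            row[f0:f1] = 1
        presence[pair] = row
        records[pair] = PairTruth(
            pair=pair,
            intervals=tuple(intervals),
            discrete_runs=tuple(f1 - f0 for f0, f1 in spans),
            merged=merged,
        )
    maps = []
    for f in range(n_frames):
        contacts = frozenset(p for p, row in presence.items() if row[f])
        maps.append(ContactMap(N=n_chain, contacts=contacts))
    traj = ContactTrajectory(maps=tuple(maps), delta_t=spec.delta_t)
    return traj, TelegraphTruth(records=records, delta_t=spec.delta_t, N=n_chain)


# ---------------------------------------------------------------------------
# canonical pure-topology contact maps


def canonical_topology_map(
    kind: str, k: int, N: int | None = None, *, neighbor_exclusion: int = 3
) -> ContactMap:
    """Contact map of k contacts with a single forced pairwise relation.

    kind='serial' : k disjoint contacts — every pair in series.
    kind='nested' : k concentric contacts — every pair parallel.
    kind='crossed': the rotated family (t, t+k), t = 1..k — every pair cross
                    (requires k > neighbor_exclusion).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if kind == "serial":
        span = neighbor_exclusion + 2  # contact width obeying the exclusion
        contacts = [((t - 1) * span + 1, t * span) for t in range(1, k + 1)]
        needed = k * span
    elif kind == "nested":
        width = 2 * k + neighbor_exclusion + 1  # innermost range > exclusion
        contacts = [(t, width + 1 - t) for t in range(1, k + 1)]
        needed = width
    elif kind == "crossed":
        if k <= neighbor_exclusion:
            raise ValueError(
                f"crossed family needs k > neighbor_exclusion ({neighbor_exclusion})"
            )
        contacts = [(t, t + k) for t in range(1, k + 1)]
        needed = 2 * k
    else:
        raise ValueError(f"unknown canonical kind {kind!r}")
    n = N if N is not None else needed
    if n < needed:
        raise ValueError(f"chain too short for {k} {kind} contacts: need N >= {needed}")
    return ContactMap(N=n, contacts=frozenset(contacts))
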