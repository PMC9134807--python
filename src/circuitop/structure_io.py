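"""Reading atomistic structures and trajectories into per-residue atom groups.

The consumed unit is a :class:`Frame`: the coordinates of one conformation of
a single protein chain, with atoms grouped by residue and residues renumbered
to the contiguous 1..N internal index space that all downstream contact and
topology analysis uses.  A mapping back to the author (original) residue
numbering is retained for reporting.

Backed by MDAnalysis: multi-model PDB files are read one model per frame, and
trajectory formats (XTC/TRR/DCD/...) are read against a PDB/GRO topology.
Only protein residues are kept (waters, ions and other heteroatoms are
dropped); by default only the first chain (segment) is analysed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Frame",
    "Ensemble",
    "read_pdb_models",
    "read_trajectory",
    "write_pdb",
    "residue_subset_by_name",
]


@dataclass(frozen=True)
class AtomRecord:
    """One atom: 1-based residue index, atom name, position in Å."""

    residue_index: int
    atom_name: str
    position: np.ndarray

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class Frame:
    """One conformation of a chain of N residues, atoms grouped by residue.

    Atoms are stored flat: ``positions[k]`` belongs to residue
    ``atom_residues[k]`` (1-based, contiguous 1..N).  ``original_resids``
    maps internal index -> author numbering.
    """

    residue_names: np.ndarray  # (N,) str
    positions: np.ndarray  # (n_atoms, 3) float, Å
    atom_residues: np.ndarray  # (n_atoms,) int, 1-based
    atom_names: np.ndarray  # (n_atoms,) str
    original_resids: np.ndarray | None = None  # (N,) int
    frame_time: float | None = None  # ns

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.atom_residues = np.asarray(self.atom_residues, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        n = self.n_residues
        present = np.unique(self.atom_residues)
        if n == 0 or not np.array_equal(present, np.arange(1, n + 1)):
            raise ValueError("residue indices must form the contiguous set 1..N "
                             "with at least one atom each")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("atom positions must be finite")
        if self.original_resids is None:
            self.original_resids = np.arange(1, n + 1)

    @property
    def n_residues(self) -> int:
        return len(self.residue_names)

    @property
    def n_atoms(self) -> int:
        return len(self.positions)

    def residue_atoms(self, residue_index: int) -> np.ndarray:
        """(n, 3) coordinates of one residue's atoms (1-based index)."""
        if not 1 <= residue_index <= self.n_residues:
            raise IndexError(f"residue index {residue_index} out of 1..{self.n_residues}")
        return self.positions[self.atom_residues == residue_index]

    def atoms(self) -> Iterable[AtomRecord]:
        for k in range(self.n_atoms):
            yield AtomRecord(
                residue_index=int(self.atom_residues[k]),
                atom_name=str(self.atom_names[k]),
                position=self.positions[k],
            )


@dataclass
class Ensemble:
    """Ordered frames of one chain with uniform inter-frame spacing (ns)."""

    frames: list[Frame]
    delta_t: float = 5.0

    def __post_init__(self) -> None:
        lengths = {f.n_residues for f in self.frames}
        if len(lengths) > 1:
            raise ValueError("all frames must share the same chain length")
        if len(self.frames) > 1 and self.delta_t <= 0:
            raise ValueError("delta_t must be positive for multi-frame ensembles")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_residues(self) -> int:
        return self.frames[0].n_residues if self.frames else 0


def _frame_from_atomgroup(protein, frame_time: float | None = None) -> Frame:
    """Build a Frame from an MDAnalysis protein AtomGroup (first altloc kept)."""
    atoms = protein
    if hasattr(atoms, "altLocs"):
        alt = np.asarray(atoms.altLocs)
        keep = (alt == "") | (alt == "A")
        if not keep.all():
            atoms = atoms[keep]
    residues = atoms.residues
    orig = residues.resids.astype(int)
    if len(orig) > 1 and np.any(np.diff(orig) != 1):
        warnings.warn(
            "chain has non-contiguous residue numbering; renumbering 1..N "
            "in chain order", stacklevel=3,
        )
    internal_of = {rix: k + 1 for k, rix in enumerate(residues.resindices)}
    atom_residues = np.array([internal_of[rix] for rix in atoms.resindices], dtype=int)
    return Frame(
        residue_names=residues.resnames.astype(object),
        positions=atoms.positions.astype(float).copy(),
        atom_residues=atom_residues,
        atom_names=atoms.names.astype(object),
        original_resids=orig,
        frame_time=frame_time,
    )


def _select_protein(universe, chain: int | None):
    protein = universe.select_atoms("protein")
    if protein.n_residues == 0:
        raise ValueError("no protein residues found in input")
    segids = protein.segments
    if len(segids) > 1:
        idx = 0 if chain is None else chain
        protein = segids[idx].atoms.select_atoms("protein")
    elif chain not in (None, 0):
        raise ValueError(f"chain {chain} requested but input has a single chain")
    return protein


def read_pdb_models(path, *, chain: int | None = None, delta_t: float = 5.0) -> Ensemble:
    """Read a (multi-model) PDB file into an Ensemble, one Frame per MODEL.

    Residues are renumbered contiguously 1..N in chain order; the first
    alternate location is kept; non-protein residues (waters, ions, ligands)
    are dropped.  A file without protein residues raises ``ValueError``; an
    unparseable file raises ``OSError``/``ValueError`` from the reader.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except (ValueError, OSError):
            raise
        except Exception as exc:  # reader-specific parse failures
            raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    protein = _select_protein(u, chain)
    frames = []
    for ts in u.trajectory:
        frames.append(_frame_from_atomgroup(protein, frame_time=len(frames) * delta_t))
    return Ensemble(frames=frames, delta_t=delta_t)


def read_trajectory(
    topology_path,
    traj_path,
    *,
    stride: int = 1,
    chain: int | None = None,
) -> Ensemble:
    """Read a trajectory against a topology, strided, protein atoms only.

    ``delta_t`` of the returned Ensemble is the trajectory frame spacing
    (converted from the reader's ps to ns) multiplied by the stride.
    Mismatched topology/trajectory atom counts raise ``ValueError``.
    """
    import MDAnalysis as mda

    if stride < 1:
        raise ValueError("stride must be >= 1")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(topology_path), str(traj_path))
        except Exception as exc:
            raise ValueError(
                f"cannot load trajectory {traj_path} with topology {topology_path}: {exc}"
            ) from exc
    protein = _select_protein(u, chain)
    dt_ns = (u.trajectory.dt or 1.0) / 1000.0  # MDAnalysis times are in ps
    frames = []
    for ts in u.trajectory[::stride]:
        frames.append(_frame_from_atomgroup(protein, frame_time=ts.time / 1000.0))
    return Ensemble(frames=frames, delta_t=dt_ns * stride)


def write_pdb(ensemble: Ensemble, path) -> None:
    """Write an Ensemble as a multi-model PDB file (one MODEL per frame)."""
    import MDAnalysis as mda

    if not ensemble.frames:
        raise ValueError("cannot write an empty ensemble")
    f0 = ensemble.frames[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(
            n_atoms=f0.n_atoms,
            n_residues=f0.n_residues,
            atom_resindex=f0.atom_residues - 1,
            residue_segindex=np.zeros(f0.n_residues, dtype=int),
            trajectory=True,
        )
        u.add_TopologyAttr("names", [str(n) for n in f0.atom_names])
        u.add_TopologyAttr("resnames", [str(n) for n in f0.residue_names])
        u.add_TopologyAttr("resids", list(range(1, f0.n_residues + 1)))
        u.add_TopologyAttr("segids", ["A"])
        with mda.Writer(str(path), multiframe=True, n_atoms=f0.n_atoms) as writer:
            for frame in ensemble.frames:
                u.atoms.positions = frame.positions
                writer.write(u.atoms)


def residue_subset_by_name(frame: Frame, residue_name: str) -> set[int]:
    """1-based indices of residues matching a 3-letter code, e.g. 'CYS'."""
    name = residue_name.upper()
    return {
        int(k) + 1 for k, rn in enumerate(frame.residue_names) if str(rn).upper() == name
    }
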