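"""Binary residue-residue contact maps from atomistic frames.

A residue pair (i, j) is in contact in a frame when *more than*
``min_close_pairs`` atom pairs (one atom from each residue) lie strictly
below the distance cutoff, and the pair is separated by more than
``neighbor_exclusion`` positions along the sequence.  Defaults follow the
standard heavy-use convention for disordered-chain contact analysis:
4.5 Å cutoff, more than five close atom pairs, the three nearest sequence
neighbours excluded.

Notes on conventions (all configurable):

* "more than five atoms" is interpreted as more than five atom *pairs*
  below the cutoff (strictly > 5, i.e. >= 6) — pairs are the quantity a
  distance computation naturally enumerates;
* distances compare with strict ``<`` (ties at exactly the cutoff do not
  count);
* every atom present in the input is used — no heavy-atom filtering.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

if TYPE_CHECKING:  # pragma: no cover
    from .structure_io import Ensemble, Frame

__all__ = [
    "Contact",
    "ContactParams",
    "ContactMap",
    "ContactTrajectory",
    "count_close_atom_pairs",
    "contact_map_from_frame",
    "contact_maps_for_ensemble",
    "write_contact_map_tsv",
    "read_contact_map_tsv",
    "write_trajectory_tsv",
    "read_trajectory_tsv",
]

#: A contact is an unordered residue-index pair stored as (i, j), i < j.
Contact = tuple[int, int]


@dataclass(frozen=True)
class ContactParams:
    """Contact-detection rule parameters.

    cutoff : Å; atom-pair distances must be strictly below this.
    min_close_pairs : contact requires strictly more than this many close
        atom pairs (default 5, i.e. at least 6).
    neighbor_exclusion : residue pairs with ``j - i <= neighbor_exclusion``
        are never contacts (default 3: the three nearest chain neighbours).
    """

    cutoff: float = 4.5
    min_close_pairs: int = 5
    neighbor_exclusion: int = 3

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.min_close_pairs < 0 or self.neighbor_exclusion < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class ContactMap:
    """Set of residue-residue contacts of one frame on a chain of length N."""

    N: int
    contacts: frozenset[Contact]
    params: ContactParams | None = None

    def __post_init__(self) -> None:
        for i, j in self.contacts:
            if not (1 <= i < j <= self.N):
                raise ValueError(f"contact ({i}, {j}) out of range for N={self.N}")

    def __len__(self) -> int:
        return len(self.contacts)

    def __contains__(self, c: Contact) -> bool:
        return tuple(c) in self.contacts

    def to_matrix(self) -> np.ndarray:
        """Dense symmetric 0/1 matrix, shape (N, N), 0-based indexing."""
        mat = np.zeros((self.N, self.N), dtype=np.uint8)
        for i, j in self.contacts:
            mat[i - 1, j - 1] = mat[j - 1, i - 1] = 1
        return mat

    @classmethod
    def from_matrix(cls, mat: np.ndarray, params: ContactParams | None = None) -> "ContactMap":
        mat = np.asarray(mat)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("contact matrix must be square")
        ii, jj = np.nonzero(np.triu(mat, k=1))
        contacts = frozenset((int(a) + 1, int(b) + 1) for a, b in zip(ii, jj))
        return cls(N=mat.shape[0], contacts=contacts, params=params)


@dataclass(frozen=True)
class ContactTrajectory:
    """Time-ordered contact maps with uniform frame spacing ``delta_t`` (ns)."""

    maps: tuple[ContactMap, ...]
    delta_t: float = 5.0

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("a contact trajectory needs at least one frame")
        if len({m.N for m in self.maps}) != 1:
            raise ValueError("all frames must share the same chain length N")
        if len(self.maps) > 1 and self.delta_t <= 0:
            raise ValueError("delta_t must be positive")

    @property
    def N(self) -> int:
        return self.maps[0].N

    @property
    def n_frames(self) -> int:
        return len(self.maps)

    def __iter__(self):
        return iter(self.maps)


def count_close_atom_pairs(
    res_a: np.ndarray, res_b: np.ndarray, cutoff: float
) -> int:
    """Number of inter-residue atom pairs strictly below ``cutoff`` (Å).

    ``res_a`` and ``res_b`` are (n_atoms, 3) coordinate arrays of the two
    residues.  Raises ``ValueError`` on an empty atom group.
    """
    a = np.atleast_2d(np.asarray(res_a, dtype=float))
    b = np.atleast_2d(np.asarray(res_b, dtype=float))
    if a.size == 0 or b.size == 0:
        raise ValueError("atom groups must be non-empty")
    return int((cdist(a, b) < cutoff).sum())


def contact_map_from_frame(frame: "Frame", params: ContactParams | None = None) -> ContactMap:
    """Detect all residue-residue contacts of one frame.

    A k-d tree over all atoms finds candidate close atom pairs; pair counts
    are accumulated per residue pair and the detection rule (strictly more
    than ``min_close_pairs`` pairs strictly below ``cutoff``, sequence
    separation above ``neighbor_exclusion``) is applied.
    """
    params = params or ContactParams()
    if frame.n_residues < 2:
        raise ValueError("contact mapping needs a chain of at least 2 residues")
    pos = frame.positions
    resid = frame.atom_residues  # 1-based residue index per atom
    tree = cKDTree(pos)
    # query_pairs uses <= r; recheck with strict < below.
    candidates = tree.query_pairs(r=params.cutoff, output_type="ndarray")
    counts: dict[Contact, int] = {}
    if len(candidates):
        d = np.linalg.norm(pos[candidates[:, 0]] - pos[candidates[:, 1]], axis=1)
        keep = candidates[d < params.cutoff]
        ra = resid[keep[:, 0]]
        rb = resid[keep[:, 1]]
        lo = np.minimum(ra, rb)
        hi = np.maximum(ra, rb)
        sep_ok = (hi - lo) > params.neighbor_exclusion
        for i, j in zip(lo[sep_ok], hi[sep_ok]):
            key = (int(i), int(j))
            counts[key] = counts.get(key, 0) + 1
    contacts = frozenset(c for c, n in counts.items() if n > params.min_close_pairs)
    return ContactMap(N=frame.n_residues, contacts=contacts, params=params)


def contact_maps_for_ensemble(
    ensemble: "Ensemble", params: ContactParams | None = None
) -> ContactTrajectory:
    """One contact map per ensemble frame, same chain length and parameters."""
    if not ensemble.frames:
        raise ValueError("ensemble has no frames")
    params = params or ContactParams()
    maps = tuple(contact_map_from_frame(f, params) for f in ensemble.frames)
    return ContactTrajectory(maps=maps, delta_t=ensemble.delta_t)


# ---------------------------------------------------------------------------
# TSV dialect: 3 columns (i, j, 1) with a header comment carrying N and params


def _params_header(params: ContactParams | None) -> str:
    p = params or ContactParams()
    return (
        f"cutoff={p.cutoff}\tmin_close_pairs={p.min_close_pairs}"
        f"\tneighbor_exclusion={p.neighbor_exclusion}"
    )


def write_contact_map_tsv(cmap: ContactMap, path_or_buf) -> None:
    """Write a contact map as 3-column TSV (i, j, 1) with an N/params header."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"# N={cmap.N}\t{_params_header(cmap.params)}\n")
        fh.write("i\tj\tcontact\n")
        for i, j in sorted(cmap.contacts):
            fh.write(f"{i}\t{j}\t1\n")
    finally:
        if own:
            fh.close()


def _parse_header(line: str) -> tuple[int, ContactParams]:
    fields = dict(
        item.split("=", 1) for item in line.lstrip("# ").strip().split("\t") if "=" in item
    )
    params = ContactParams(
        cutoff=float(fields.get("cutoff", 4.5)),
        min_close_pairs=int(fields.get("min_close_pairs", 5)),
        neighbor_exclusion=int(fields.get("neighbor_exclusion", 3)),
    )
    return int(fields["N"]), params


def read_contact_map_tsv(path_or_buf) -> ContactMap:
    """Read a contact map written by :func:`write_contact_map_tsv`."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("missing contact-map header line ('# N=...')")
        n, params = _parse_header(header)
        contacts: set[Contact] = set()
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "i\t")):
                continue
            i, j, flag = line.split("\t")
            if int(flag):
                contacts.add((int(i), int(j)))
    finally:
        if own:
            fh.close()
    return ContactMap(N=n, contacts=frozenset(contacts), params=params)


def write_trajectory_tsv(traj: ContactTrajectory, path) -> None:
    """Write a trajectory as blocks of contact-map TSV separated by '## frame'."""
    with open(path, "w") as fh:
        fh.write(f"## frames={traj.n_frames}\tdelta_t={traj.delta_t}\n")
        for k, cmap in enumerate(traj.maps):
            fh.write(f"## frame={k}\n")
            write_contact_map_tsv(cmap, fh)


def read_trajectory_tsv(path) -> ContactTrajectory:
    """Read a trajectory written by :func:`write_trajectory_tsv`."""
    with open(path) as fh:
        text = fh.read()
    lines = text.splitlines()
    if not lines or not lines[0].startswith("## frames="):
        raise ValueError("missing trajectory header ('## frames=...')")
    meta = dict(item.split("=", 1) for item in lines[0].lstrip("# ").split("\t"))
    delta_t = float(meta["delta_t"])
    blocks: list[list[str]] = []
    for line in lines[1:]:
        if line.startswith("## frame="):
            blocks.append([])
        elif blocks:
            blocks[-1].append(line)
    maps = tuple(read_contact_map_tsv(io.StringIO("\n".join(b) + "\n")) for b in blocks)
    return ContactTrajectory(maps=maps, delta_t=delta_t)
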