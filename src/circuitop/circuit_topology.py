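"""Series / parallel / cross classification of intra-chain contacts.

Circuit topology describes a folded chain by the pairwise arrangement of its
intra-chain contacts.  Each contact occupies a chain interval [i, j] (residue
indices, i < j).  Any two distinct contacts stand in exactly one of three
relations:

* **series (S)** — the intervals do not intersect (different chain sections);
* **parallel (P)** — one interval is nested inside the other;
* **cross (X)** — the intervals partially overlap: they intersect but neither
  contains the other.

Contacts sharing an endpoint are folded into the three-class scheme with
non-strict interval comparisons: tangent-disjoint counts as S, tangent-nested
as P.  The (n_S, n_P, n_X) census over all contact pairs is the simplest
topological fingerprint of a conformation, and its normalised fractions
(f_S, f_P, f_X) trace a trajectory on the 2-simplex when followed over time.

The module also provides contact-range (sequence-separation) statistics,
including the data-driven long-range threshold lambda = <d> + sigma_d, and
per-region long-range contact densities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .contact_mapping import Contact, ContactMap, ContactTrajectory

__all__ = [
    "Relation",
    "TopologyFractions",
    "RangeStats",
    "RegionSpec",
    "AR_NTD_REGIONS",
    "classify_relation",
    "topology_fractions",
    "topology_restricted",
    "possible_pairs",
    "contact_range",
    "range_stats",
    "long_range_density",
    "topology_trajectory",
]

#: The three circuit-topology relations.
Relation = str  # one of "S", "P", "X"

S, P, X = "S", "P", "X"


def classify_relation(c1: Contact, c2: Contact) -> Relation:
    """Classify the arrangement of two contacts as series, parallel or cross.

    Parameters
    ----------
    c1, c2
        Contacts ``(i, j)`` with ``i < j`` on the same chain.  The relation is
        symmetric in its arguments.

    Returns
    -------
    str
        ``"S"`` if the intervals are disjoint (a shared endpoint counts as S),
        ``"P"`` if one interval is nested in the other (shared endpoints count
        as P), ``"X"`` otherwise (partial overlap).

    Raises
    ------
    ValueError
        If the two contacts are identical.
    """
    i1, j1 = c1
    i2, j2 = c2
    if (i1, j1) == (i2, j2):
        raise ValueError(f"cannot classify a contact against itself: {c1}")
    if j1 <= i2 or j2 <= i1:
        return S
    if (i1 <= i2 and j2 <= j1) or (i2 <= i1 and j1 <= j2):
        return P
    return X


@dataclass(frozen=True)
class TopologyFractions:
    """S/P/X census over all contact pairs of one contact map.

    ``n_S + n_P + n_X == m * (m - 1) // 2`` where ``m`` is the number of
    contacts.  Fractions are ``None`` when fewer than two contacts exist
    (the census is then empty and fractions are undefined).
    """

    n_S: int
    n_P: int
    n_X: int
    m: int

    @property
    def n_pairs(self) -> int:
        return self.m * (self.m - 1) // 2

    def _frac(self, n: int) -> float | None:
        return n / self.n_pairs if self.n_pairs > 0 else None

    @property
    def f_S(self) -> float | None:
        return self._frac(self.n_S)

    @property
    def f_P(self) -> float | None:
        return self._frac(self.n_P)

    @property
    def f_X(self) -> float | None:
        return self._frac(self.n_X)

    def as_dict(self) -> dict:
        return {
            "m": self.m,
            "n_S": self.n_S,
            "n_P": self.n_P,
            "n_X": self.n_X,
            "f_S": self.f_S,
            "f_P": self.f_P,
            "f_X": self.f_X,
        }


def _census(contacts: Sequence[Contact]) -> TopologyFractions:
    """Vectorised S/P/X census over all unordered pairs of ``contacts``."""
    m = len(contacts)
    if m < 2:
        return TopologyFractions(0, 0, 0, m)
    arr = np.asarray(sorted(contacts), dtype=np.int64)
    i = arr[:, 0]
    j = arr[:, 1]
    # upper-triangle index pairs (p < q)
    p, q = np.triu_indices(m, k=1)
    i1, j1, i2, j2 = i[p], j[p], i[q], j[q]
    s = (j1 <= i2) | (j2 <= i1)
    par = ~s & (((i1 <= i2) & (j2 <= j1)) | ((i2 <= i1) & (j1 <= j2)))
    n_s = int(s.sum())
    n_p = int(par.sum())
    n_x = len(p) - n_s - n_p
    return TopologyFractions(n_s, n_p, n_x, m)


def topology_fractions(cmap: ContactMap) -> TopologyFractions:
    """S/P/X counts and fractions over all contact pairs of a contact map."""
    return _census(list(cmap.contacts))


def topology_restricted(
    cmap: ContactMap, predicate: Callable[[Contact], bool]
) -> TopologyFractions:
    """S/P/X census restricted to contacts satisfying ``predicate``.

    Used e.g. for the topology of long-range contacts only
    (``predicate=lambda c: contact_range(c) >= lam``) or of contacts within
    one chain region.
    """
    return _census([c for c in cmap.contacts if predicate(c)])


def topology_trajectory(traj: ContactTrajectory) -> list[TopologyFractions]:
    """Per-frame S/P/X census along a contact-map trajectory."""
    return [topology_fractions(m) for m in traj.maps]


def possible_pairs(subset: Iterable[int]) -> int:
    """Number of distinct contacts a residue subset can form: k*(k-1)/2."""
    k = len(set(subset))
    return k * (k - 1) // 2


def contact_range(c: Contact) -> int:
    """Sequence separation j - i of a contact (its chain 'range')."""
    i, j = c
    return j - i


@dataclass(frozen=True)
class RegionSpec:
    """A named chain region as a union of closed residue-index intervals."""

    name: str
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for start, end in self.intervals:
            if not (1 <= start <= end):
                raise ValueError(f"invalid interval ({start}, {end}) in region {self.name!r}")

    def __contains__(self, residue: int) -> bool:
        return any(start <= residue <= end for start, end in self.intervals)

    @property
    def length(self) -> int:
        return sum(end - start + 1 for start, end in self.intervals)


#: Region preset for the androgen-receptor N-terminal domain (538 residues):
#: N-terminal region NR = 1-224, C-terminal region CR = 225-538, with the
#: compact CR core 355-469.  The CR shell is quoted in the source figure as
#: 255-354 ∪ 470-538, which leaves residues 225-254 unassigned relative to
#: the CR start at 225; both readings are kept verbatim rather than guessing
#: which boundary is a typo.
AR_NTD_REGIONS: dict[str, RegionSpec] = {
    "NR": RegionSpec("NR", ((1, 224),)),
    "CR": RegionSpec("CR", ((225, 538),)),
    "CR_core": RegionSpec("CR_core", ((355, 469),)),
    "CR_shell": RegionSpec("CR_shell", ((255, 354), (470, 538))),
}


@dataclass(frozen=True)
class RangeStats:
    """Contact-range statistics with the long-range threshold lambda.

    ``per_residue_mean_range`` maps each residue that participates in at
    least one contact to the mean sequence separation of its contacts,
    pooled over all frames.  ``mean_range`` (<d>) and ``std_range`` (sigma_d,
    population) are taken over that per-residue distribution by default, and
    ``lam`` = <d> + sigma_d is the threshold above which a contact counts as
    long-range.
    """

    per_residue_mean_range: Mapping[int, float]
    mean_range: float
    std_range: float
    lam: float
    pooled_ranges: tuple[int, ...] = field(repr=False, default=())

    def as_dict(self) -> dict:
        return {
            "mean_range": self.mean_range,
            "std_range": self.std_range,
            "lambda": self.lam,
            "n_residues": len(self.per_residue_mean_range),
        }


def range_stats(
    maps: ContactTrajectory | ContactMap,
    *,
    per_contact: bool = False,
    ddof: int = 0,
) -> RangeStats:
    """Contact-range distribution and long-range threshold over a trajectory.

    Parameters
    ----------
    maps
        A contact-map trajectory or a single contact map.
    per_contact
        If True, <d> and sigma_d are computed over the pooled per-contact
        ranges instead of the per-residue mean ranges (the default follows
        the per-residue-average reading of the range distribution).
    ddof
        Delta degrees of freedom for sigma_d; 0 (population) by default.

    Raises
    ------
    ValueError
        If no contact is present anywhere.
    """
    map_list = maps.maps if isinstance(maps, ContactTrajectory) else [maps]
    per_res: dict[int, list[int]] = {}
    pooled: list[int] = []
    for cmap in map_list:
        for c in cmap.contacts:
            d = contact_range(c)
            pooled.append(d)
            for res in c:
                per_res.setdefault(res, []).append(d)
    if not pooled:
        raise ValueError("range_stats requires at least one contact")
    per_res_mean = {res: float(np.mean(ds)) for res, ds in sorted(per_res.items())}
    values = (
        np.asarray(pooled, dtype=float)
        if per_contact
        else np.asarray(list(per_res_mean.values()))
    )
    mean = float(values.mean())
    std = float(values.std(ddof=ddof)) if values.size > 1 else 0.0
    return RangeStats(
        per_residue_mean_range=per_res_mean,
        mean_range=mean,
        std_range=std,
        lam=mean + std,
        pooled_ranges=tuple(pooled),
    )


def long_range_density(
    maps: ContactTrajectory | ContactMap,
    lam: float,
    regions: Sequence[RegionSpec],
) -> dict[str, float]:
    """Density of long-range contacts (range >= lam) per region.

    For each region the count of distinct contacts with *both* endpoints in
    the region and sequence separation >= ``lam``, divided by the region
    length in residues.  Long-range contacts whose endpoints fall in no
    single listed region are tallied under ``"inter-region"`` (count, not a
    density, since no region length applies).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    map_list = maps.maps if isinstance(maps, ContactTrajectory) else [maps]
    long_contacts: set[Contact] = set()
    for cmap in map_list:
        long_contacts.update(c for c in cmap.contacts if contact_range(c) >= lam)
    out: dict[str, float] = {}
    assigned: set[Contact] = set()
    for region in regions:
        inside = {c for c in long_contacts if c[0] in region and c[1] in region}
        assigned |= inside
        out[region.name] = len(inside) / region.length
    out["inter-region"] = float(len(long_contacts - assigned))
    return out
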