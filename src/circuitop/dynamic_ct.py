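"""Dynamic circuit topology: contact lifetimes, kymographs and regime filters.

A contact-map trajectory is condensed into a *kymograph*: a binary matrix
whose rows are the residue pairs that are ever in contact and whose columns
are frames.  Runs of consecutive presence give per-contact lifetimes
(run length x frame spacing); the maximum lifetime per pair defines the
contact-lifetime distribution, which for disordered chains tends to follow a
scale-free law P(tau) = A * tau^-gamma over a wide range of time scales.

Lifetime *regimes* (short / middle / long; defaults 0-0.5, 0.5-2 and > 2 us)
partition the contact pairs by maximum lifetime.  Masking a trajectory to one
regime and re-running the S/P/X census yields time-scale-resolved topology
trajectories.  The per-residue C-factor is the mean maximum contact lifetime
over all contacts a residue participates in.

All times are in nanoseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .circuit_topology import TopologyFractions, _census
from .contact_mapping import Contact, ContactTrajectory

__all__ = [
    "Kymograph",
    "LifetimeTable",
    "PowerLawFit",
    "RegimeSpec",
    "DEFAULT_REGIMES",
    "CFactorProfile",
    "build_kymograph",
    "run_lifetimes",
    "lifetime_table",
    "fit_power_law",
    "fit_power_law_density",
    "fit_power_law_mle",
    "regime_mask",
    "filtered_topology_trajectory",
    "c_factor",
    "cumulative_contact_time",
]


@dataclass(frozen=True)
class Kymograph:
    """Contact presence matrix: rows = pairs ever in contact, columns = frames."""

    pairs: tuple[Contact, ...]
    presence: np.ndarray  # (n_pairs, n_frames) uint8
    delta_t: float  # ns
    N: int

    @property
    def n_frames(self) -> int:
        return self.presence.shape[1]

    def row(self, pair: Contact) -> np.ndarray:
        return self.presence[self.pairs.index(tuple(pair))]


def build_kymograph(traj: ContactTrajectory) -> Kymograph:
    """Stack a contact-map trajectory into a kymograph.

    Rows are exactly the residue pairs appearing in at least one frame
    (pairs that never participate are removed), in sorted order; columns
    follow frame order.  A trajectory with no contacts yields a 0-row
    kymograph, not an error.
    """
    pair_set: set[Contact] = set()
    for cmap in traj.maps:
        pair_set.update(cmap.contacts)
    pairs = tuple(sorted(pair_set))
    index = {p: r for r, p in enumerate(pairs)}
    presence = np.zeros((len(pairs), traj.n_frames), dtype=np.uint8)
    for col, cmap in enumerate(traj.maps):
        for c in cmap.contacts:
            presence[index[c], col] = 1
    return Kymograph(pairs=pairs, presence=presence, delta_t=traj.delta_t, N=traj.N)


def run_lifetimes(row: Sequence[int], delta_t: float, *, gap_tolerance: int = 0) -> list[float]:
    """Lifetimes (ns) of the maximal presence runs in one binary row.

    A run is a maximal stretch of consecutive 1s; its lifetime is the run
    length times ``delta_t``.  With ``gap_tolerance`` g > 0, runs separated
    by at most g absent frames are merged (the gap frames do not add to the
    lifetime).  Default g = 0: a single absent frame splits a run.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    arr = np.asarray(row, dtype=bool).astype(np.int8)
    if arr.size == 0 or not arr.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], arr, [0]))))
    starts, ends = edges[::2], edges[1::2]  # runs are [start, end)
    if gap_tolerance > 0:
        merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
        for s, e in zip(starts[1:], ends[1:]):
            if s - merged[-1][1] <= gap_tolerance:
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e)])
        # lifetime counts only present frames within the merged span
        out = []
        for s, e in merged:
            out.append(float(arr[s:e].sum()) * delta_t)
        return out
    return [float(e - s) * delta_t for s, e in zip(starts, ends)]


@dataclass(frozen=True)
class LifetimeTable:
    """Per-pair run lifetimes with maxima and cumulative contact times (ns)."""

    pairs: tuple[Contact, ...]
    runs: tuple[tuple[float, ...], ...]
    delta_t: float
    N: int

    @property
    def max_lifetime(self) -> np.ndarray:
        return np.array([max(r) if r else 0.0 for r in self.runs])

    @property
    def cumulative_time(self) -> np.ndarray:
        return np.array([sum(r) for r in self.runs])

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "i": [p[0] for p in self.pairs],
                "j": [p[1] for p in self.pairs],
                "n_runs": [len(r) for r in self.runs],
                "max_lifetime_ns": self.max_lifetime,
                "cumulative_time_ns": self.cumulative_time,
            }
        )


def lifetime_table(kymo: Kymograph, *, gap_tolerance: int = 0) -> LifetimeTable:
    """Run lifetimes, maximum and cumulative contact time for every pair."""
    runs = tuple(
        tuple(run_lifetimes(kymo.presence[r], kymo.delta_t, gap_tolerance=gap_tolerance))
        for r in range(len(kymo.pairs))
    )
    return LifetimeTable(pairs=kymo.pairs, runs=runs, delta_t=kymo.delta_t, N=kymo.N)


@dataclass(frozen=True)
class PowerLawFit:
    """Scale-free lifetime law P(tau) = A * tau^-gamma fitted on log-log axes."""

    A: float
    gamma: float
    fit_window: tuple[float, float]  # ns
    r_squared: float
    n_bins_used: int = 0

    def density(self, tau: np.ndarray) -> np.ndarray:
        return self.A * np.asarray(tau, dtype=float) ** (-self.gamma)

    def as_dict(self) -> dict:
        return {
            "A": self.A,
            "gamma": self.gamma,
            "fit_window_ns": list(self.fit_window),
            "r_squared": self.r_squared,
            "n_bins_used": self.n_bins_used,
        }


def fit_power_law_density(tau: Sequence[float], density: Sequence[float]) -> PowerLawFit:
    """Fit P = A * tau^-gamma to given (tau, density) points by log-log least squares.

    Requires >= 2 distinct positive tau values with positive density; exact
    power-law input is recovered exactly (gamma = -slope, A = 10^intercept).
    """
    t = np.asarray(tau, dtype=float)
    d = np.asarray(density, dtype=float)
    keep = (t > 0) & (d > 0)
    t, d = t[keep], d[keep]
    if len(np.unique(t)) < 2:
        raise ValueError("power-law fit needs at least two distinct positive tau values")
    res = stats.linregress(np.log10(t), np.log10(d))
    return PowerLawFit(
        A=float(10.0 ** res.intercept),
        gamma=float(-res.slope),
        fit_window=(float(t.min()), float(t.max())),
        r_squared=float(res.rvalue**2),
        n_bins_used=len(t),
    )


def fit_power_law(
    max_lifetimes: Sequence[float],
    window: tuple[float, float] | None = None,
    *,
    n_bins: int = 25,
) -> PowerLawFit:
    """Fit the scale-free law to a sample of (maximum) lifetimes.

    Lifetimes inside ``window`` (default: full observed range) are histogrammed
    into logarithmically spaced bins; the count density (count / bin width,
    normalised by sample size) against the geometric bin centre is fitted by
    linear regression on log-log axes.  Returns gamma (negated slope), the
    amplitude A and the regression R^2.

    Raises ``ValueError`` for degenerate data (fewer than two distinct values
    in the window).
    """
    tau = np.asarray(max_lifetimes, dtype=float)
    tau = tau[tau > 0]
    if window is not None:
        lo, hi = window
        tau = tau[(tau >= lo) & (tau <= hi)]
    if tau.size < 2 or len(np.unique(tau)) < 2:
        raise ValueError("power-law fit needs >= 2 distinct lifetimes in the window")
    lo, hi = float(tau.min()), float(tau.max())
    edges = np.logspace(np.log10(lo), np.log10(hi * (1 + 1e-12)), n_bins + 1)
    counts, edges = np.histogram(tau, bins=edges)
    widths = np.diff(edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    dens = counts / (widths * tau.size)
    keep = counts > 0
    fit = fit_power_law_density(centers[keep], dens[keep])
    return PowerLawFit(
        A=fit.A,
        gamma=fit.gamma,
        fit_window=(lo, hi),
        r_squared=fit.r_squared,
        n_bins_used=int(keep.sum()),
    )


def fit_power_law_mle(
    max_lifetimes: Sequence[float],
    window: tuple[float, float] | None = None,
) -> PowerLawFit:
    """Maximum-likelihood exponent for a truncated power law on [lo, hi].

    Alternative to the log-log binned regression, robust to binning choices.
    The amplitude A is the normalisation constant of the fitted density.
    """
    tau = np.asarray(max_lifetimes, dtype=float)
    tau = tau[tau > 0]
    if window is not None:
        lo, hi = window
        tau = tau[(tau >= lo) & (tau <= hi)]
    if tau.size < 2 or len(np.unique(tau)) < 2:
        raise ValueError("power-law fit needs >= 2 distinct lifetimes in the window")
    lo, hi = float(tau.min()), float(tau.max())
    slog = float(np.log(tau).sum())
    n = tau.size

    def neg_loglik(gamma: float) -> float:
        if abs(gamma - 1.0) < 1e-9:
            norm = math.log(math.log(hi / lo))
        else:
            a = 1.0 - gamma
            norm = math.log((hi**a - lo**a) / a)
        return gamma * slog + n * norm

    res = optimize.minimize_scalar(neg_loglik, bounds=(0.01, 6.0), method="bounded")
    gamma = float(res.x)
    a = 1.0 - gamma
    A = a / (hi**a - lo**a) if abs(a) > 1e-9 else 1.0 / math.log(hi / lo)
    return PowerLawFit(A=float(A), gamma=gamma, fit_window=(lo, hi), r_squared=float("nan"))


@dataclass(frozen=True)
class RegimeSpec:
    """A lifetime regime: half-open interval [lo, hi) in ns.

    The defaults partition lifetimes at 500 ns (0.5 us) and 2000 ns (2 us):
    short [0, 500), middle [500, 2000), long [2000, inf).  Half-open bounds
    give every boundary value exactly one regime.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("regime bounds must satisfy lo < hi")

    def __contains__(self, lifetime: float) -> bool:
        return self.lo <= lifetime < self.hi


DEFAULT_REGIMES: dict[str, RegimeSpec] = {
    "short": RegimeSpec("short", 0.0, 500.0),
    "middle": RegimeSpec("middle", 500.0, 2000.0),
    "long": RegimeSpec("long", 2000.0, float("inf")),
}


def regime_mask(table: LifetimeTable, regime: RegimeSpec) -> set[Contact]:
    """Pairs whose *maximum* lifetime falls in the regime's [lo, hi) window."""
    mx = table.max_lifetime
    return {p for p, m in zip(table.pairs, mx) if float(m) in regime}


def filtered_topology_trajectory(
    traj: ContactTrajectory, mask: Iterable[Contact]
) -> list[TopologyFractions]:
    """Per-frame S/P/X census after intersecting each frame with a pair mask.

    Equivalent to multiplying every binary contact matrix elementwise with
    the 0/1 filter matrix defined by ``mask``.
    """
    mask_set = {tuple(p) for p in mask}
    return [_census([c for c in cmap.contacts if c in mask_set]) for cmap in traj.maps]


@dataclass(frozen=True)
class CFactorProfile:
    """Per-residue mean maximum contact lifetime (ns); NaN where no contacts."""

    values: np.ndarray  # (N,), NaN for residues without contacts

    @property
    def N(self) -> int:
        return len(self.values)

    def __getitem__(self, residue: int) -> float:
        return float(self.values[residue - 1])


def c_factor(table: LifetimeTable, N: int | None = None) -> CFactorProfile:
    """C-factor: per residue, the mean max lifetime over its contacts.

    Residues participating in no contact carry NaN (no value), not zero.
    """
    n = N if N is not None else table.N
    total = np.zeros(n)
    count = np.zeros(n, dtype=int)
    for (i, j), m in zip(table.pairs, table.max_lifetime):
        total[i - 1] += m
        total[j - 1] += m
        count[i - 1] += 1
        count[j - 1] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return CFactorProfile(values=values)


def cumulative_contact_time(kymo: Kymograph, subset: Iterable[int]) -> dict[Contact, float]:
    """Cumulative contact time (ns) for every pair within a residue subset.

    All |subset| * (|subset| - 1) / 2 candidate pairs are reported; pairs
    never in contact carry 0.  Useful e.g. for the census of possible
    cysteine-cysteine contacts.
    """
    members = sorted(set(subset))
    out: dict[Contact, float] = {
        (a, b): 0.0 for k, a in enumerate(members) for b in members[k + 1 :]
    }
    counts = kymo.presence.sum(axis=1)
    for pair, cnt in zip(kymo.pairs, counts):
        if pair in out:
            out[pair] = float(cnt) * kymo.delta_t
    return out
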