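"""Contact-lifetime analysis of a synthetic trajectory.

Simulates telegraph on/off kinetics with scale-free on-dwells for 200 contact
pairs over 1000 frames (5 ns apart), builds the kymograph, fits the lifetime
law P(tau) = A tau^-gamma, partitions pairs into short/middle/long lifetime
regimes, and reports the per-residue C-factor range.
"""

import numpy as np

from circuitop import (
    DEFAULT_REGIMES,
    ExponentialLaw,
    KineticSpec,
    PowerLawLaw,
    build_kymograph,
    c_factor,
    filtered_topology_trajectory,
    fit_power_law,
    lifetime_table,
    regime_mask,
)
from circuitop.synthetic_data import generate_contact_trajectory

spec = KineticSpec(
    pairs=tuple((i, i + 10) for i in range(1, 201)),
    on_law=PowerLawLaw(gamma=1.5, tau_min=5.0, tau_max=2000.0),
    off_law=ExponentialLaw(mean=5000.0),
    total_time=5000.0,
    delta_t=5.0,
    seed=2,
)
traj, truth = generate_contact_trajectory(spec)
kymo = build_kymograph(traj)
table = lifetime_table(kymo)

print(f"kymograph: {len(kymo.pairs)} pairs ever in contact x {kymo.n_frames} frames")
fit = fit_power_law(table.max_lifetime)
print(f"lifetime law fit: gamma = {fit.gamma:.3f} (truth 1.5), R^2 = {fit.r_squared:.3f}")

for name, regime in DEFAULT_REGIMES.items():
    mask = regime_mask(table, regime)
    fracs = filtered_topology_trajectory(traj, mask)
    defined = [f for f in fracs if f.n_pairs > 0]
    print(f"{name:>6} regime: {len(mask):3d} pairs, "
          f"{len(defined)} frames with a defined S/P/X census")

prof = c_factor(table)
vals = prof.values[~np.isnan(prof.values)]
print(f"C-factor over {len(vals)} contact-forming residues: "
      f"{vals.min():.0f}-{vals.max():.0f} ns (mean {vals.mean():.0f} ns)")
print("\nThe exponent gamma characterises how steeply short-lived contacts dominate;")
print("regime masks isolate the contacts driving topology at each time scale.")
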