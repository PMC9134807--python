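"""Contact-range statistics and long-range contact density by chain region.

Builds a synthetic trajectory with mixed short- and long-range contacts on a
538-residue chain, computes the per-residue mean contact range, the data-driven
long-range threshold lambda = <d> + sigma_d, and the density of long-range
contacts inside the named regions of the androgen-receptor N-terminal domain
preset (NR 1-224, CR 225-538, CR core 355-469).
"""

import numpy as np

from circuitop import (
    AR_NTD_REGIONS,
    ExponentialLaw,
    KineticSpec,
    long_range_density,
    range_stats,
)
from circuitop.synthetic_data import generate_contact_trajectory

rng = np.random.default_rng(5)
pairs = set()
while len(pairs) < 150:
    i = int(rng.integers(1, 520))
    sep = int(rng.integers(4, min(200, 538 - i) + 1))
    pairs.add((i, i + sep))

spec = KineticSpec(
    pairs=tuple(sorted(pairs)),
    on_law=ExponentialLaw(mean=100.0),
    off_law=ExponentialLaw(mean=300.0),
    total_time=2500.0,
    delta_t=5.0,
    seed=5,
    N=538,
)
traj, _ = generate_contact_trajectory(spec)

rs = range_stats(traj)
print(f"mean contact range <d> = {rs.mean_range:.1f} residues, "
      f"sigma_d = {rs.std_range:.1f}")
print(f"long-range threshold lambda = <d> + sigma_d = {rs.lam:.1f} residues")

dens = long_range_density(traj, rs.lam, [AR_NTD_REGIONS["NR"], AR_NTD_REGIONS["CR"]])
for name, value in dens.items():
    unit = "contacts/residue" if name != "inter-region" else "contacts"
    print(f"  {name:>12}: {value:.4f} {unit}")
print("\nContacts with sequence separation above lambda count as long-range;")
print("their per-region density reveals which chain segment folds back on itself.")
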