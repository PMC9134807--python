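"""Classify contact pairs as series / parallel / cross and map them onto the simplex.

Builds a small contact map by hand, prints every pairwise relation, the
S/P/X census, and the planar coordinates of the composition on the ternary
(2-simplex) topology space.
"""

import itertools

from circuitop import ContactMap, classify_relation, topology_fractions
from circuitop.viz import to_ternary

contacts = [(2, 30), (5, 20), (10, 40), (50, 60)]
cmap = ContactMap(N=70, contacts=frozenset(contacts))

print("pairwise relations:")
for c1, c2 in itertools.combinations(sorted(contacts), 2):
    print(f"  {c1} vs {c2}: {classify_relation(c1, c2)}")

f = topology_fractions(cmap)
print(f"\ncensus over {f.n_pairs} contact pairs: "
      f"n_S={f.n_S}, n_P={f.n_P}, n_X={f.n_X}")
print(f"fractions: f_S={f.f_S:.3f}, f_P={f.f_P:.3f}, f_X={f.f_X:.3f}")

p = to_ternary(f)
print(f"ternary coordinates: ({p.x:.3f}, {p.y:.3f})")
print("\nThe fractions locate this conformation inside the S/P/X triangle;")
print("pure series sits at the origin, pure parallel at (1,0), pure cross at the apex.")
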