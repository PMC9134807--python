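# circuitop

Circuit topology analysis of intra-chain contacts in protein conformational
ensembles — built for intrinsically disordered chains, where no single native
structure exists and the informative object is the *arrangement* of transient
residue–residue contacts and its evolution in time.

## The idea

A chain conformation is reduced to its set of intra-chain contacts, each
occupying a sequence interval [i, j]. Any two contacts stand in exactly one of
three relations:

* **series (S)** — disjoint intervals,
* **parallel (P)** — one interval nested in the other,
* **cross (X)** — partial overlap (entanglement).

The census (n_S, n_P, n_X) over all m(m−1)/2 contact pairs, normalised to
fractions (f_S, f_P, f_X), is the simplest topological fingerprint of a
conformation and traces a trajectory on the 2-simplex when followed over an
ensemble. The dynamic layer condenses a contact-map time series into a
**kymograph** (pairs × frames presence matrix), extracts per-contact lifetimes
τ from presence runs, fits the scale-free lifetime law

    P(τ) = A · τ^(−γ)

by log-binned log–log regression (maximum-likelihood variant included),
partitions contacts into short/middle/long lifetime **regimes** (defaults
split at 0.5 μs and 2 μs), filters topology trajectories by regime, and
computes the per-residue **C-factor** (mean maximum contact lifetime).
Contact-range statistics provide a data-driven long-range threshold
λ = ⟨d⟩ + σ_d over the per-residue mean sequence separations, with per-region
long-range contact densities (a named preset ships for the 538-residue
androgen-receptor N-terminal domain: NR 1–224, CR 225–538, CR core 355–469).

Contacts are detected from atomistic coordinates with the standard rules:
two residues are in contact when more than five atom pairs lie strictly below
a 4.5 Å cutoff, excluding the three nearest sequence neighbours (all three
thresholds configurable).

## Worked example

`examples/02_contact_maps_from_structure.py` engineers three contacts into a
45-residue bead chain, round-trips it through a PDB file and recovers them:

```
engineered contacts: [(1, 20), (5, 15), (30, 40)]
detected contacts:   [(1, 20), (5, 15), (30, 40)]
S/P/X fractions: 0.67 / 0.33 / 0.00
```

(1,20) and (5,15) are nested — a parallel pair — and each is in series with
(30,40), giving f_S = 2/3, f_P = 1/3. `examples/03_lifetime_kymograph.py`
runs the dynamic layer on a seeded telegraph trajectory (200 pairs, 1000
frames, 5 ns apart, scale-free on-dwells with γ = 1.5):

```
kymograph: 128 pairs ever in contact x 1000 frames
lifetime law fit: gamma = 1.392 (truth 1.5), R^2 = 0.947
 short regime: 116 pairs, ...
middle regime:  12 pairs, ...
C-factor over 174 contact-forming residues: 5-1795 ns (mean 160 ns)
```

The fitted exponent recovers the generator's lifetime law; the regime masks
show short-lived contacts dominating, as expected for a disordered chain.
The other examples cover relation classification with ternary coordinates
(`01`) and long-range contact densities by chain region (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
circuitop simulate spec.json -o fixture/
circuitop contacts structure.pdb -o maps/
circuitop topology maps/contact_maps.tsv -o topo/
circuitop dynamics maps/contact_maps.tsv -o dyn/
circuitop report maps/contact_maps.tsv -o rep/ --region NR --region CR
```

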