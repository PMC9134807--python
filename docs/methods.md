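# Methods

## Contact detection

A residue pair (i, j) is a contact in a frame when strictly more than
`min_close_pairs` inter-residue atom pairs lie strictly below `cutoff`, and
j − i > `neighbor_exclusion`. Defaults: 4.5 Å, 5 (i.e. at least 6 close
pairs), 3. Two readings of the close-atom rule exist — distinct atoms versus
atom pairs — and the pair reading is implemented because pairs are what a
distance computation enumerates; the threshold is configurable, so the other
reading is a parameter change away. All atoms present in the input are used
(no heavy-atom filtering); ties exactly at the cutoff do not count. Candidate
pairs come from a k-d tree over all atoms with an explicit strict-`<`
re-check, so results are identical to the brute-force double loop the tests
compare against.

Structure input (multi-model PDB, or XTC/TRR/DCD against a PDB/GRO topology)
is read through MDAnalysis. Only protein residues of one chain are kept;
residues are renumbered contiguously 1..N in chain order (the author
numbering is retained for reporting), the first alternate location wins, and
non-contiguous numbering triggers a warning rather than an error because
disordered-protein constructs frequently carry gapped numbering.

## Relation classification

With contacts as closed intervals [i₁, j₁], [i₂, j₂]:

* S when j₁ ≤ i₂ or j₂ ≤ i₁ (disjoint; tangency at a shared residue counts
  as series),
* P when one interval contains the other under non-strict comparisons
  (shared-endpoint nesting counts as parallel),
* X otherwise.

Contacts sharing a residue have no universally agreed class in the
three-letter scheme; the non-strict folding above keeps the census total at
exactly m(m−1)/2 and is exercised directly by unit tests. The census is
vectorised over all interval pairs; fractions are undefined (reported as
`None`) for maps with fewer than two contacts rather than silently zero.

## Range statistics

The contact range is the sequence separation d = j − i. By default ⟨d⟩ and
σ_d are computed over the *per-residue mean* ranges pooled across frames
(each contact-forming residue contributes the mean separation of its
contacts), because the range distribution is naturally reported per residue;
a pooled per-contact variant is available via `per_contact=True`. σ_d is the
population standard deviation (`ddof=0`) — λ = ⟨d⟩ + σ_d is a descriptive
threshold on an observed distribution, not an inferential estimate; `ddof`
is an argument for those who prefer the sample convention. Long-range
density divides the count of distinct contacts with both endpoints in a
region and d ≥ λ by the region length; long-range contacts spanning regions
are tallied separately as a count under `inter-region` since no single
region length applies to them.

The AR-NTD region preset records NR = 1–224, CR = 225–538,
CR core = 355–469 and CR shell = 255–354 ∪ 470–538. The shell start (255)
leaves residues 225–254 outside both core and shell relative to the CR
start; both published boundaries are kept verbatim rather than guessing
which is a typo, and the unassigned band is documented here.

## Lifetimes and regimes

Kymograph rows are exactly the pairs present in at least one frame, sorted;
a trajectory with no contacts yields a 0-row kymograph. Lifetimes are
maximal presence runs times the frame spacing Δt (default 5 ns, 1000 frames
— pure configuration defaults). A single absent frame splits a run
(`gap_tolerance=0`); a positive tolerance merges runs across short gaps
without counting the gap frames, for data where detection flicker is
expected.

Regime membership uses the pair's **maximum** lifetime, matching the
maximum-lifetime selection used for the lifetime distribution; whether the
filter should instead act per run is genuinely open, so run-level filtering
is available by building masks from `LifetimeTable.runs` directly. Regime
intervals are half-open [lo, hi) — strict inequalities on both sides would
orphan lifetimes exactly at the 0.5 and 2 μs boundaries. All times are
nanoseconds internally; the default regime bounds are 500 and 2000 ns.

Filtering a trajectory by a pair mask intersects each frame's contact set
with the mask — exactly the elementwise product of the binary contact matrix
with a 0/1 filter matrix — then re-runs the census per frame. The C-factor
averages the maximum lifetime over the contacts each residue participates
in; residues with no contacts carry NaN, never 0, since "no information" and
"instantaneous contacts" must not be conflated.

## Power-law fitting

`fit_power_law` histograms lifetimes into logarithmically spaced bins,
normalises counts by bin width and sample size, drops empty bins, and fits
log₁₀(density) against log₁₀(geometric bin centre) by least squares; γ is
the negated slope, A the de-logged intercept, and R² the regression quality.
Logarithmic binning is the standard estimator for graphical power-law fits
and recovers γ = 1.5 within ±0.01 at n = 10⁴ on the truncated law used in
the tests; `fit_power_law_mle` provides the maximum-likelihood exponent for
the truncated law (normalisation solved by bounded scalar minimisation) as a
binning-free cross-check. Exact power-law bin densities are recovered
exactly (R² = 1). Fewer than two distinct lifetimes in the window is a fit
error, not a degenerate answer.

## Synthetic data

`generate_bead_chain` builds a planar self-avoiding persistent walk of
residue centres (bond 3.8 Å; centre separations kept above 4 Å for 2–3
sequence neighbours and above 7 Å beyond that), each residue carrying a
deterministic 0.3 Å-radius atom cloud (8 atoms by default). Engineered
contact pairs are realised by lifting the larger-index residue 3.5 Å out of
the plane above its anchor, alternating sides with a clash check; the
geometry guarantees every atom pair of an engineered contact is below
4.5 Å while no other non-neighbour residue pair can contribute a single
close atom pair. The generator verifies recovery with the real detector
before returning and raises a generation error for infeasible sets (a
residue moved twice, more than two partners per anchor, or no clash-free
side). The walk is a geometric scaffold for detector tests, not a polymer
model: lifted residues break bond geometry, and the planar layout carries
none of the excluded-volume statistics of real chains — passing tests
validate the detection and topology machinery, not any conformational
ensemble physics.

`generate_contact_trajectory` runs an independent two-state telegraph
process per pair: dwell times alternate between an off-law and an on-law
(constant, exponential, or truncated power law sampled by inverse
transform), starting in the off state with a first off-dwell drawn from the
off-law so pair histories are unsynchronised. Continuous on-intervals are
discretised by rounding both endpoints to the nearest frame boundary;
ground truth records the continuous intervals, the discretised runs actually
realised (merges flagged when rounding fuses two intervals), so tests can
assert exact agreement with the discrete truth and ≤ Δt agreement with the
continuous truth for unmerged pairs. Truncation bounds of the power law are
explicit spec parameters (defaults in tests: 5–2000 ns) because an empirical
lifetime range motivates but does not define them. For exponent-recovery
demonstrations the off-dwell mean is set equal to the observation window
(5 μs), so each pair contributes roughly one on-interval and the per-pair
*maximum* is essentially a single draw from the on-law; with dense on-events
the maximum statistic is upper-biased and the fitted γ would systematically
undershoot — that bias is a property of maximum-lifetime selection, not of
the fitter.

`canonical_topology_map` emits the three pure motifs: k disjoint contacts
(all S), k concentric contacts (all P), and the rotated family (t, t+k)
(all X; requires k > the neighbour exclusion).

## Problem sizes

Tests and the acceptance script use chains of 10–538 residues, contact maps
of up to 60 contacts, 10⁴-sample power-law fits, and telegraph trajectories
of 200–400 pairs × 1000 frames at Δt = 5 ns — the full suite runs in a few
seconds, and these sizes already expose every failure mode the larger
MD-scale inputs would (the algorithms are exact, not statistical, except for
the power-law fit whose error scales as 1/√n).

## Known limitations

* The ternary embedding and plots are matplotlib-only; no interactive
  output.
* `read_trajectory` trusts the reader's frame-spacing metadata (converted
  ps → ns) and assumes a uniform stride.
* The bead-chain generator supports engineered sets only up to its placement
  scheme's feasibility limits (documented above); arbitrarily dense contact
  graphs require a real embedding optimiser, which is out of scope.
* Energy-based contact definitions and higher-order circuit decomposition
  are not implemented.
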