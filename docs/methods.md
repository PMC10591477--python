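# Methods

## Scope and data model

`tndyn` analyses existing trajectories; it performs no simulation, model
building, force-field handling or energy evaluation (MMPBSA-style ΔG tables
enter only as external per-snapshot values or (mean, std, n) summaries for
ΔΔG arithmetic). A topology is an ordered atom table with subunit labels
(chain IDs mapped through a configurable chain→subunit map, default
A→TnC, B→TnI, C→TnT), 1-based author residue numbering and inclusive
residue ranges. Trajectories are multi-model PDB (the canonical,
human-readable dialect) or DCD files, concatenated with `run_id` equal to
the file ordinal; frames are held as a single (n_frames, n_atoms, 3) float64
array in Å. Selections are strings `subunit:lo-hi:filter` with filter one of
`CA`, `heavy` (non-hydrogen by element, name-inferred when the element
column is absent) or `all`.

## Geometric observables

All angle/distance metrics are internal, computed without superposition, and
therefore exactly invariant under global rigid-body motion (asserted to
1e-9° in tests).

**Hinge angle.** The angle at the fulcrum centroid between the vectors to
the head and IT-arm-end centroids. Default anchors: head = Cα centroid of
TnC 3–85, fulcrum = Cα centroid of TnC 94–157, arm end = the *pooled*
Cα centroid of TnT 241–251 ∪ TnI 69–76 (a single joint average of the
union, not a mean of two sub-centroids; the difference is small but the
convention is fixed). Coincident centroids are an error and the frame is
flagged; a series with more than 10% failed frames aborts.

**A/B interhelical angle.** Each helix axis runs from the centroid of the
first `endpoint_window` Cα to the centroid of the last `endpoint_window`
Cα (N→C orientation); the reported angle is 180° minus the angle between
the two axes. The default window of 10 residues exceeds half the length of
helix A (12 residues) and equals the length of helix B (10 residues), so
windows are clamped to min(window, length−1) with a warning; only exactly
coincident window centroids are an error. This clamping rule is this
package's choice for a case the endpoint-average convention leaves
undefined. Note that for short helices the endpoint-window axis estimate
deviates deterministically from the geometric helix axis (the windowed
radial terms do not cancel); the convention, not an idealised axis, is the
definition.

**Distances** are Euclidean distances between two selection centroids
(default NcTnC = TnC 3–85 vs CcTnC = TnC 94–157).

## Fluctuation analysis

Superposition is least-squares rigid-body fitting (Kabsch, SVD with
determinant correction); it is cross-checked in the test suite against an
independent quaternion-method oracle and MDAnalysis. RMSF uses an iterated
mean-structure reference — align to the current mean, re-average, two
passes — and reports per-residue Cα values; the reference convention is the
package's choice since only "RMSF per residue" is fixed by common usage.
The pairwise RMSD matrix is computed over all heavy atoms after optimal
per-pair superposition; a guard refuses more than 20,000 strided frames
(the matrix is quadratic) unless forced. The representative structure is
the medoid — the frame minimising the row sum of the matrix — with ties
broken to the lowest (run_id, frame_index). In the orchestrated pipeline
the matrix is computed on a stride chosen so at most 200 frames enter
(logged in the bundle); the medoid definition is unchanged, only its
sampling resolution.

## Interaction profiling

A clean-room geometric profiler, not a port of any existing contact tool.
Typing covers the 20 standard amino acids plus phosphoserine (SEP), taken
as the doubly deprotonated, net −2 species present at physiological pH.
Criteria (all configurable, defaults logged into every output):

| type | criterion (defaults) |
|---|---|
| hydrogen bond | donor-heavy–acceptor ≤ 3.5 Å, and D–H···A ≥ 120° when explicit hydrogens exist (distance-only "no-H" mode otherwise) |
| ionic | any (+) group atom within 4.0 Å of any (−) group atom |
| aromatic | ring-centroid distance ≤ 5.0 Å |
| van der Waals | heavy-atom distance ≤ r₁+r₂+0.5 Å (Bondi radii), only for pairs without an H-bond/ionic event that frame |

Charge groups: Arg (NE, NH1, NH2)⁺, Lys (NZ)⁺, His⁺ only as HIP,
Asp (OD1, OD2)⁻, Glu (OE1, OE2)⁻, SEP (O1P, O2P, O3P)⁻, chain-terminal
N⁺ and (OXT, O)⁻. Rings: Phe/Tyr six-ring, His five-ring, Trp both rings.
Presence is boolean per residue pair per type per frame (multiple atom
pairs count once); intra-residue pairs and backbone–backbone pairs of
sequence neighbours are excluded from the polar types to avoid trivially
constant signals. Occupancy percentages are 100·count/n_frames; state
comparisons are percentage-point differences with absent pairs at 0%.
Because published troponin contact percentages depend on the (unpublished)
geometric criteria of the original profiler, only scale/sign behaviour on
planted contacts — not numeric agreement with published percentages — is a
meaningful validation target, and that is what the tests assert.

## Distribution statistics

KDE uses a Gaussian kernel with Scott's bandwidth (the default of common
plotting stacks), evaluated on a 1,024-point uniform grid padded 3
bandwidths beyond the data range; the mode is the grid argmax and the FWHM
spans the outermost half-peak crossings located by linear interpolation.
The outermost-crossing rule is deliberate: hinge/helix-angle series can be
bimodal, where a narrow per-mode width would misrepresent the accessible
range; per-mode widths are available separately (`per_mode_widths`).
For Gaussian data the estimator converges to 2√(2 ln 2)·√(σ²+h²), which the
tests check to 5%. Sample std uses the n−1 denominator; Cohen's *d* uses
the classical pooled-std form; percent changes are rounded half-away-from-
zero to integer percent in formatted reports (raw values are preserved).
A constant series is flagged degenerate (std 0, FWHM undefined) rather
than silently reported as zero-width. Statistics are computed on samples
pooled over all runs of a system.

## Synthetic generator

The generator emulates the *statistical* structure of multi-replica
troponin-core simulations, not their physics: no force field, no solvent,
no realistic backbone connectivity. A rigid head (toy NcTnC, residues
TnC 1–93, containing ideal α-helices A and B with 1.5 Å rise, 100°/residue
twist, 2.3 Å radius, plus a TnI 1–30 flexible-tail stand-in) articulates
against a rigid arm (TnC 94–161, TnI 31–80, TnT 230–260 on compact
serpentine Cα lattices). Per frame the hinge angle is drawn from the
specified Gaussian or mixture and realised *exactly* by rotating the head
about an axis through the fulcrum centroid; the NcTnC–CcTnC distance is
the fixed domain separation by construction. Because the planted angles are
realised geometrically, recovery tests are tolerance-tight (1e-6°) rather
than statistical. The helix-B tilt is calibrated numerically at build time
so that the *measured* endpoint-window crossing angle equals the requested
value (compensating the short-helix axis bias described above); the ground
truth records the realised value. Gaussian jitter of stated σ applies
i.i.d. to the flexible-tail atoms only, so jitter convergence (RMSF → σ√3)
is testable without perturbing the planted geometry. Planted contacts place
designated side-chain pseudo-atoms (Arg/Glu, Ser/Gln, Phe rings, SEP/Lys…)
within the type's cutoff in a Bernoulli(f) subset of frames and beyond
1.5× cutoff + 1 Å otherwise; every draw is recorded, so measured
occupancies equal the recorded realisation exactly and sit inside the
exact binomial interval of f.

Defaults mirror the wild-type unphosphorylated study conditions: five
independent runs, hinge ~ N(121.6°, 7.2°), A/B crossing 101.8°, domain
separation 30 Å, tail jitter 0.5 Å, and four planted contacts at 80/60/25/
80% occupancy (the last a phosphoserine–lysine ionic pair mirroring the
strong phosphorylation-induced contacts). The published analyses pool
37,500 frames per system over five runs; the per-run frame count is not
stated there, and desk-scale validation does not need it — the generator
defaults to 1,000 frames per run, which the statistical tolerances above
are sized for.

What passing on synthetic data does *not* show: correctness on real MD
output with solvent, ions, alternate conformations or chain breaks; the
profiler's agreement with any specific published contact percentages; or
robustness of the hinge metric when domains are themselves flexible (the
toy domains are rigid apart from the tail).

## Numerical choices and degeneracies

* Angles are clipped into arccos's domain before evaluation; zero-length
  vectors (coincident centroids, degenerate helix axes) raise rather than
  returning NaN silently.
* Kabsch RMSD uses the E₀ − 2Σσ identity, accurate to ~1e-6 Å for
  identical structures (catastrophic cancellation below that).
* Medoid ties (row sums within 1e-9) break deterministically to the lowest
  (run_id, frame_index).
* Pipeline outputs round angles/distances to 2 dp and percent changes to
  integer percent; comparison tables embed the analysis-settings hash, and
  two bundles can only be compared when their hashes match.
* The comparison table reports FWHM *percent change* for angle metrics and
  *absolute* FWHM difference for distances, matching how such tables are
  conventionally reported for these quantities.

## Known limitations

* PDB parsing is delegated to MDAnalysis; exotic PDB features (insertion
  codes, altlocs, multi-character chain IDs) are untested.
* The profiler implements four interaction classes only; weak H-bonds,
  CH–π, halogen and water-mediated contacts are out of scope.
* His protonation is name-driven (HIP/HID/HIE); plain HIS is treated as
  neutral donor/acceptor, never charged.
* RMSF reports Cα only; side-chain fluctuation is not aggregated.
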