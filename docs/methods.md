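# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices a user should know about.

## Coordinate model and conventions

All analyses consume a `TrajectoryFrames`: a tidy table of labelled atom
coordinates (Å) with a constant atom roster across frames and a saving
interval `dt` (ps, default 200). Saved frame *i* is timestamped at
`t = (i + 1)·dt`, i.e. at the end of its saving interval, so a 200-ns run
saved every 200 ps has exactly 1,000 frames and its (100, 200] ns window is
the last 500 of them. Residue numbering is 1-based per chain (Gln at 10 or
17, Ser at 6/13/20); chains are labelled A–E. Waters are identified by
residue name (`HOH`, `SOL`, `TIP3`, `WAT`, configurable) and located by their
oxygen atom.

`orient_pore_axis` aligns each frame's pore with +z: the largest-variance
eigenvector of the selected Cα covariance is rotated onto +z by the minimal
arc, the selection centroid is moved to the origin, and the axis sign is
fixed so +z points from the residue-22 Cα centroid toward residue 5
(N-terminal side up; configurable). The operation is rigid (pairwise
distances preserved to 1e-8 Å) and idempotent. Exactly collinear selections
are accepted — the principal axis is still well defined — and only
zero-extent selections are rejected.

## Sidechain orientation and symmetry

For each pore-lining Gln we compute v⃗ = r(Nε2) − r(Cα) per frame and chain,
and the z-offset of Nε2 relative to the Gln Cα plane. The "plane" is taken as
z = mean z of the five Gln Cα atoms of that frame: in a near-symmetric bundle
the five Cα are nearly coplanar and normal to the pore axis, so a
least-squares plane fit would change nothing at the precision that matters
here. Nε2 (PDB atom `NE2`) is the sidechain amide nitrogen; Gln has no `NE`
atom.

States: down (z < 0), neutral (0 ≤ z < t_high), up (z ≥ t_high), with
t_high = 2.5 Å by default and 2.4 Å exposed as a configurable alternative
(both appear in the literature for this classification; the choice moves a
measure-zero boundary). Intervals are half-open so every z maps to exactly
one state.

Pairwise state agreement between chains i and j is the fraction of frames
with state_i = state_j; frames from supplied replicates are concatenated
before averaging. The matrix is symmetric with unit diagonal, and for
independent identically distributed chains with marginal state probabilities
p the off-diagonal entries converge to Σ_s p_s² (≈ 1/3 for uniform p), which
the tests verify at 30,000 pooled frames.

## Rotamer analysis

χ1 (N–Cα–Cβ–Cγ) and χ2 (Cα–Cβ–Cγ–Cδ) are signed torsions in (−180°, 180°]
(IUPAC convention, cis = 0, trans = 180), computed with the standard
cross-product/atan2 form in float64. The test suite checks 1,000 random
geometries against an independently coded projection oracle (≤ 1e-9°) and
against MDAnalysis (≤ 1e-3°, its float32 precision).

Clustering uses DBSCAN on the 4-D embedding (sin χ1, cos χ1, sin χ2, cos χ2)
so the ±180° seam is respected; `eps` is stated as an arc in degrees and
converted to the chord 2·sin(eps/2) that the same displacement produces in
the embedding. Defaults: eps = 20°, min_samples = max(10, 0.5% of points) —
wide enough to absorb thermal jitter, far smaller than the ≥ 60° separations
between rotamer wells. Cluster fractions are reported both over all points
and excluding noise (the two conventions differ when noise is appreciable);
clusters are ranked by descending membership.

The background density for χ1/χ2 plots is a 2-D Gaussian KDE (Scott's rule by
default) over a reference dihedral table, made periodic by replicating
reference points shifted ±360° within a 90° margin of the domain edge. The
contour levels are density quantiles at the reference points, so the
super-level set at `thresholds[p]` encloses ≈ p% of the reference probability
mass; the 90% region contains the 70% region (d70 ≥ d90). A Monte-Carlo
check with a fresh 10,000-point sample recovers the enclosed masses to ±0.03.

## Hydration

The pore volume is approximated per frame by the convex hull of the Cα atoms
of residues 5 and 22 on all five chains (a pentagonal prism for an ideal
bundle; the hull degrades gracefully for tilted helices and needs no other
parameters). Membership is closed (boundary points count as inside).

Residence intervals are maximal runs of consecutive inside-frames per water;
durations are run length × dt. Intervals touching the first or last frame
are flagged as censored rather than dropped.

The density profile is the per-frame histogram of inside-water z positions,
averaged over frames and normalised to waters per Å (so ∫ρ dz equals the
mean per-frame pore count, which the tests verify to ±1 count for edge bins).
Before differentiation the profile is Savitzky–Golay smoothed (window 11
bins, order 3, configurable) — second derivatives of raw histograms are
noise-dominated. The second derivative is taken by central differences;
zero crossings (linearly interpolated between bins, with curvature below
1e-3 of the maximum — or below an absolute floor tied to the density scale —
treated as zero) mark changes of hydrophobicity. A span between consecutive
crossings counts as hydrophobic when its interior mean smoothed density is
below 25% of the profile maximum (configurable); without such a cutoff,
incidental inflections inside fully hydrated stretches would generate
spurious spans. The effective hydrophobic length is the longest qualifying
span. On analytic sum-of-logistics profiles the recovered inflection
positions and span lengths are exact to within one bin width, provided the
logistic scale is comparable to the smoothing window (a sharper step rings
under the filter; the fixtures respect this).

Wet/dry classification uses hysteresis: a frame becomes wet at the first
pore count n ≥ 10 and stays wet until n ≤ 1, at which it becomes dry;
intermediate counts (2–9) inherit the current state, and intermediate counts
before any threshold crossing are labelled `transition` and excluded from
wet/dry pooled statistics.

## Hydrogen-bond networks

Geometric criteria (not derivable from the network software the analysis
mirrors, so stated here explicitly): donor–acceptor heavy-atom distance
≤ 3.5 Å and, when the donor carries hydrogens (an H atom of the same residue
within 1.2 Å), D–H···A ≥ 150°. Hydrogen-free inputs fall back to
distance-only detection, flagged per bond. Chemistry: Gln NE2 donates, OE1
accepts; Ser OG does both; backbone carbonyl O accepts; water O does both.
Intra-residue pairs are excluded.

Two residues interact in a frame when a breadth-first search through water
nodes only connects them within ≤ 5 interior waters; the recorded bridge
length is the minimum interior count among qualifying paths (0 = direct).
Note this is a minimum: a scripted 2-water chain whose geometry happens to
admit a 1-water shortcut is reported with bridge length 1. The search is
verified against brute-force simple-path enumeration on random graphs of 12
nodes, and is monotone in `max_waters` (raising the cutoff never removes an
interaction), as bond detection is monotone in `d_max`.

Aggregation over an analysis window (default: the second half of the
trajectory) yields an undirected graph with per-edge occupancy
(frames-with-interaction / window frames) and the mean bridging-water count
over frames where the edge exists. Edges below 10% occupancy and nodes
outside the core residue range 6–20 are dropped. Interaction-type fractions
classify every bond whose endpoints are pore-facing sidechain atoms (Gln
NE2/OE1, Ser OG within the core) or water, with at least one sidechain
endpoint; bonds touching backbone or out-of-core atoms are not part of the
denominator, and water–water bonds are not counted as pore interactions.

## Proton-flux assay

Calibration: pH = −log₁₀(A·B^R − 1) with A = 8.959×10⁻⁸ and B = 1.185; the
fit estimates (log A, B) by least squares in ratio space (the measured
quantity), initialised at the published constants, and requires ≥ 4 points
spanning ≥ 2 pH units. The inverse is R = ln((10^(−pH) + 1)/A)/ln B.

A property of these constants worth knowing: they compress the whole pH 3–9
range into a ratio band only ~6×10⁻³ wide around R ≈ 95.6 (6×10⁻⁵ in
relative terms). Two consequences are documented and tested rather than
hidden. First, one float64 ulp of the ratio corresponds to ~1e-6 pH units at
pH 9, so the pH→ratio→pH composition is identity to 1e-9 only below
pH ≈ 6.5; above that it is identity to within a few ulps of the ratio
quantization (the ratio→pH→ratio composition is machine-precision everywhere).
Second, ratio noise must be far below 6×10⁻⁵ relative for the traces to stay
within the calibration domain at all; the synthetic generator's default
multiplicative ratio noise (2×10⁻¹¹) is chosen to correspond to ≈ 0.005 pH
units of read noise.

Buffering: with h = 10^(−pH), the total proton concentration is
[H]ₜ = h + [P]·h/(Kₐ + h) — free protons plus protons on monobasic phosphate
with a single effective Kₐ = 6.31×10⁻⁸ M and [P] = 0.03 M. At h = Kₐ the
bound term is [P]/2 = 0.015 M; at [P] = 0 the expression reduces to h. The
implementation is checked against an independently coded
Henderson–Hasselbalch speciation to 1e-12 relative. The diprotic character
of phosphate is deliberately neglected (single effective pKa over pH 3–9),
and the buffer correction is applied point-wise before rate fitting.

ΔpH traces subtract the mean pH over all pre-valinomycin points. Initial
rates are ordinary least-squares slopes of [H]ₜ over (t_val, t_val + 60 s]
(closed on the right; 10-s sampling puts 6 points in the window). For a
variant measured as 8 biological × 3 technical replicates, the run-level rate
estimator pools the window points of all technical wells into a single OLS
fit; with ~142 residual degrees of freedom its 2-SE interval has essentially
nominal Gaussian coverage, which the acceptance suite verifies over 100
seeded synthetic runs (per-trace fits, with 4 residual df, would cover only
~88%). Per-biological-replicate rates (technical triplicates pooled per
replicate) feed the group comparison.

Group comparison is a one-way fixed-effects ANOVA computed from the standard
sums of squares (identical observations short-circuit to F = 0) followed by
Tukey's HSD using the studentized-range distribution
(q = |Δmean|/√(MS_within/2·(1/n₁ + 1/n₂))). Both are cross-checked in the
tests against scipy's F test and statsmodels' Tukey implementation, and the
two-group case reduces to the pooled-variance t-test exactly.

## Synthetic data generators

`generate_trajectory` builds an ideal C5 pentamer: 5 chains × 25 residues on
a circle of radius 8 Å with a 1.5 Å/residue rise, N-terminal side up. The
pore-lining Gln's sidechain is placed so that Nε2 realises the scripted
state's target z-offset exactly (defaults down → −1.0 Å, neutral → 1.2 Å,
up → 3.3 Å, near the cluster means reported for channels of this family);
the realised χ1/χ2 of each placement are recorded as ground truth. State
sequences are either scripted per chain or generated by a per-chain Markov
chain (default stay probability 0.98/frame, mimicking slow rotamer
switching). Scripted z targets must sit ≥ 0.5 Å from the classification
thresholds so the ground-truth labels are unambiguous; positional noise is
seeded Gaussian jitter on all atoms. Waters follow an explicit entry/exit
schedule: inside the pore they sit within 1 Å of the axis (membership
unambiguous by construction), outside they are parked ≥ 25 Å from the
bundle; the atom roster is constant across frames. Optional bridge scripts
place chains of waters between one chain's NE2 and another's OE1 with ≤ 3.4 Å
spacing, giving exact scripted edge occupancies.

What the generator does **not** emulate: physical sidechain bond geometry
(the Gln sidechain is a kinked path with the correct endpoints, not a
rotamer-library conformer), water dynamics or energetics, membrane and lipid
environment, and thermal coupling between chains. Passing tests therefore
demonstrate that the *analysis* operations are correct and exactly invert the
generative script — not that any particular channel behaves this way.

`generate_flux_traces` forward-maps pH(t) = pH₀ − a·(1 − e^(−(t−t_val)/τ))
(defaults pH₀ = 7.5, a = 0.4, τ = 180 s, valinomycin at 120 s, 10-s sampling
to 720 s — the assay's plate-reader schedule) through the calibration inverse
to F460/F417 channel pairs with seeded multiplicative noise; the ground-truth
rate is the OLS slope of the exact [H]ₜ curve over the sampled window points.
`generate_density_fixture` produces alternating-logistic density profiles
whose curvature sign changes sit exactly at the requested positions, plus an
inverse-CDF water-placement sampler. All generators are deterministic given
spec + seed.

## Problem sizes

The test and acceptance runs use the study's stated design where it is cheap
(three 1,000-frame replicates for frame bookkeeping, 15,000 pooled histogram
points, 500-frame network windows, 8×3 wells × 73 time points × 100 seeded
runs for rate-recovery coverage) and smaller trajectories (10–500 frames)
for per-operation checks, which the operations' exactness at zero noise makes
equally informative.

## Known limitations

- The pH→ratio→pH identity degrades above pH ≈ 6.5 for the float64 reasons
  described above; this is a property of the published calibration constants,
  not of the fitting code.
- Water density is reported per unit length of the pore axis (waters/Å), not
  per unit volume; the two differ by the pore cross-section profile.
- The hydrophobic-span cutoff (25% of maximum density) and the smoothing
  window are heuristics; both are exposed as parameters and should be held
  fixed within a comparison.
- Periodic-boundary imaging is out of scope: inputs are assumed whole and
  centred, as produced by standard trajectory post-processing.
- DBSCAN cluster fractions depend on eps/min_samples; defaults separate wells
  ≥ 60° apart and are not tuned per dataset.
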