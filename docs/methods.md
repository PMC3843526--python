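# Methods

## Fingerprints

A compound is abstracted to its carbon atoms: each unordered carbon pair
(i, j) contributes one fingerprint element (δᵢ, δⱼ, dᵢⱼ) with the two ¹³C
chemical shifts (ppm) and the Euclidean inter-atomic distance (Å).
Heteroatoms enter only through their influence on the input shifts; the
method performs no shift prediction and no conformer generation — shifts
and 3D geometries are inputs.

Design choices that the definition leaves open:

- **Canonicalization.** Shift pairs are stored as (min, max) so each pair
  occupies a single point of the shift plane.  This makes binning
  deterministic.  The symmetric alternative — mirroring every pair across
  the δx = δy plane — is available via `build_fingerprint(..., mirror=True)`
  and doubles every off-diagonal element.
- **Multiplicity.** Symmetric molecules produce coincident elements (e.g.
  two para-related pairs at identical shifts and distance).  These are all
  retained, so bin occupancy counts them individually.

## Tessellation

The space is cut by regular grids anchored at (0 ppm, 0 ppm, 0 Å) with
square shift-plane bins.  The canonical scan uses widths 2–20 ppm (step 2)
× heights 0.5–2.5 Å (step 0.5): 50 grids.  Bins are half-open,
[edge, edge + width), so boundary values belong to the upper bin; the
anchor and the boundary convention are conventions of this implementation
(nothing in the method fixes them) chosen for reproducibility.  A bin is
identified by its integer index triple, never by a column serial, so bins
are comparable across training subsets and grids.  Occupancy matrices keep
only bins occupied by at least one compound, in lexicographic column
order; zero-variance columns inside a training split are retained (with
zero standardized contribution) to keep bin labels stable across cycles.

## PLS engine

SIMPLS for a univariate response: the cross-product vector s = Xᵀy is
deflated by projecting out an orthonormal basis of the loading space; each
component yields a unit-norm score, an x-loading, and an x-weight.
Coefficient paths are nested, so one fit at the maximum LV count serves
every smaller count (used by the hyperparameter scan).  Properties relied
on and tested: equality with least squares at full rank, and equality with
the NIPALS PLS1 implementation in scikit-learn for any LV count.

- Descriptors are standardized per training split with the sample SD
  (n − 1 denominator); the response is centered but not scaled.
- Requesting more LVs than the rank supports truncates with a warning.
- Prediction aligns query columns to training bin labels: unseen bins are
  dropped, missing training bins are imputed as zero occupancy.
- "PLS weights" for interpretation are the per-LV x-weight vectors
  (normalized to unit length), not loadings and not regression
  coefficients: the extraction protocol ("10 most positive and negative
  weights per LV") only makes sense for per-LV vectors.  A different
  choice would change which bins are ranked, which is why the weight
  matrix is stored on the model and exposed directly.

## KNN engine

Generalized Tanimoto similarity T = a·b/(‖a‖² + ‖b‖² − a·b) on the raw
(non-standardized) occupancy rows, so T is a bijective invariant of a
compound pair at fixed granularity — standardizing would make it depend on
the training split.  Prediction is the T-weighted mean of the k most
similar training activities.  Conventions: ties in similarity break by
training compound id (stable, platform-independent); if all selected
similarities are zero the prediction falls back to the unweighted neighbor
mean with a warning (the weighted form is undefined; this situation does
not arise in practice on occupied fingerprints).  Query bins unseen in
training stay in the vector space and lower T through ‖query‖².

## Validation

A `SplitPlan` draws `n_cycles` uniform train/test partitions (test size =
round(0.2·m); 19 of 94) from one seeded generator, which also emits one
scrambling sub-seed per cycle.  Both engines consume the same plan, so
their per-cycle R²_test values are matched pairs.  Per PLS cycle the
training activities are additionally permuted once (cycle sub-seed), the
model refit, and the true hold-out activities predicted: R²_scrambling.
The exact random-number protocol is a convention of this implementation;
only its properties (bit-exact reproducibility from the seed, identical
splits across engines) are contracts.

R² is reported in two modes: squared Pearson correlation (default, the
R² of the fit line in a predicted-vs-observed plot) and 1 − SSE/SST
(penalizes bias, can be negative).  Cycles with undefined R² (constant
prediction or constant hold-out) are recorded as NaN and excluded from
means with a logged count.  Composite summaries are means and SDs over
cycles and deliberately include good and bad splits alike.

The matched-pair diagnostic reports, for two composites on a shared plan,
the per-cycle ΔR² distribution, the count of cycles deviating ≥ 1 SD from
the mean Δ (split by which engine won), and the signed squared correlation
of the matched R² sequences — low correlation means the engines capture
partially orthogonal structure, which is what pairwise consensus exploits.

## Consensus and interpretation

Consensus is the per-compound arithmetic mean of two composites' averaged
hold-out predictions, kept at full precision; display rounding is decimal
half-up with a 9-decimal guard snap so binary-float noise cannot flip an
exact tie.  Compounds never held out by a member (possible only at very
low cycle counts) are excluded with a log message.  Improvement is
100·(R²_cons − mean(R²_members))/mean(R²_members), reported to 1 decimal.
Consensus of more than two members is deliberately out of the core
surface.

Interpretation: per retained cycle model and per LV, the `n_top` most
positive and most negative weight bins are extracted (2 × cycles × LVs ×
n_top entries); unique bins are ranked per sign by recurrence frequency
(denominator = total extractions of that sign), the top
ceil(0.2 × unique) kept (ties: frequency desc, then lexicographic bin),
and back-projected to every (compound, atom-pair) element occupying them.
Disjointness of the positive and negative selections is asserted on the
planted-signal dataset but not forced in general — an overlap would be a
finding, not an error.

## Synthetic data

The generator emulates the statistical shape of the modeled dataset, not
its chemistry: 94 compounds in 3 classes (the PCB/PHDD/PCDF structure), 12
–18 carbons each, rigid point-set "skeletons" in an 8 Å box with ≥ 1.3 Å
separation, aromatic-window shifts (110–160 ppm).  Class members are
jittered copies of a class template (0.05 Å coordinates, 1 ppm shifts), so
within-class Tanimoto similarity dominates between-class similarity — the
block pattern of congener-family similarity maps.  Activity is
baseline (6.0) + Σ effect·occupancy over the 5 most variable bins of the
10 ppm × 10 ppm × 0.5 Å grid (alternating ±0.6 effects) + N(0, 0.3²)
noise, i.e. a known sparse linear signal on the log(1/EC₅₀) scale.

What passing tests on this data do show: the pipeline recovers a planted
linear bin signal (noise-free mean R²_test ≥ 0.95 at 100 cycles),
Y-scrambling destroys it (≤ 0.15), the 100-cycle running mean of R²_test
sits within 0.02 of its 1000-cycle value, and the interpretive ranking
returns the planted bins with sign-disjoint selections.  What they do not
show: behavior under real shift-prediction error, conformational
uncertainty, or activity data aggregated from heterogeneous assays — the
original descriptors (predicted shifts, optimized geometries) are not
redistributable, so per-grid statistics of the real dataset are not
reproduced here, only the published prediction table itself (packaged as
`data/ahr_table2.csv`) and the arithmetic derived from it.

## Numerical choices

- Rank tolerance 1e-10 (relative) for SIMPLS deflation and zero-variance
  detection.
- Sample SD (ddof = 1) throughout, including cycle-statistic SDs.
- Seeds: a single master seed per plan; derived sub-seeds are drawn below
  2³¹.  Identical seeds ⇒ byte-identical outputs (tested).
- Problem sizes in the test suite are scaled to the study's own scale (94
  compounds, 100 cycles; 1000 cycles only for the convergence check),
  which keeps the full suite in seconds on one CPU.

## Known limitations

- No conformational search or NMR shift prediction; garbage geometries or
  shifts propagate silently into fingerprints.
- The acceptance surface covers pairwise consensus only.
- Synthetic skeletons are not valid molecules (no bonds, no valence);
  SDF round-trips treat them as disconnected carbon point sets.
- KNN composite models store no training-set state beyond the plan; they
  are re-evaluated, not serialized.
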