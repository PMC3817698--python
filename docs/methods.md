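# Methods

This note documents the models, algorithms, parameter choices and known
limitations of morphassign. Everything quantitative stated here is
computed by the test suite or the benchmark functions in
`morphassign.benchmarks`.

## Model density

Model density is a sum of isotropic atomic Gaussians. An atom with
element electron count *Z*, occupancy *q* and isotropic B factor *B*
contributes a Gaussian of integrated weight *qZ* and variance
σ² = (B + B_blur)/(8π²), truncated at 4.5 σ. The blur term `blur_b`
(default 50 Å²) sets the effective resolution of synthetic maps to roughly
3 Å; grid spacing defaults to 1.0 Å (≈ resolution/3). Map–model
correlations are Pearson correlations (mean-subtracted) over the grid
nodes of a sphere; regions with zero variance return CC = 0 rather than
NaN. Only orthogonal (90°, 90°, 90°) map cells are supported:
crystallographic symmetry is out of scope and synthetic testing does not
need it. Map origins are carried in the MRC2014 ORIGIN header words.

## Morphing

Each cycle measures, for every residue, the rigid translation of the model
density of the atoms within `sphere_radius` (6 Å) of its Cα that maximises
the local correlation with the map. The search is a lattice of step
`shift_search_step` (0.25 Å) inside the ball of radius `max_shift` (2 Å),
followed by one half-step polish around the optimum; ties break towards
the smallest shift norm, then lexicographically, making the result
deterministic and directly checkable against exhaustive per-candidate
evaluation. The neighbourhood density is rasterised once per residue on a
local 0.5 Å grid and sampled at translated positions by a fused
numba kernel. Atoms of other chains inside the sphere are included.

Raw shifts are smoothed with an unweighted boxcar over `smooth_window`
residues (10, rounded up to the odd 11 so the window is centred), truncated
at chain ends and never crossing a chain break (numbering gap or Cα–Cα
step above 4.5 Å, i.e. the trans-peptide 3.8 Å plus tolerance). Residues
without a Cα receive the average of the available shifts in their window.
Because smoothing is a convex combination, no applied shift ever exceeds
`max_shift`. All atoms of a residue are translated together, so
intra-residue geometry is exactly preserved; only the connecting peptides
distort.

Between cycles the geometry is restored by a restrained real-space
minimisation rather than crystallographic refinement (reciprocal-space
machinery is out of scope; the algorithmic role — fixing the connecting
residues — is the same). The energy is a sum of harmonic distance
restraints: all intra-residue distances at their input values (weight
100), the five inter-residue link distances (C–N 1.329 Å at weight 100;
Cα–N, C–Cα, O–N, Cα–Cα at their ideal-geometry values, weights 30/30/30/10)
and Cartesian tethers to the input coordinates (weight `w_tether`,
default 10). Links whose C–N distance already exceeds 3 Å are treated as
real chain gaps and left alone, so deletion gaps are not crushed shut.
L-BFGS-B minimisation with analytic gradients; displacements are capped at
1.5 Å. An already-ideal model is a fixed point, and w_tether → ∞ recovers
the identity.

Six cycles are the default. On noise-free synthetic maps the mean
per-residue CC is non-decreasing across cycles within a 0.02 tolerance
(regularisation can trade a little CC for geometry).

## Trimming

ρ_mean of a residue is the mean interpolated map value at its atom
centres; ρ_mean_all and SD_mean_all are the mean and population SD of
those values over all residues of the *untrimmed* model, computed once
(single-pass trimming keeps the operation deterministic; the criteria are
config-exposed because they are calibration constants, not laws). A
residue is removed when ρ_mean < k_mean·ρ_mean_all + k_sd·SD_mean_all
(defaults 0.5, 0.2) or when its local CC — a 2.5 Å sphere at the residue
centroid; the region is our choice, the criterion value 0.4 is the
method's — falls below `cc_min`. Whole residues only.

## Sequence assignment

**Segments** are maximal runs of consecutive residues (numbering gap or
Cα break splits; runs shorter than `min_segment_length` = 4 are dropped).
Each surviving residue keeps its `template_index`, the position in the
original template chain, which is what the order constraint compares.

**Side-chain placement probabilities.** The probe for residue *i* is a
2 Å sphere centred 2.4 Å from Cα along Cα→Cβ (an ideal Cβ is constructed
from the backbone when absent), sampled with a fixed 33-point quadrature.
Probe densities are z-scored within the segment and correlated with the
z-scored side-chain electron counts of the candidate target residues; the
per-offset sums, scaled by `prob_sharpness` (0.25), are softmaxed into a
probability per offset. This is a transparent monotone surrogate for a
full Bayesian residue-type likelihood model: it preserves the interface (a
probability of correctness per segment × offset) that the scoring function
consumes and is the designated swap-in point for a richer model. The
sharpness is chosen so that a clear 12-residue match concentrates most of
the mass on one offset while wrong registers remain within a few score
units — which is what lets the constraint terms overturn a marginal
density preference.

**Score terms** (all additive; the total equals the sum of the reported
breakdown exactly):

* density: ln *p* of each placed segment (p clamped to [10⁻¹², 1−10⁻⁹]);
  the 0.95-vs-0.05 difference is ln 19 ≈ 2.94 units;
* connection: a pair of sequence-adjacent segments with *g* residues
  between their assigned spans is **rejected** when the end-to-end
  distance exceeds (g+1) × `max_span_per_residue` (3.8 Å); feasible pairs
  get −d/limit ∈ [−1, 0], a small closeness reward that never dominates
  the principal terms;
* loop bonus: +`loop_bonus` (10) when a validated loop of exactly the
  assigned gap length connects the pair;
* template term: the BLOSUM62 Z-score of the assigned target window
  against the segment's template sequence, relative to the score
  distribution over *all* offsets of the segment in the target, floored at
  zero and weighted by `w_template` (1).

**Constraints.** Non-overlap (each target residue used at most
`ncs_copies` times), and optionally strict order: offsets must increase
with template order. Reverse-direction placements are never considered
(template connectivity fixes the direction). With NCS copies > 1 the
connection/loop terms are skipped (copies need not be conformationally
related).

**Search.** Candidate offsets per segment are the `top_k_offsets` (16) by
static score (density + template term). When the combination count
∏(k_i + 1) fits in `exhaustive_limit` (10⁵), a depth-first enumeration
over segments in template order with incremental order/overlap pruning
finds the exact optimum; otherwise a deterministic beam search
(width 50) grows assignments one segment at a time. States are ranked by
residue coverage first, then score, then a lexicographic key: the additive
terms are all ≤ 0 except bonuses, so a zero-penalty "unassigned" state
would otherwise trivially dominate — the procedure's intent is to *add*
segments until the constraints refuse, and the coverage-first ranking
encodes exactly that. A segment therefore stays unassigned only when
every candidate placement is rejected.

## Loop building

Loops are attempted only between segment ends within `d_close` (15 Å) or
between segments assigned with a gap of at most `g_close` (6) residues.
A candidate loop is a Cα trace between the two anchor Cαs with steps in
[3.6, 4.0] Å and second neighbours at least 5.0 Å apart (bend ≤ ~97°, the
backbone's own limit; this forbids degenerate paths that oscillate across
one strong density blob). Tracing is guided by the **difference map**
(map minus current-model density): a loop should explain density the
model does not, and guiding by the raw map would pull traces into the
already-built neighbours.

Two proposal mechanisms feed a common refinement: a deterministic beam
dynamic-programming search for the densest lattice path satisfying the
step and skip constraints (the primary proposal), and `n_trials` (32)
seeded random perturbations of the straight chord. Every proposal is
refined by alternating a density-weighted-centroid projection (radius 1 Å;
0.5 Å for the lattice optimum) with iterative step projection; the trace
with the highest mean difference-map density wins, and is accepted when
its mean *map* density reaches `f_loop` (0.5) × ρ_mean_all of the current
model — the acceptance threshold is our calibration of "matching the
density map". On the 4-residue deleted-loop fixture the rebuilt trace
lies within 0.7 Å mean Cα deviation of the truth.

Accepted loops consistent with the winning assignment are inserted as
backbone-only residues (N, Cα, C, O placed crudely about the trace) and
the merged, renumbered model feeds the next assignment iteration; on
noise-free synthetic cases the number of assigned residues is
non-decreasing across iterations. Three iterations by default.

## Synthetic cases

`make_truth` builds an all-ideal backbone (Engh–Huber-style internal
coordinates via natural-extension frames) in helix-bundle or helix–strand
layouts with a fixed four-residue connector chosen so nonlocal Cα–Cα
contacts stay above 5.5 Å; sequences are drawn from a standard globular
amino-acid composition. Side chains are reduced to Cβ plus one
pseudo-atom 2.4 Å from Cα along Cα→Cβ carrying the electron count of the
atoms beyond Cβ; its B factor is raised by 60 Å² so those electrons
spread over the ~1.3 Å the real atoms occupy — a point-like pseudo-atom
would make side-chain peaks several times stronger than backbone, which no
real map shows. The pseudo-atom sits exactly in the assignment probe
region, so the reduced representation exercises the scoring interface
deterministically.

`perturb_template` applies a sum of three long-wavelength sinusoidal
displacement fields scaled to an exact main-chain RMS amplitude (the
regime morphing targets: locally similar, globally drifted), mutates a
requested fraction of residue types, and applies indels with sequential
renumbering; truth provenance (`truth_index`) is carried per residue so
benchmarks can score assignments exactly. `make_map` rasterises the truth
with the default 50 Å² blur and adds Gaussian noise as a fraction of the
map SD. The default study case is 100 residues, 2 Å amplitude, 40%
mutations (~60% identity), one 4-residue deletion, 10% noise.

What the generator does **not** emulate: phase error and solvent noise,
anisotropy, crystallographic symmetry and packing, rotamer-level
side-chain detail, and register-shifted or topologically rearranged
templates. Passing tests therefore demonstrate the algorithmic behaviour
of the stages under controlled conditions, not performance on real
crystallographic data.

## Benchmark problem sizes

The reference experiments use 60–100-residue chains: morph recovery on a
60-residue, 2 Å-deformed template against a noise-free map (main-chain
RMSD 2.0 → ≤ 0.8 Å required; measured ≈ 0.1 Å); trim recovery with 20% of
residues displaced 5 Å into empty density (≥ 90% removed, ≤ 5% false
removals); the information-source comparison on twenty 72-residue cases
fragmented by five 3-residue deletions at 40% map noise with the template
term disabled (density alone ≈ 0.50 mean correct fraction, + overlap/
connection ≈ 0.95, + order ≥ that); and the end-to-end default case
(≥ 80% of built residues correctly assigned, ≤ 5% incorrect; measured
100%/0% over ten seeds). These sizes keep every experiment deterministic
and fast while leaving each stage's failure modes visible.

## Known limitations

* The side-chain probability model is a size-correlation surrogate, not a
  per-residue-type likelihood; it cannot distinguish residues of similar
  size and is the main fidelity gap versus a full Bayesian treatment.
* Inserted loops are backbone-only and crudely framed; they anchor the
  next extraction round but are not refined models.
* The connection closeness term's functional form is invented (only the
  rejection rule is prescribed); it is bounded by 1 unit so it cannot
  override the principal terms.
* With NCS copies > 1 the optimiser enforces the usage count but applies
  no connection/loop reasoning between copies.
* Maps must be orthogonal P1; symmetry expansion, mmCIF, ligands and
  nucleic acids are out of scope.
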