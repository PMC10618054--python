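# Methods

## Model

The chromosome segment is a bead-on-a-string homopolymer in reduced units:
length in sigma (one pseudo-bond, one 100 kb locus per bead at the reference
resolution), energy in epsilon, time in tau, bead mass 1, temperatures with
the Boltzmann constant absorbed.  The stage potential is

    V(stage) = V_homopolymer + V_bias(stage)

with

* **bonds** — harmonic, `k_b = 100 epsilon/sigma^2`, rest length 1 sigma;
* **angles** — linear-placement favoured, `V = k_a (1 + cos theta)`,
  `k_a = 2 epsilon`, so a straight chain is the local minimum;
* **soft-core repulsion** — a tanh-capped Weeks–Chandler–Andersen form,
  `V = cap * tanh(V_WCA / cap)` with WCA prefactor 1 epsilon, cut off at
  `2^{1/6} sigma`, bounded by `cap = 4 epsilon`.  The bounded core lets chain
  segments pass through one another at finite energy cost, standing in for
  topoisomerase activity; the force vanishes smoothly at zero separation so
  no configuration is singular.  Directly bonded pairs are excluded.
* **confinement** — half-harmonic spherical wall
  (`k_w = 100 epsilon/sigma^2`) whose radius solves
  `n (sigma/2)^3 / R^3 = 0.10`, i.e. the beads occupy 10% of the sphere:
  R = 8.61 sigma for the 510-bead segment, 4.22 sigma for the 60-bead desk
  chain.

The biasing term couples every locus pair at genomic separation >= 2:

    V_bias = sum_{i<j} alpha_ij f(r_ij),     f(r) = (1 + tanh[eta (r_c - r)]) / 2

with `r_c = 1.8 sigma`, `eta = 5 / sigma`.  `f` is a smooth per-configuration
contact indicator; its ensemble mean is the simulated contact probability, so
the same kernel serves in the potential and in the measurement
(self-consistency).  Pairs at separation <= 1 are never biased — their
probabilities are pinned to 1 by the map normalization and are carried by
the bond term instead.

## Contact-map conventions

Maps are symmetric locus-by-locus probability matrices.  Normalization
divides the whole matrix by the mean first-off-diagonal value, clips to
[0, 1], and pins both first off-diagonals to exactly 1 (adjacent loci are
always in contact).  A single global scale was chosen over row-wise scaling
because it preserves all relative contact structure; the operation is
idempotent.  The diagonal is stored but excluded from every observable.

Observables follow the field's standard definitions: the insulation score is
the mean contact probability in a 500 x 500 kb sliding block crossing each
locus, log2-relative to the chromosome mean, with ends masked and TAD
boundaries called at local minima whose prominence over the flanking maxima
exceeds 0.1 (log2 units; chosen once as the value that separates planted
boundaries from a flat profile in the synthetic suite).  Plateau minima are
reported once, at the plateau centre.  Enhanced contacts sum fine-scale
probabilities into 1 Mb blocks and divide by the coarse distance expectation
(log2); the compartment profile is the leading principal axis of that
matrix with undefined cells imputed to zero, unit norm, signed so the bin
class with the higher short-range enhanced contact is positive (the
convention is arbitrary but deterministic, which is what reproducibility
needs).

## Dynamics

Langevin dynamics by BAOAB splitting, time step 0.0005 tau, friction
10 / tau.  With zero friction the scheme reduces to velocity Verlet, which
is how the integrator's energy conservation is checked; at the defaults the
free-bead diffusion coefficient is T/gamma = 0.1 sigma^2/tau and harmonic
equipartition holds to a few percent, both asserted in the test suite.  All
noise flows from a single `SeedSequence`-seeded generator per trajectory;
replica seeds are spawned deterministically from a base seed, so every
ensemble is bit-reproducible and each trajectory carries a manifest of its
settings and seed.

Sampling runs anneal from 4 epsilon to 1 epsilon linearly over the first
quarter of the trajectory (the ramp shape is not dictated by the protocol;
linear is the simplest monotone choice between the stated endpoints) and
hold 1 epsilon thereafter; only the second half of each trajectory enters
ensemble estimates.  Cold starts are self-avoiding random walks grown inside
the confinement sphere and briefly minimized.

## Maximum-entropy calibration

Because the bias is linear in the observable, matching the target map is a
fixed-point problem: simulate under the current couplings, measure
`P_sim`, update

    alpha_ij <- clamp(alpha_ij + lr_t (P_sim - P_target)_ij, +-10 epsilon)

Positive alpha raises the energy of a formed contact, so over-formed
contacts are penalized.  The learning rate decays as
`lr_t = lr0 / (1 + t/3)` with `lr0 = 3 epsilon` (Robbins–Monro style):
with a constant rate the couplings random-walk on the sampling noise of
`P_sim` and the error plateaus above its systematic floor; decay lets them
settle.  Divergence (three consecutive error increases) halves the base
rate once, then aborts with the history preserved.  Convergence is tracked
as mean absolute error over pairs at separation >= 2 (scale-appropriate for
probabilities), with the Pearson correlation reported alongside.

The final measurement is deliberately better sampled than the per-round
measurements: extra replicas are run under the final couplings purely to
estimate the calibrated ensemble's map, since the per-round split-half noise
(~0.03 at the desk scale) would otherwise dominate the reported error.

## Landscape switching

Transitions between stages swap the bias field instantaneously and relax at
constant 1 epsilon — relaxation on the post-switch landscape, not
re-equilibration from a melt.  Initial structures come from average-linkage
agglomerative clustering of the pre-switch ensemble on pairwise aligned RMSD
(threshold 2.5 sigma), keeping up to two structures nearest each medoid from
every cluster whose population exceeds 0.2% of the ensemble.  Clustering and
selection are deterministic given the input order.  Positions carry over at
the swap; velocities are drawn Maxwell–Boltzmann at the running temperature,
which for an equilibrated source ensemble is statistically identical to
retaining the momenta.  Checkpoints default to 1, 10, 100 and 1000 tau.

## Structural observables

Geometry comes from the gyration tensor (unit masses, 1/N normalization):
`R_g = sqrt(tr T)` and asphericity
`Delta = (3/2) sum_k (lambda_k - mean)^2 / (tr T)^2`, which is 0 for an
isotropic configuration and 1 for a rod.  (The trace identity is sometimes
written without the square root on R_g; the root is required for dimensional
consistency and is used throughout.)  Free-energy landscapes over
(R_g, Delta) are `-ln p` of the 2D histogram in units of the sampling
temperature, minimum-shifted to zero.

The fluctuation matrix `M_ij = <delta r_i . delta r_j>` is computed after
iterative superposition: each structure is centred and Kabsch-rotated onto
the running mean until the mean moves less than 1e-8 sigma.  The reference
is the ensemble mean, not a cluster representative — chromosome ensembles
are heterogeneous enough that no single cluster dominates.  The alignment
initializes from the raw ensemble mean (falling back to the first member if
rotations cancel it), which makes re-aligning an aligned ensemble a no-op.
`fluctuation_matrix` refuses ensembles that have not passed through the
aligner, because M is meaningless with rigid-body motion left in.

## Pathways

Transition pathways are quantified in observable space: PCA is fitted on the
endpoint stage profiles plus the checkpoint ensemble means (a fitting set
that embeds both statics and dynamics and gives stable axes), masked
features dropped globally rather than imputed, axis signs fixed by making
the largest-magnitude loading positive.  The null pathway interpolates the
two endpoint contact maps linearly and passes each interpolate through the
same observable; the unit adjacent band is closed under the convex
combination, so interpolates are valid maps.  The deviation score is the
mean distance from the simulated points to the interpolated polyline,
normalized by the endpoint separation — 0 means relaxation along the
interpolation, and the score is invariant to rotations of the PC plane.
A perfectly collinear fitting set is accepted (PC2 then carries ~0
variance); only a zero-variance set is an error.

## Synthetic data

The generator emulates normalized Hi-C maps at 40–120 loci (60 by default)
so the whole pipeline runs at desk scale with known ground truth:

* power-law distance decay, exponent 1;
* three equal TAD blocks at 3x enrichment (internal splits at loci 20, 40);
* an aperiodic A/B block pattern (10-locus blocks, `A A B A B B`) with
  1.6x same-label / 0.625x cross-label plaid applied only at separations
  >= 12 loci.  Two deliberate choices here: a strictly periodic pattern
  aliases away under observed/expected normalization (every coarse pair at
  a given distance would relate the same two labels), and keeping the plaid
  strictly longer-range than twice the insulation window prevents
  compartment edges from masquerading as TAD boundaries;
* a mitotic-like mode: uniform contacts within a 5-locus band, exponential
  decay beyond, no blocks, no plaid;
* a five-stage series interpolating the background and ramping the
  enrichment factors linearly, whose endpoints equal the two dedicated
  generators bit-exactly.

What the generator does not emulate: ICE-balancing artifacts, distance-
dependent noise, unmappable bins, translocations, or the empirical decay
exponents of real chromosomes.  Passing the recovery suite therefore shows
the machinery is correct and self-consistent, not that real data would be
recovered at the same fidelity.

## Problem sizes and numerical choices

The desk preset — 60 beads, 6 replicas, 120 tau annealed trajectories
(30 tau ramp), 10 calibration rounds, and transitions of a few hundred tau
— is the package's own working scale: it exercises every stage of the
pipeline end to end on a single CPU in minutes per stage.  The production preset
(510 beads, 100 replicas, 1000 tau) records the full-scale protocol and is
cluster-scale by construction.  At the desk scale, calibration of the
synthetic interphase target reaches MAE < 0.05 and Pearson > 0.9 against
the target map within ~10 rounds, which the acceptance tests assert.

Numerical details worth knowing: the contact indicator and its force are
short-circuited outside `|eta (r_c - r)| <= 8`, where the switch is flat to
~1e-7; tanh is evaluated through an exp identity that is exact to double
precision; coincident beads fall on the capped branch of the soft core
(finite energy, zero force) rather than a singularity; cluster ties break
toward the lower structure index; degenerate gyration tensors (all beads
coincident) yield R_g = 0 with Delta undefined-masked.

## Limitations

* The bias acts on smooth indicator means, not on hard contact counts;
  calibrated maps match targets up to the indicator's softness and residual
  sampling noise (~0.03–0.04 MAE at the desk scale).
* Maps whose short-range entries saturate at 1.0 are matched only
  asymptotically — a probability of exactly 1 requires a permanent contact.
* No explicit loop-extrusion agents; TADs and compartments exist only as
  imposed contact statistics.
* Aligned-RMSD clustering is O(M^2) in ensemble size; subsample before
  clustering very large ensembles.
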