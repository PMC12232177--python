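# Methods

`translocv` re-implements, at desk scale, an enhanced-sampling analysis of
stepwise DNA translocation through a Y-family polymerase: machine-learning
collective variables (CVs) trained on protein–DNA contact descriptors, OPES
biased sampling on those CVs, state/pathway bookkeeping, and free-energy
surface (FES) barrier extraction. Because microsecond all-atom MD is out of
reach on a desk, every stage is exercised on a synthetic surrogate whose
ground truth — basin positions, saddle heights, the discriminative
descriptor subset — is known by construction. What the tests establish is
therefore *method correctness* (each stage recovers what was designed into
the data), not any statement about the real enzyme.

## The surrogate landscape

The two slow degrees of freedom are progress coordinates x = (x1, x2) for
the primer and template strand, each 0 (pre-translocation position) or 1
(post-translocation). Four metastable states sit at the unit-square
corners: PRE = (0,0), INT1 = (1,0) (primer moved first), INT2 = (0,1)
(template first), POST = (1,1).

The potential is a sum of two quartic double wells with state-dependent
coefficients, a C² smoothstep tilt that sets the basin depths, and a
product coupling g(x1)·g(x2) that penalises the concerted diagonal
PRE↔POST move:

V(x) = A(x2)·g(x1) + B(x1)·g(x2) + tilt(x) + C·g(x1)·g(x2),
g(u) = 16u²(1−u)².

The four edge coefficients are calibrated at build time by bisection on 1-D
edge scans so that each edge saddle hits its designed height exactly.
Defaults place the saddles at 7.5 (PRE–INT1), 15.0 (INT1–POST, measured
from PRE — the "overall barrier" reading; whether that published value is
referenced to PRE or INT1 is ambiguous, and this package fixes the PRE
reading), 17.0 (PRE–INT2) and 10.0 kcal/mol above INT2 (INT2–POST). Basin
depths relative to PRE are a free choice of the surrogate (INT1 = +3.0,
INT2 = +5.0, POST = 0.0 kcal/mol): intermediates are shallow relative
minima, the end states roughly isoenergetic. The diagonal penalty (default
10 kcal/mol) keeps the concerted crossing at least 10 kT above every edge
saddle, making the two stepwise paths the only viable mechanisms.

kT = 0.616 kcal/mol (310 K), so all energies live on the kcal/mol scale.
Dynamics are overdamped Euler–Maruyama Langevin steps with friction 1 and
dt = 5·10⁻⁴ in reduced time, chosen against the stiffest basin curvature
(stability requires dt < 2γ/V'' ≈ 4·10⁻³) and validated by the harmonic
equipartition test at 5%.

## Descriptor emulation and the packaged candidate pool

Each synthetic "contact" is a logistic switch between two plateau distances
(≈4 Å formed, ≈9 Å broken) as its axis crosses ½, plus Gaussian noise
(0.4 Å). The packaged pool holds 350 candidates: 69 informative columns
(35 primer-axis, 34 template-axis; exactly one per residue–base-pair
group), 81 redundant duplicates sharing a group with an informative column
but with a smaller between-state margin, 100 low-presence columns
(essentially never within contact range) and 100 non-discriminative
columns. The three-rule filter — (i) present (≤6 Å) in ≥50% of the frames
of at least one state, (ii) between-state mean shift > 2·max(SD_A, SD_B),
(iii) one contact per residue–base-pair group, keeping the largest
rule-(ii) margin — retains exactly the 69 informative columns by design.
The 6 Å presence cutoff is this package's definition (a typical
Nζ/Cζ–phosphate salt-bridge range); the filtering literature the pipeline
mirrors does not state one.

Per-state fixture frames are drawn from the local harmonic (Boltzmann)
approximation at each minimum rather than from short Langevin runs: every
saddle is ≥12 kT above its adjacent minima, so within-basin statistics are
harmonic to high accuracy, and direct sampling keeps fixture generation
fast and exactly reproducible. "Reactive" (unlabeled) frames are spread
along the two L-shaped corridors with transverse scatter 0.05.

What the generator does *not* emulate: real contact-distance distributions
are skewed and multi-modal (side-chain rotamers, water bridges), descriptor
noise is correlated across contacts, and real trajectories carry kinetic
correlation between frames. Passing tests therefore validate the pipeline
machinery, not its behaviour on all-atom data.

## Collective variables

Both CVs are small dense networks (numpy, hand-written backprop, Adam,
full-batch or stratified mini-batches; deterministic for a fixed seed).

**Discriminant CV (1-D).** Architecture [69, 30, 20, 15, 10, 5], ReLU; a
trainable direction over the last layer gives a scalar projection whose
Fisher ratio (variance of the two class means over the mean within-class
variance, with S_w regularization 0.05 added to the denominator) is
maximized; training minimizes −log(ratio) + 10⁻⁴ L². 500 epochs at
learning rate 5·10⁻⁴. The "Lorentzian" regularization (published scale 40;
functional form this package's documented choice) enters the objective
twice: the Fisher ratio is computed on the saturating transform
z/√(1+(z/40)²) of the raw projection, and a quadratic penalty
mean(z²)/40² keeps the projection inside the transform's responsive
range — a discriminant parked on the plateaus would have no gradient left
to transmit bias forces. The bounded projection is affinely normalized so
the two training states sit at +1 (PRE) and −1 (POST), flipping sign if
needed.

**Multitask CV (2-D).** Autoencoder [69, 50, 30, 15, 5, 2] / mirror
decoder, shifted-softplus activations, 500 epochs at 10⁻³. Loss =
reconstruction MSE on unlabeled reactive frames + a targeted-discriminant
(TDA) term on labeled frames: Σ_states Σ_components α(μ_batch−μ_tg)² +
β(σ_batch−σ_tg)², α = β = 1. Targets: PRE (−6,−6), INT2 (−3,3), INT1
(3,−3), POST (6,6), σ_tg = 0.2. Each epoch draws one stratified labeled
sub-batch (500/state) for the TDA term and one unlabeled sub-batch (2000)
for reconstruction; the published protocol does not specify loss weights or
batch mixing, so these are package defaults exposed in the config.

## OPES

The bias is built from a compressed kernel-density estimate of the sampled
CV distribution, targeting the well-tempered distribution
P_tg ∝ P^{1/γ}:

V(s) = c·[log(p̂(s)/Z + ε) − log ε],

with γ = β·BARRIER by default, Z the maximum of p̂ over kernel centers, and
ε = 1/(e^{cap/c} − 1) chosen so the bias saturates at exactly
cap = (1−1/γ)·BARRIER. Normalizing by the maximum instead of a running
average shifts the bias by an s-independent constant at any fixed time,
which changes neither forces nor normalized reweighting, and makes the
saturation cap exact. Two deposition variants are provided: *standard*
(kernel weights e^{βV}, estimating the unbiased distribution) and
*explore* (unit weights, estimating the biased distribution). Kernels
deposit every STRIDE steps; near-coincident kernels merge by moment
matching. The kernel bandwidth starts at SIGMA and, in the default
production mode, widens to the CV displacement between consecutive
depositions (capped at 3×SIGMA): a neural-network CV stretches latent
space very unevenly, and fixed-width kernels leave gaps exactly where a
saddle region is stretched across many CV units. Count-based bandwidth
shrinkage is also available but off by default — at desk-scale deposition
counts it makes the bias surface spiky.

Bias forces reach the latent coordinates by the chain rule through the CV
network and the analytic descriptor map (the reason the surrogate's
descriptor response is smooth). A per-step cap on the deterministic
displacement (0.1 latent units) guards against rare force spikes where a
stiff wall meets a steep CV region; in the well-behaved regions the cap is
far above typical forces. Repulsive walls k·(s−limit)² act per CV
component (|CV| ≤ 1.5 for the 1-D CV, ±7.5 per component in 2-D,
k = 40000).

The 2-D production protocol separates the two jobs a biased run performs.
A *build* phase (explore variant, STRIDE = 20 reduced steps, jump-mode
bandwidth) only has to produce a flat static bias: unit-weight kernels
flatten the landscape democratically — under-biased regions attract the
walker, collect kernels and rise, and diagnostics show the residual
F + V varies by less than ±1.5 kcal/mol along all four corridors after
4·10⁵ steps. (The e^{βV}-weighted variant is the textbook estimator of
the unbiased density, but at desk-scale deposition counts its enormous
weight ratios let kernels from one corridor spill across CV-space
neighbours and pin them at the cap.) Four *tail* walkers, one started in
each basin, then sample the frozen bias for 2.5·10⁵ steps each; the first
20% of each tail is discarded as equilibration. Umbrella reweighting with
w ∝ e^{βV(s)} is exact for a static bias, so the pooled tails give an FES
whose only error is statistical. A molecular-dynamics STRIDE of 500×2 fs
deposits ~10⁶ kernels over microseconds; the much finer surrogate stride
keeps a comparable deposition density. The recorded CV values are
evaluated on *noisy* descriptors (as an on-the-fly CV of a real trajectory
would be) from an independent noise stream, while forces always use the
noise-free map — without this, the noise-free basin image collapses to a
point in CV space and every barrier read from the CV-space FES inflates by
a kT·log(compression) entropy term.

## States, transitions, pathways

Frames are assigned by fixed-radius spheres (0.25 latent units) around the
four reference points, TRANSIT otherwise — deliberately independent of any
trained CV so the assignment can audit CV-driven runs. An end state counts
as *visited* after 10 consecutive frames (recrossing suppression); a
PRE↔POST record is emitted between consecutive distinct end-state visits,
and its intermediate is the last raw INT1/INT2 label strictly between them,
so fast single-frame passages through an intermediate still classify the
pathway. Pathway preference is reported as the fraction of PRE-origin
records via INT1 with an exact (Clopper–Pearson) binomial interval.

## FES and barriers

F(cell) = −(1/β)·log(weighted occupancy), min-shifted to zero; unvisited
cells are flagged impassable, never zero. The default 60×60 grid covers the
wall-bounded square [−7.5, 7.5]². Before taking the log, the occupancy is
convolved with a fixed Gaussian of 0.4 CV units — twice σ_tg, the width of
the narrowest physical feature on the map. This suppresses the single-cell
sampling spike of the σ_tg-pinned basins (which otherwise biases every
barrier upward by the basin/corridor resolution mismatch) while leaving the
much broader saddle profiles intact, and it makes the barrier readout
stable under grid refinement.

A barrier is the minimax path height: the 8-connected cell path minimizing
the maximum free energy crossed, above the starting basin cell. Because the
two stepwise paths occupy opposite half-planes of the anti-diagonal
coordinate cv1−cv2, each *edge* barrier is searched within its own corridor
(side·(cv1−cv2) ≥ −1.0); without the restriction the minimax path between
non-adjacent basins detours through the other intermediate and reports that
detour's saddle instead of the edge's own. Reference conventions follow the
published values: INT1→POST is quoted from PRE ("overall barrier"),
INT2→POST from INT2, the others from PRE. Uncertainties are block
averages: the kept frames are split into 4 contiguous blocks, each barrier
recomputed per block, and SD/√n_blocks reported; how the original
uncertainties were computed is not stated, so block averaging is this
package's choice.

## Problem sizes and determinism

Default desk-scale sizes: 5000 fixture frames/state for CV training (the
full-scale protocol uses 20000), 10000 unlabeled reactive frames, a 400k-step
bias build plus four 250k-step tails for the FES, and sixteen pooled 35k-step
runs for transition statistics. All
randomness flows from explicit integer seeds through `numpy` Generators;
identical configs and seeds reproduce trajectories bit-for-bit. Training is
deterministic because initialization and batch draws come from the config
seed.

## Known limitations

- The surrogate's barriers are *potential-energy* saddle heights; the
  CV-space FES adds small entropic distortions (quantified at ≲0.8 kcal/mol
  under ideal sampling with the smoothing above).
- Pathway preference is a filling-regime observable, and a weak one here:
  OPES reaches its bias cap at any sampled point almost immediately, so
  both corridors open within the first escapes and the thermodynamic
  via-INT1 preference (9.5 kcal/mol at the saddles) survives only as a
  modest dynamical bias of the escape route (~70–85% of PRE-origin
  transitions across calibration protocols). The real enzyme's unanimous
  route choice rests on orthogonal slow modes that gate the template-first
  path kinetically — structure the surrogate deliberately does not model.
  Transition statistics are harvested from many short runs pooled, the
  regime where the preference is strongest.
- No kinetics: biased transition counts say nothing about rates.
- Real-structure support covers distance computation from PDB models and
  the filter; no trajectory-format readers beyond multi-model PDB and
  COLVAR-style tables.
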