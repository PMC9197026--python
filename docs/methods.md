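# Methods

## The generative model

Each V-segment read `s` is assumed to derive from a germline template `t`
(drawn from a template set with prior `p_t`, uniform by default) through a
single round of somatic hypermutation summarized by a per-sequence
*maturation age* `mu`: the point-mutation rate per base pair accumulated
over the sequence's history in germinal centers. The repertoire-wide
distribution of ages is a mixture

    P(mu) = f * delta(mu) + (1 - f) * Ptilde(mu),

where `f` is the fraction of naive cells (exactly `mu = 0`) and `Ptilde`
is a smooth density stored on a uniform binning of [0, 1] (bin width
0.0005 by default, configurable). Conditioned on `mu`, the mutation
process sweeps the template once; at each position, independently:

* a deletion event starts with probability `mu * beta_del` and removes
  `ell ~ P_del` template bases (`ell <= theta_max`);
* an insertion event starts with probability `mu * beta_ins` and inserts
  `ell ~ P_ins` uniform-random bases;
* otherwise the base substitutes with probability
  `(1 - mu*beta_del - mu*beta_ins) * mu` to one of the three other bases.

The rescaled rates `beta_del`, `beta_ins` are repertoire-wide constants:
indel and point-mutation loads scale together with age, which is the
empirical signature this model encodes. Note that the mismatch
probability is `mu` for *any* wrong base (no `mu/3` split); the emission
mass per position is therefore not exactly 1. This literal form is what
gives the deterministic aligner its `ln(mu) ~ -3` mismatch penalty and is
used consistently in the simulator and the likelihood.

Model parameters are collectively `theta = (P(mu), phi)` with
`phi = (beta_del, beta_ins, P_del, P_ins)`.

### What the generator emulates — and what it does not

The synthetic benchmark conditions (module `shmindel.simulate`) are: 10%
naive cells; experienced ages from a shifted Gamma (unshifted mode 0.07,
sd 0.04, shift 0.02, negatives rejected — resulting mode 0.05);
`beta_del = beta_ins = 0.025`; geometric event lengths of characteristic
scale 15 bp truncated at 30 bp; uniform placement along the template.
These are the defaults of `benchmark_model()` and are what the acceptance
script regenerates.

Real repertoires have features the generator deliberately omits:
positional hotspots (profiles here are flat), homology of inserted
segments to their flanks (inserts here are uniform — so flank-overlap
statistics act as a negative control), context-dependent substitution
biases, lineage structure, and sequencing error. Passing tests therefore
demonstrate correctness of the inference machinery under the model's own
assumptions, not that real data satisfy those assumptions.

Boundary conventions of the simulator (all rare at realistic rates): a
deletion overrunning the 3' end is truncated; an indel starting inside an
already-deleted stretch is discarded; point mutations hit only
template-derived positions, at most once; insertions attach immediately
before their template position. Ground-truth scenarios record exactly the
applied events, so replaying a scenario reproduces its read byte for
byte.

## The sum-over-alignments likelihood

The conditional likelihood `S(s, t | mu; phi)` sums the probabilities of
*all* global alignment scenarios: a matched column contributes
`M(s_i, t_j)`, a deletion of `ell` template bases contributes
`Gamma_del(ell) = mu*beta_del*P_del(ell)`, and an insertion of `ell` read
bases contributes `Gamma_ins(ell) = mu*beta_ins*P_ins(ell)*(1/4)^ell`
(the last factor is the probability of the specific observed inserted
bases — which is why insertions must consume read bases and deletions
template bases). Abutting indel events are distinct scenarios and are all
included; this is exactly what lets the model reinterpret one long
deletion as several shorter nearby ones.

The forward recursion computes this in `O(L_s * L_t * (2*theta_max + 1))`
operations. The per-read marginal is

    L(s; theta) = f * S(s, t*|0; phi)
                + (1 - f) * sum_bins Ptilde(mu) * S(s, t*|mu; phi) * dmu,

a midpoint quadrature over the binned prior, with the template sum
collapsed to the single best template `t*` chosen by deterministic
alignment score (with templates as distinct as real V genes, the best
template dominates the sum overwhelmingly; the uniform `p_t` prefactor is
a constant and is dropped).

### Numerics

The recursions run in linear space with adaptive per-row rescaling (one
log-scale constant per read position), which is equivalent to log-space
accumulation but avoids a transcendental call per term. Correctness is
pinned by a brute-force scenario-enumeration oracle at 1e-12 relative
tolerance. In the fitting hot loop the row scales are frozen per
sequence (recomputed once per iteration at the sequence's current
posterior age) so that one likelihood evaluation is a single multiply-add
sweep over the precomputed edge list; any evaluation that leaves the
representable range is automatically redone with an exact streaming
log-sum-exp sweep. Likelihoods of exactly zero (e.g. `mu = 0` with a
mutated read) are legitimate and reported as `-inf` log-likelihoods.

### Pruning

For each read, one unpruned forward+backward pass at an initial parameter
guess (the deterministic-annotation age, floored at 0.01 so the band has
width) yields the passage posterior
`Shat_ij = S(s_1:i, t_1:j) * S(s_i+1:, t_j+1:) / S(s, t)` — the
probability that the true alignment passes through cell `(i, j)`. Cells
with `Shat < 1e-5` are frozen out of all subsequent evaluations of that
read. The mask is fixed once (a `refresh` flag exists but is off, since
parameters move little after initialization); masked likelihoods agree
with unmasked ones to better than 0.1% at the default threshold, which
the test suite asserts.

## Inference

The repertoire log-likelihood is maximized by alternating:

1. **E step / prior update (exact EM).** Each read's age posterior is
   `P(mu|s) = f_s * delta(mu) + (1 - f_s) * Ptilde(mu|s)` with
   `f_s = f L(s|0) / [f L(s|0) + (1-f) integral Ptilde L(s|mu) dmu]`. The
   new prior is the closed-form maximizer: `f <- mean(f_s)` and
   `Ptilde <- sum_s (1-f_s) Ptilde(mu|s) / sum_s (1-f_s)`.
2. **Gradient step on phi.** The expected conditional log-likelihood is
   approximated by one Monte-Carlo age sample per read per iteration
   (slowly moving parameters make the time average stand in for a large
   sample); its gradient is estimated by forward finite differences
   (`epsilon = 1e-4`) and applied with momentum,
   `phi <- Proj(phi + alpha_t * scale * grad + omega_t * (phi - phi_prev))`,
   where `Proj` clips the rates at 0 and projects each length
   distribution onto the probability simplex (sort-and-threshold
   Euclidean projection). Schedules: `alpha_t = alpha0 * exp(-2t/T)`,
   `omega_t = t/(t+3)`. The learning-rate scale is the parameter
   magnitude (floored) for the two rate components, but *uniform* within
   each length-distribution block: because the simplex projection
   subtracts one common threshold, a non-uniform scale inside a block
   would move the projected-gradient fixed point away from the
   maximum-likelihood solution (its stationarity condition would become
   `scale_i * g_i = const` instead of `g_i = const`).

**Posterior representation.** `L(s|mu)` is evaluated at 15 nodes (25 for
reads with >= 5 substitutions) placed with Gauss-like spacing over
+/- 4 posterior spreads around the current posterior maximum, plus
mandatory endpoint nodes at the lowest and highest prior bins; the
log-likelihood is interpolated onto the prior grid with a monotone
piecewise cubic (PCHIP) before the quadrature. Node centers and spreads
are refreshed from each iteration's posterior. An `exact_grid` mode
evaluates every prior bin instead; with `phi` frozen this makes the EM
update exact, and the test suite verifies the textbook monotonicity
guarantee in that mode.

**Initialization.** All of `theta` starts from the deterministic
annotation: `f` is the fraction of event-free reads, the betas are event
count ratios, `Ptilde` is a kernel-smoothed histogram of per-read
mutation loads (with a 1e-4 uniform floor so no bin is exactly empty),
and the length distributions are smoothed event-length histograms
(Gaussian kernel, sigma 1.5 bp, floor 1e-6). This initial model is also
reported as the "deterministic estimate" against which the fit is
compared.

**Numerical choices and their rationale.**

* `alpha0 = 0.005`: with per-component magnitude scaling, the effective
  contraction rate of a rate parameter is roughly
  `alpha0 * beta * I_beta` per iteration (`I_beta ~ E[events]/beta^2` the
  per-read Fisher information); at realistic event loads, larger rates
  (0.05) overshoot and oscillate once momentum builds up, visibly
  distorting the fitted length distributions. 0.005 keeps the largest
  per-iteration relative step below ~10%.
* `scale_floor = 1e-3` prevents the rate components from freezing when
  pinned near zero (their learning-rate scale would vanish).
* `gradient_clip = 2.0` caps each length-probability gradient component:
  these gradients behave like `counts/P` and diverge as a component
  approaches zero, and without a cap momentum launches a rarely
  supported length far past its equilibrium before the restoring force
  (which is bounded by the simplex multiplier, ~0.4) can pull it back.
  The cap changes no fixed point — equilibrium gradients sit at the
  multiplier, well below it.
* Ties in the simplex projection and the NW traceback are broken
  deterministically (aligned column > deletion > insertion; extend over
  open on equal score), so the whole pipeline is reproducible bit for bit
  under a fixed seed.
* Degenerate inputs: a read with zero likelihood under every allowed
  scenario raises a dedicated error instead of returning `-inf` silently;
  an all-naive posterior keeps the previous smooth density with a
  warning (the density is unidentifiable in that limit).
* The prior density is not smoothed between EM iterations.

## Deterministic baseline

`shmindel.annotate` implements the standard affine-gap Needleman-Wunsch
annotation with the log-odds penalties implied by average mutation
statistics (5% substitutions, 0.05% indels, geometric length scale 10):
match `ln 0.95 ~ -0.05`, mismatch `ln 0.05 ~ -3.0`, deletion open
`ln 0.0005 - 0.1 ~ -7.7`, extend `-0.1`, insertion open/extend shifted by
`-ln 4` for the inserted base. Gap "open" includes the first extension
step. Exact constants are derived from the rates at run time, never
hard-coded. Two biases of this baseline are reproduced and tested: every
mutation-free read is called naive (overestimating `f`), and deletion
pairs closer than ~`|del_open| / (mismatch - match)| ~ 2.6` bp are merged
into one long event, depleting short inter-deletion distances.

## Summary statistics

`shmindel.stats` computes, in template-local 0-based coordinates:
per-read event counts with a Poisson reference fit; SHM load conditioned
on indel count; insertion/deletion flank overlaps with a
randomized-insert control (the duplication signature of polymerase
slippage — identically null under this generator); inter-deletion
distances (half-open convention: a deletion ending at 10 and one starting
at 15 are 5 bp apart); coverage-normalized positional profiles with a 2%
coverage mask and pairwise Pearson correlations; an indel-to-nearest-SHM
co-localization ratio against a within-template reshuffling null; and a
200-bp V-coverage quality filter. IMGT gapped numbering is out of scope;
an optional position mapping can be applied to the profile table by the
caller.

## Problem sizes used in the test-bed

The acceptance benchmark fits 4,000 synthetic reads from 8 random 300-bp
templates with inference support `theta_max = 60` and `T = 80`
iterations (the convergence criterion usually stops it after ~30-55); at
these sizes the statistical error of the recovered naive fraction is
~0.5 percentage points and of the rescaled rates ~3-4% relative,
comfortably inside the tolerances being checked.

The repertoire size matters for one statistic in particular: the
inferred length-distribution mass above the generative 30-bp cutoff.
The generator occasionally emits two indel events that abut (or are
separated by a few, possibly mutated, bases); in a finite repertoire the
maximum-likelihood fit genuinely supports the corresponding merged
length `l > 30` at probability `~ k/(N*lambda)`, where `k` is the number
of such reads, `N` the repertoire size and `lambda ~ 0.4` the mean
number of indel events per read (the simplex multiplier). A length stays
supported only while its amortized pattern frequency exceeds
`lambda * P_half`, where `P_half` is the probability ratio of the
two-shorter-events explanation to the one-long-event explanation. For
insertions `P_half` is large (the merged explanation pays the
`(1/4)**l` composition factor through a longer insert), so at 4,000
reads isolated coincidences fall below threshold and the inferred
insertion tail is clean — the behaviour reported at the much larger
original scale. For deletions `P_half` is ~50x smaller and two or three
abutting deletion pairs in one repertoire can legitimately keep ~1e-3
at one length; the deletion-side cutoff test documents this and is
expected to fail for such seeds.

Unit and
property tests use templates of 60-300 bp, repertoires of 8-400 reads,
and enumeration oracles on sequences up to length 6 with
`theta_max <= 3`, where the brute-force scenario sum is tractable. These
sizes are the package's own test-bed choices; the library itself has no
intrinsic size limits beyond memory.

## Known limitations

* One template per read after selection (the multi-template marginal is
  approximated by its dominant term); fine for V genes, wrong if two
  templates are nearly identical over the read.
* The generative model has flat positional profiles and non-templated
  uniform insertions; fitted parameters on real data describe rates and
  length laws, not hotspot structure.
* `N_MC = 1` makes individual iterations noisy; the trajectory, not a
  single iteration, carries the convergence signal.
* The EM monotonicity guarantee is exact only in `exact_grid` posterior
  mode; the node-interpolated mode trades a ~1e-4 quadrature error for a
  ~100x speedup.
* Gradient ascent on `phi` has no exact M step; convergence to a local
  maximum is the standard caveat, mitigated by initializing at the
  deterministic estimate.
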