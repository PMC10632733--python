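# Methods

## Steady-state model

The signaling network is a directed graph over named nodes (receptors,
enzymes, transcription factors). Each link carries one local response
coefficient `r`, the direct sensitivity of the target to the source with
the rest of the network frozen; the measured quantities are global
responses, the steady-state log2 fold changes after the whole network
re-equilibrates under a sustained perturbation. Treatments are encoded
per agent: an inhibitor contributes a strength `u_inh` added to its
target node's *output* (multiplicative attenuation of the signal seen
downstream, additive in log space), a ligand stimulation contributes an
additive input `u_stim` on its receptor, and withdrawal of a
constitutive ligand is a stimulation-type parameter with unconstrained
(in practice negative) strength. The response of condition `c` solves
the linear system `x = r (x + u_inh) + u_stim`, evaluated by one LU
solve per parameter vector across all conditions.

This "inhibitor acts on the output" convention is the only linear one
that reproduces a diagnostic feature of such data: under MEK inhibition
the pMEK readout itself *rises* when an ERK→RAF negative feedback is
present, because the readout responds only through the network. All
parameters — link coefficients and agent strengths — are unconstrained
reals with no sign restrictions; signs are results.

Assumptions: a single time point at an approximate post-translational
steady state; linearity of log fold changes in perturbation strength
(small-to-moderate responses); independent Gaussian noise on the log2
scale (log-normal fold changes); both cell lines share one network
structure, differing only in parameter values.

## Fitting

The residual is the error-standardized sum of squares over all
non-missing (treatment, readout) points, using replicate-mean log2 fold
changes; missing cells simply drop out (zero weight, no imputation).
Measurement errors default to the standard error of the replicate mean,
`max(sd/√n_rep, σ_min)` with `σ_min = 0.1` log2 units (the floor keeps
zero-variance cells from dominating); a dataset may instead carry known
errors, which the synthetic benchmarks use so that calibration
statements are exact.

Optimization is multi-start Levenberg–Marquardt with an analytic
Jacobian (for `A = (I−r)⁻¹`, `∂x/∂r_ts = (x_s + u_s) A e_t`, and agent
columns `A r e_k` / `A e_k`). Starts are Latin-hypercube samples over a
`[−5, 5]` box; when no warm start is supplied the zero vector (the
no-interaction model) is always included as the first start — it is
deterministic, costs one local fit, and in our tests reached the global
basin far more reliably than small LHS batches alone. Default
`n_starts=1000` (desk scale; published applications of this family of
methods use up to 10⁵), tolerances 1e−10, 2000 function evaluations per
start. Parameter vectors that make `I − r` numerically singular
(|det| < 1e−12) receive a large penalty residual, which confines the
search to the model's domain. Among numerically tied optima the
minimum-norm solution is kept: structurally non-identifiable scale
directions (e.g. through an unmeasured, unperturbed node) create exactly
flat valleys, and the minimum-norm representative keeps downstream
profiling inside its walk range. Problems with fewer residuals than free
parameters fall back to the trust-region solver, since MINPACK LM
rejects them.

## Network completion

Candidate links originate from nodes acting via post-translational
modification (receptors, enzymes) and may target anything but a ligand.
Per round, every candidate is added individually and refitted in each
cell line (one warm start from the parent optimum plus optional LHS
starts); the residual decrease is tested against χ²(df = 1) and
BH-adjusted per cell line across the round's candidates (a pooled
adjustment is available). Links significant in **both** lines at
`α = 0.005` are eligible — the two lines keep one structure — and the
eligible link with the highest relative residual reduction averaged over
the lines is accepted, ties broken lexicographically. After each
acceptance every link is tested for removability (refit without it;
removable if the residual increase stays below the χ² 1−α quantile in
both lines); pruning is opt-in. Rounds repeat until no eligible link
remains or a safety cap (default 15) is reached. With a fixed seed the
whole trace is bit-for-bit reproducible.

## Profile likelihood and pathway coefficients

A parameter's profile fixes it at values walking outward from the MLE
(step `max(0.2·|θ|, 0.05)`, walk limit `|θ| ≤ 50`) while all other free
parameters are re-optimized — except the inhibitor strengths, which are
held at their MLEs following the source procedure; the χ² threshold then
uses `df = 1 + (number of fixed inhibitors)` (8 in the seven-inhibitor
study design; `df` and the fixed set are configurable, with
`fixed_params=[]`, `df=1` giving the conventional profile). Confidence
bounds are refined by bisection refits to the exact threshold crossing —
a single linear interpolation between walk points systematically
underestimates the bound on the locally quadratic residual surface. A
bound not crossed within the walk limit is reported infinite
(practically non-identifiable).

Pathway coefficients multiply the coefficients along canonical paths
(ligand entry to the pathway's most downstream measured protein,
*including* the stimulation strength so each canonical pathway is one
interpretable number), feedback loops (all simple cycles; the product is
rotation-invariant), and crosstalk paths (ligand entry to a measured
terminal via at least one added link; paths spanning more than two
canonical pathways are computed but flagged). CIs are propagated through
the profiles: along each member's profile, the product is evaluated with
the co-fitted values of the other members, and the interval is the
envelope over every member's confidence region. A member with an
unbounded CI makes the path CI unbounded unless the product saturates at
the walk edge — the signature of compensating parameters whose product
remains identifiable (this is also why a perfectly anti-correlated pair
yields a near-point product CI). Two pathway coefficients differ
significantly when their 95% CIs do not overlap; touching intervals
count as overlapping.

## Synthetic data generator

The generator emulates the study design: 16 nodes (LIFR–JAK–STAT3,
IGFR–PI3K–AKT–{GSK3, mTOR}, FGFR–RAS–RAF–MEK–ERK, ACTR–SMAD2, BMPR),
10 agents (7 inhibitors, FGF4 and Activin A stimulations, LIF
withdrawal), all singles and pairs except the two same-pathway pairs
(IGFRi+PI3Ki, MEKi+FGFRi) — 53 treatments — 7 phospho-readouts, 3
replicates, Gaussian log2 noise (default sd 0.15 per replicate, matching
the visual replicate spread of such data; benchmarks use 0.1). Two
parameterizations share the structure: the MAPK feedback loop product is
−0.09 (XX-like) vs −1.38 (XO-like) and the Activin canonical coefficient
0.43 vs 0.95, with five added links (JAK→FGFR, GSK3→IGFR, ERK⊣RAF,
ACTR⊣RAS, LIFR→AKT) on top of the literature chains. The BMP receptor
carries a weak literature link to SMAD2 so its inhibitor parameter is
not structurally disconnected in the starting network; the fixture is a
test scaffold, not a claim about the full completed topology, and the
structure files are user-replaceable. Control rows are exactly 1 (fold
changes are defined relative to control). With `attach_true_sigma` the
dataset carries the exact error of the replicate mean (`sd/√n_rep`);
with three replicates an *estimated* per-cell error has t₂-tailed
standardized residuals (infinite second moment), so calibration-style
statements are made with known errors.

What the generator does **not** emulate: raw Luminex/immunoblot
intensities (preprocessing has its own fixtures), heteroscedastic or
outlier noise, antibody cross-reactivity, replicate-level batch
structure. Passing benchmarks therefore demonstrate correctness of the
estimation machinery under the stated noise model, not robustness to
every artifact of real data.

## Benchmark problem sizes

`mranet.benchmarks` (used by the test suite and `scripts/acceptance.py`)
runs at desk scale on one CPU: oracle agreement on 100 random stable
networks; noiseless recovery with 500 starts and CI coverage over 100
noisy runs on the 3-node identifiable chain-with-feedback scenario;
extension recovery and null control over 20 single-round runs each of
the full 16-node design (12 initial starts, warm-start candidate
refits); residual calibration over 200 simulations; and the differential
comparison with 60 starts per line, profiling only the members of the
two pathways of interest.

## Known limitations

Individual coefficients through unmeasured, unperturbed nodes are
structurally non-identifiable (only products are constrained); the
package reports this honestly as unbounded profile CIs rather than
reparameterizing. The fixed-inhibitor/df=8 CI convention is inherited
from the source procedure and is statistically unconventional; the
conventional df=1 full profile is available. Greedy completion explores
one link per round and offers no global structure-search guarantee. The
linear steady-state model cannot represent saturation or time-resolved
dynamics.
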