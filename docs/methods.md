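# Methods

## Scope and units

`neqcycle` analyses nonequilibrium alchemical free-energy data: it
starts from per-transition dH/dλ traces (or work values) and ends at
ligand-network statistics. System preparation, topology generation and
molecular dynamics are outside its scope. All internal energies are in
kcal/mol (R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹, 1 kcal = 4.184 kJ); trace
files default to kJ/mol, the MD-engine convention, and are converted
once at integration time so parsed traces always show the file's raw
numbers. The default temperature is 298.15 K.

## Work integration

Work is the composite-trapezoid integral of dH/dλ over λ ∈ [0, 1].
Time-indexed traces are mapped linearly onto λ between their first and
last timestamps — the intended use is fixed-length switches (the
benchmark protocol used 100 ps), so nonlinear λ(t) schedules are not
supported. Reverse (1→0) traces are integrated in their own frame: the
file's progress variable runs 0→1 and the integral is the reverse-switch
work, which is what the Bennett equation consumes. Trapezoid quadrature
is exact for linear integrands and second-order otherwise; traces are
densely sampled in practice, and the synthetic-trace writer guarantees
its files integrate back to the generating work within 1e−9.

## Estimators

* **Jarzynski**: ΔG = −kT ln((1/n) Σ e^(−Wᵢ/kT)), evaluated through a
  log-sum-exp shift so works of magnitude 10⁵ kcal/mol cannot overflow.
  The exponential average is dominated by rare low-work tails, so it is
  kept as a diagnostic rather than the headline value.
* **Gaussian approximation**: ΔG = ⟨W⟩ − var(W)/(2kT), with the
  unbiased (n−1) variance. Exact in expectation when the work
  distribution is Gaussian.
* **BAR**: the self-consistent Bennett equation under the convention
  P_f(W)/P_r(−W) = e^(β(W−ΔG)), with the sample-count constant
  M = kT ln(n_f/n_r) (the standard minimum-variance choice). The root
  is bracketed on the pooled work range expanded by 50 kT per side and
  solved by Brent's method to 1e−8 kcal/mol; the residual is written in
  Fermi functions evaluated via `scipy.special.expit`, so no exponent
  can overflow. The default uncertainty is Bennett's asymptotic
  variance; a seeded bootstrap is available as a cross-check — both are
  reported because published pipelines are rarely explicit about which
  they quote.

BAR is the reported estimator throughout the pipeline (it converges
fastest when bidirectional sampling exists); Jarzynski and Gaussian
values are computed and stored alongside.

## Replica weighting

Replicate ΔG values are combined with proximity weights
ωᵢ = Σⱼ exp(−(ΔGᵢ−ΔGⱼ)²/(2σ²)) and ΔG = Σωᵢ ΔGᵢ / Σωᵢ. The bandwidth
follows the rule of thumb σ = std(ΔG)·n^(−1/5) with the (n−1) sample
standard deviation — worth stating because the default replica count is
only 3. Degenerate cases fall back to the arithmetic mean: σ = 0 (all
replicas equal), n = 1, or the user choosing σ → ∞, which is realized
exactly as equal weights rather than by plugging in a large number.

The weight formula is deliberately the squared-exponent Gaussian
kernel. A linear, unsquared exponent (available for comparison via
`kernel="printed"`) would *increase* the weight of replicas with larger
ΔG rather than downweight outliers symmetrically, contradicting the
purpose of proximity weighting; the package treats the Gaussian kernel
as the defining form.

Combined uncertainty: err² = (ω-weighted variance of replica values)/n
+ mean(per-replica err²)/n. The first term (scatter) dominates when
replicas disagree, which is the empirically common regime at default
protocol settings; the second keeps single-estimator precision from
being discarded when replicas agree.

## Cycle decomposition

ΔΔG_obs/int/mem are plain differences of the per-environment ΔG values
(0→1 transformation free energy in each environment), so the additivity
identity ΔΔG_obs = ΔΔG_int + ΔΔG_mem is exact by construction. Errors
add in quadrature under independence across environments — each
environment is a separate simulation. The decomposition only propagates
forward; it never back-infers per-environment errors from edge-level
ones, which is an ill-posed inversion (printed benchmark uncertainties
are in fact not mutually consistent under any single quadrature
scheme).

## Overlap and convergence diagnostics

The overlap coefficient is the histogram intersection
Σ min(p_f, p_r⁻) of the forward and negated-reverse work histograms on
shared bins (Freedman–Diaconis width from the pooled sample, minimum 10
bins). A fitted-Gaussian overlap would be tighter for Gaussian data but
misleading for the multimodal work distributions slow degrees of
freedom produce; the histogram form is distribution-free, and the fixed
bin rule keeps it reproducible. For equal-variance Gaussian pairs it
converges to the analytic value 2Φ(−W_d/σ), which the tests check.
The convergence sweep subsamples the work sets without replacement at a
grid of sizes and reports the deviation of BAR from its full-sample
value, seeded for reproducibility.

## Network maximum likelihood

Minimizing Σ (ΔG_to − ΔG_from − ΔΔG)²/err² gives graph-Laplacian normal
equations solved per connected component with a pseudo-inverse; node
uncertainties are the square roots of the pseudo-inverse diagonal. Each
component carries one free constant: it is fixed by shifting the
component so its mean prediction over experimentally characterized
nodes equals their experimental mean (per component, because benchmark
maps are typically disconnected star maps and a single global shift is
ill-posed); components with no anchors stay mean-zero. Zero edge errors
would mean infinite weight, so they are replaced by the smallest
positive error in the network, with a logged warning.

K_i values convert as ΔG = −RT ln(K_i), kept sign-for-sign with the
benchmark source even though it yields positive ΔG for sub-molar K_i;
`convention="binding"` gives the conventional +RT ln(K_i), and pairwise
ΔΔG magnitudes are identical either way. Kendall τ is the tie-corrected
tau-b as implemented in scipy (exact p-values for small samples without
ties, asymptotic otherwise). Sign concordance treats an edge as correct
when predicted and experimental ΔΔG share a sign *or* the experimental
magnitude is within a near-zero band (default 0.4 kcal/mol — wide
enough that edges experimentally indistinguishable from zero cannot be
scored as failures).

The bundled benchmark (`p2y1_bptu_benchmark()`) is a twelve-edge,
two-star-map table for a purinergic GPCR antagonist series, transcribed
at printed precision. Its cycle-closure residuals are up to
0.10 kcal/mol — pure rounding, since values are printed at 0.01–0.1
kcal/mol resolution — so tests assert closure within 0.15 kcal/mol (the
sum of printed half-ulps) on transcribed data and 1e−9 on computed
decompositions. The benchmark's published absolute-ΔG comparison
against experiment is not reproducible from printed data alone (the
experimental absolute anchors are not tabulated), so the MLE is instead
validated by property tests: exact path-summation on trees, agreement
with an independent least-squares oracle on inconsistent cycles, and
gauge invariance of anchoring.

## Synthetic data

The simulator draws from the Gaussian family that satisfies the Crooks
fluctuation theorem exactly: W_f ~ N(ΔG + W_d, 2kT·W_d) and
W_r ~ N(−ΔG + W_d, 2kT·W_d). The variance–dissipation tie σ² = 2kT·W_d
is what makes the pair Crooks-consistent, giving every estimator a
known ground truth. The `mixture` shape draws each sample from one of
two such components (dissipations W_d and 2W_d, equal probability);
because both components share ΔG and the mixture weights match across
directions, the mixture is still exactly Crooks-consistent while being
visibly non-Gaussian — a stress test for the Gaussian estimator and the
histogram overlap. Defaults mirror the benchmark protocol: 50
transitions per direction, 3 replicas, 298.15 K, dissipation of order
1 kcal/mol. All randomness flows from one explicit integer seed
(spawned per environment × replica for study directories); there is no
global random state.

What the simulator does *not* emulate: correlated transitions spawned
from a finite production trajectory (samples are i.i.d.), slow
conformational degrees of freedom, λ-dependent Hamiltonian structure
below the work level, and anharmonic tails beyond the two-component
mixture. Passing recovery tests therefore demonstrates the correctness
of the estimators and plumbing under the stated statistical model, not
the adequacy of any particular MD sampling protocol.

## Problem sizes and determinism

Test and example workloads use 50–500 transitions per direction and
study directories of ~900 small trace files, the scale at which the
whole suite runs in seconds while leaving Monte-Carlo assertions
3-sigma headroom. Bootstrap resampling defaults to 1000 draws with seed
2024. Re-running any pipeline with identical inputs and configuration
reproduces byte-identical outputs.

## Known limitations

* No MBAR over multiple λ states, equilibrium TI, or Crooks-intersection
  estimator; no parsing of equilibrium multi-λ dhdl files.
* No replica outlier *rejection* — only downweighting.
* No cycle-closure correction at the edge level (network-level MLE is
  the consistency mechanism).
* No edge-selection / map-design functionality.
* BAR's asymptotic variance understates the error at very low overlap;
  the convergence sweep and bootstrap exist for exactly that regime.
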