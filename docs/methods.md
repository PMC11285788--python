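# Methods

## Model

The core is a deterministic ODE system for five bacterial genotypes
(S⁻, R⁻, S⁺, R⁺, C⁺; densities in cells/ml) and free phage V (pfu/ml),
with shared logistic crowding g = r(1 − N/K), N = S⁻+R⁻+S⁺+R⁺+C⁺:

- dS⁻/dt = (g(1−μ) − αV − m_b) S⁻
- dR⁻/dt = μ g S⁻ + (g(1−c_R) − m_b) R⁻
- dS⁺/dt = (g(1−μ) − αV − m_b) S⁺
- dR⁺/dt = μ g S⁺ + (g(1−c_R) − m_b) R⁺
- dC⁺/dt = αAV S⁺ + (g(1−c_I) − m_b) C⁺
- dV/dt  = (αB(S⁻ + S⁺(1−A)) − m_v − α(S⁺+S⁻+C⁺)) V

Assumptions worth making explicit:

- **Units.** Time is in hours and densities per ml throughout, matching the
  24 h culture window the experiment design uses; nothing in the equations
  fixes the units, so this is a documented convention.
- **Receptor mutants do not adsorb phage**; immune (C⁺) cells adsorb and
  destroy phage without lysis, which is why abundant C⁺ accelerates phage
  decline.  Spacer acquisition (probability A per infection) aborts the
  burst.
- **The (1−μ) factor applies only to division of sensitive cells**, exactly
  as the equations are written; R and C divisions do not mutate.
- **No double resistance** (surface mutant *and* spacer): the genotype is
  rarely observed and confers no additional protection.
- **Deterministic, no latency**: bursts are instantaneous and there is no
  stochastic (birth–death) variant.
- One caveat of the equations as written: above carrying capacity (N > K)
  the crowding factor is negative, so with μ > 0 the "mutation influx"
  term μg S into an empty R compartment is negative.  All analyses stay in
  the N ≤ K regime, where every compartment flux is outgoing-free at zero.

Derived statistics are always recomputed from state, never stored: the
CRISPR⁺ frequency N⁺, the protected-fraction contrast f_Δ (undefined — a
raised error, not a silent 0/NaN — when either subpopulation is empty, since
a silent default could flip a sign analysis), and the selection coefficient
αVf_Δ.  In the cost- and mutation-free limit (c_R=c_I=μ=A=0) the system
collapses to dN⁺/dt = αV f_Δ N⁺(1−N⁺); the package checks this numerically
by driving the reduced equation with V(t), f_Δ(t) interpolated from a full
run (agreement ~4×10⁻⁷ relative over 24 h at default tolerances).

### Default parameters

r=0.5 h⁻¹, K=10⁹ cells/ml, α=10⁻⁹ ml/h, B=100, c_R=0.05, c_I=0, μ=A=0,
m_b=m_v=0, with N(0)=10⁶ cells/ml and V(0)=10⁴ pfu/ml — the illustrative
scenario of the source model, also used as the experimental condition
(phage dose 10⁴ pfu/ml, 1:100 inoculum of a saturated culture ≈ 10⁶
cells/ml).  The illustrative initial mix sets 50% CRISPR⁺ with protected
fractions 0.30 (carriers, split half R⁺/half C⁺) versus 0.15
(non-carriers), i.e. f_Δ(0)=+0.15; the mirrored mix gives −0.15.  These
within-subpopulation fractions are documented illustrative defaults — the
qualitative behaviours (sign of change, fixation, plateau), not particular
curves, are the validated surface.

### Numerics

LSODA (stiff-capable, adaptive) with rel_tol 10⁻⁸ and abs_tol 10⁻²
cells/ml; the phage burst makes the system moderately stiff once the
epidemic peaks (V overshoots to ~6×10⁹/ml before collapsing).  Negative
excursions of order abs_tol occur as compartments crash; integration uses
the raw state (clipping inside the RHS would change the dynamics) and
output is clipped to zero.  Outcome classification uses a 10⁻⁶ dead-band on
ΔN⁺ — below plausible solver noise, so "no change" is never an artefact of
tolerance.  Sensitive collapse is declared below 1 cell/ml (less than one
cell per experimental volume).  A fixed-step forward-Euler integrator
(dt=10⁻⁴ h) serves as a brute-force cross-check; its own truncation error
at that step is ~3×10⁻⁴ in the phage component (first order in dt), so the
adaptive solution is compared to it at 10⁻⁴ on the bacterial state and N⁺
and at 10⁻³ on V.

## Horizontal transfer extension

Transfer of the CRISPR locus follows mass-action conjugation kinetics:
every CRISPR⁺ cell is a donor, rate constant γ (ml/h).  Recipients keep
their surface phenotype (R⁻→R⁺, S⁻→S⁺), except that an S⁻ recipient
becomes immune (C⁺) with probability `spacer_transfer_fraction` × C⁺/D —
spacer co-transfer weighted by the immune share of the donor pool D.
Transfer relabels cells, so N is conserved exactly.  The contribution to
df_Δ/dt along the transfer-only flux reduces analytically to

γ [ S⁻(q·C⁺ − (R⁺+C⁺)) + R⁻S⁺ ] / D,   q = spacer_transfer_fraction,

so with q=0 the sign is governed by the contrast R⁻/S⁻ vs (R⁺+C⁺)/S⁺.
That sign is *not* negative for arbitrary rare-resistance states; it is
negative in the early-epidemic regime the qualitative claim describes,
where receptor mutants arise at the same per-capita rate in both genetic
backgrounds (mutation pressure μ is background-independent) and spacer
acquisition adds protected cells only on the CRISPR⁺ side.  The random
ensemble used for validation encodes exactly that regime: a shared mutant
fraction on both sides (log-uniform, ≤2.5×10⁻⁴) plus a CRISPR-specific
immune fraction, total resistance < 10⁻³.  Under it the transfer flux is
non-positive in every draw.  The flux is validated against a
central-difference transfer-only step (δt=10⁻⁶ h); the difference quotient
has a roundoff floor near 10⁻¹³/h, so relative agreement (10⁻⁴) is
measured against max(|oracle|, 10⁻⁹/h).  Where transfer kinetics differ
(e.g. transduction-like), `hgt_flux` is the single swap point.

## Synthetic competition experiment

The generator emulates the 24 h strain-competition design: six initial
mixes crossing the sign of f_Δ(0) with the immune:resistant ratio within
the protected CRISPR⁺ pool, six replicates, paired ±phage arms (10⁴ pfu/ml
or none), genotype compositions read at 0 h and 24 h.

- **Design defaults.** Protected fractions 0.45/0.15 (so |f_Δ(0)| = 0.3),
  C⁺:R⁺ ∈ {4:1, 1:1, 1:4}, initial CRISPR⁺ frequency 0.5.  The real
  study's mix fractions are published only graphically, so these are
  design choices of comparable magnitude; all are configurable and every
  validation claim is property-based (signs, orderings, recovery rates),
  never curve-matching.
- **Replicate jitter**: each replicate's true initial mix is a
  logistic-normal perturbation (σ=0.05 per genotype, renormalised) of the
  designed mix, emulating pipetting variation; the two arms of a replicate
  share one jittered mix and one measured t0 composition, as they share an
  inoculum.
- **Measurement noise**: observed compositions are Dirichlet resamples of
  the truth with concentration κ×truth, κ=200 — compositional noise with
  sd ≈ √(p(1−p)/κ) ≈ 0.03 at p=0.5, the scale of qPCR frequency
  estimates.  This is deliberately simpler than modelling amplification
  curves; it does not reproduce qPCR-specific artefacts (primer-efficiency
  bias, correlated triplicate error, detection floors), so passing
  recovery tests show robustness to compositional noise of this magnitude,
  not to every real assay pathology.  Phage-contaminated no-phage vials
  are not simulated.
- The response variable is (N⁺ with phage − N⁺ without)/N⁺ without at
  24 h, computed from observed compositions; pairing is by
  (condition, replicate).

All randomness flows through one `numpy` Generator (seed or spawned
substreams), so datasets are byte-identical under a fixed seed.

## Inference

- **Baseline drift tests.**  Without phage the frequency response is zero
  only in the cost-free model; with c_R > c_I the CRISPR⁺ frequency drifts
  according to each subpopulation's mean cost burden.  Expected one-tailed
  directions are therefore *derived from the design and costs*
  (`expected_baseline_directions`) rather than hard-coded; per-condition
  one-sample t-tests are combined with a hand-implemented
  Benjamini–Hochberg step-up adjustment (cross-checked against
  statsmodels).  An identically-zero sample is reported as t=0, one-tailed
  p=0.5; a zero-variance nonzero sample is an error.
- **Response model.**  OLS of the response on f_Δ(0), the immune fraction
  C⁺/(C⁺+R⁺), and the initial CRISPR⁺ frequency (all measured at t0, as in
  the real assay), computed directly by QR decomposition with classical
  SEs, adjusted R² and the overall F-test; rank-deficient designs fail
  naming the collinear columns.  The immune *fraction* is the default
  encoding because the raw ratio C⁺/R⁺ is unbounded as R⁺→0; the ratio is
  also exposed.  Whether the initial CRISPR⁺ frequency belongs in the
  fitted model is genuinely ambiguous in this design; it is included by
  default (its coefficient is the direct test of
  frequency-independence) and can be dropped by passing a different
  predictor tuple.
- **Bootstrap.**  Nonparametric case resampling of replicates, percentile
  intervals, 10 000 draws by default (1 000 in the 200-dataset recovery
  study, a problem-size choice that keeps the full study at a few
  minutes); rank-deficient resamples are redrawn and counted.
- **Validation.**  Per-replicate sign agreement between the measured
  response and the model prediction started from the *observed* t0 mix,
  with the same 10⁻⁶ dead-band.

## Validation study sizes

The acceptance script and validation tests use: 241-point reporting grids
over 24 h (1001 over 100 h for fixation), 100 random mixes for the sign
law (Dirichlet-uniform, resampled under |f_Δ(0)| < 10⁻³ to stay clear of
the measure-zero neutral boundary), 100 ensemble states for the HGT sign
law, and 200 synthetic datasets (6 conditions × 6 replicates, κ=200,
1 000 bootstrap draws each) for effect recovery.

## Known limitations

- Deterministic dynamics: no establishment/extinction stochasticity, so
  the frequency-independence result speaks to short-term direction of
  selection, not to fixation probability of rare carriers.
- Single phage, single spacer class; no coevolution (protospacer escape),
  no latency, no explicit resource dynamics beyond logistic crowding.
- The HGT layer models conjugation-like transfer only; transduction and
  plasmid loss are out of scope.
- The noise model is compositional only; absolute abundances
  (total cells, phage titre) are recorded noise-free.
- Printed statistics from the real deposited dataset depend on that
  dataset and its exact design coding and are not reproduced here; the
  loader accepts tables of the same shape for re-analysis.
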