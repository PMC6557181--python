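# Methods

`reflift` recovers the non-solvent scattering-length-density (SLD) profile
ρ(z) and the hydration (solvent volume fraction) profile h(z) of an
interfacial film from specular neutron reflectivity curves measured at
several solvent contrasts, without assuming a layer model.  The pipeline has
two stages: an indirect Fourier transform (IFT) that fixes the overall film
extension D, followed by a simulated-annealing search for the two profiles.

## Interfacial model

The film of extension D between semi-infinite fronting (solid or air, SLD
ρ₀) and backing (solvent, SLD ρ_solvent) media is split into N = 50 equally
thick sub-layers (d = D/N), each carrying a non-solvent SLD ρₙ and a
hydration hₙ ∈ [0, 1].  Two virtual boundary layers impose h₀ = 0 and
h_{N+1} = 1: hydration vanishes at the fronting wall and reaches pure
solvent beyond the film.  Both step profiles are smoothed with a Gaussian
error function of a single global width σ,

    ρ(z) = ρ₀ + Σₙ (ρ_{n+1} − ρₙ) · ½[1 + erf((z − n·d)/(√2 σ))],

and likewise for h(z).  The composite SLD seen by the neutrons is
ρ′(z) = ρ(z)[1 − h(z)] + h(z)·ρ_solvent.  σ is bounded by the spatial
resolution implied by the measured q-range, π/(4 q_max) ≤ σ ≤ π/(2 q_max)
(≈ 3.1–6.3 Å at q_max = 0.25 Å⁻¹).

Two conventions were genuinely open:

* **Backing plateau of ρ(z).**  The non-solvent profile keeps its last
  sub-layer value ρ_N as the backing plateau; the hydration boundary
  condition alone carries the transition to pure solvent.  The alternative
  (stepping ρ(z) to ρ_solvent at z = D) makes the composite transition at D
  the product of two smeared steps — a spurious ~10⁻⁶ Å⁻² hump — and makes
  the "non-solvent" profile depend on the contrast, contradicting the
  model's central assumption.  With the chosen convention an erf-smoothed
  slab stack reproduces the Névot–Croce reflectivity of the same stack to
  ~1% RMS in log R over the full q-range.
* **One σ for both profiles**, applied at every sub-layer boundary; the
  smoothing represents instrument-scale resolution, not a per-interface
  physical roughness.

## Reflectivity engine

Exact specular reflectivity of the discretized profile by the Abelès 2×2
characteristic-matrix product, with Fresnel coefficients
r = (kₙ − k_{n+1})/(kₙ + k_{n+1}) and kₙ = [q²/4 − 4π(ρ′ − ρ₀)]^{1/2}
(principal branch, decaying evanescent waves).  The sign convention is
regression-tested against closed-form Fresnel and single-slab formulas to
10⁻¹⁰ relative.  For synthetic ground-truth generation the Fresnel
coefficients are damped by the Névot–Croce factor exp(−2 kₙ k_{n+1} σ_r²).

The composite profile is sampled at sub-layer centres, extended by ⌈3σ_max⌉
whole sub-layers beyond [0, D] so the smeared tails are captured.

Instrumental resolution is a Gaussian of FWHM (δq/q)·q applied as a 17-point
weighted average spanning ±2.5 standard deviations (weight tail < 10⁻³).
Inside the fitting loop the reflectivity is evaluated exactly on a
log-spaced fine grid (≥ 260 points, ≥ 8 points per Kiessig fringe of the
padded stack) and the 17 offsets are read off by cubic interpolation in
(ln q, ln R), clamped to the local stencil range so the cubic's negative
lobes cannot amplify the floored logarithm at exact reflectivity nulls.
One feature defeats any practical interpolation grid: a total-reflection
critical edge is a square-root cusp in R(q), and the q⁴ weighting of the
score amplifies errors there roughly two orders of magnitude (q⁴R peaks at
the edge).  Data points whose resolution window touches a cusp — detected
as a near-unity reflectivity plateau in the data — are therefore evaluated
exactly at every Gaussian offset.  This matters scientifically, not just
numerically: the edge region encodes the absolute composite-SLD levels
that break the (ρ, h) decomposition degeneracy, and with interpolation
error left in place the search converges to a visibly wrong hydration for
the solvent-penetrated layer.  Away from the edge the interpolated path
agrees with the exact computation to ≲ 0.1% in log R.  Synthetic data
generation, by contrast, always evaluates every offset exactly, so
round-trip tests compare two independent numerical paths.

## Score function

Agreement with the M_c contrast curves is measured per contrast by the mean
squared difference of the q⁴-weighted reflectivities normalised by the mean
of the q⁴-weighted experimental curve, plus the mean squared difference of
the logarithms:

    f = (1/M_c) Σ_c { ⟨[(q⁴R_exp − q⁴R_th)/⟨q⁴R_exp⟩_c]²⟩ + ⟨(ln R_exp − ln R_th)²⟩ }

The q⁴ term emphasises the high-q structure; the log term keeps the
low-reflectivity decades in play, so the whole q range is handled evenly.
Both terms are dimensionless and commensurate.  Points with non-positive
reflectivity (possible after background subtraction) cannot enter the log
term and are dropped at load time with a logged count.

## Simulated annealing

From a random start (ρₙ ~ U[ρ_min, ρ_max], hₙ ~ U[0,1], σ = π/4q_max), each
run has two stages.

*Cooling* — each trial redraws exactly one randomly chosen free parameter
uniformly over its whole admissible interval (pure exploration; no step
size to tune).  A trial is accepted when Δf ≤ 0, otherwise with probability
exp(−Δf/T).  The full schedule is T₀ = 1, 100·N trials per temperature,
T′ = 0.9 T, stopping after 100 consecutive rejections (a single global
counter across temperature decrements) or when T falls below a freeze-out
floor.  In the move mix every free parameter is equally likely except that
the single global σ counts ten-fold (a ~9% draw rate; at the naive
1/(2N+1) ≈ 1% rate runs freeze into wrong-smoothing basins because σ
couples to every layer).  The mix is configurable.  When the reduced-model
factor divides N (default: 25 sub-layers against the final 50), the
cooling searches the half-resolution model — half the dimensions makes the
basin search far more reliable at a fixed trial budget, and the coarse
layer width stays below the smoothing length, so no representable
structure is lost; the frozen coarse profile is replicated onto the full
grid before polishing.  A schedule may run several independent cooling
attempts and keep the best frozen state; the second attempt starts σ
mid-range rather than at its lower bound, which defuses the most common
trap (σ frozen at its spec'd starting value).

*Quench* — full-interval redraws cannot do coordinated fine refinement:
with them alone both schedules stall around f ~ 10⁻³ with visibly biased
profiles.  After freeze-out a greedy (T = 0) polish therefore continues
from the best state with a cascade of local uniform steps of shrinking
half-width (10%, 3%, 1% of each parameter's interval, 80% of trials; the
remainder stay full-interval redraws), each stage ending after a fixed
number of consecutive rejections.  The cascade descends one to two orders
of magnitude in f.  A run still above f = 10⁻² after a stage is frozen in
a structurally wrong basin that refinement cannot rescue and skips the
remaining stages; the multi-run selection discards it anyway.

The cooling stage evaluates the profile on coarse (one slice per
sub-layer) sampling, the quench on the accurate doubled sampling; both
always include the exact critical-edge evaluation, which steers the search
into the correct decomposition basin.

*Canonicalization* — the model admits an exact translation symmetry: a
leading film region that is dry and at the substrate SLD is optically
indistinguishable from the substrate in every solvent contrast, so the
whole structure can sit anywhere within the slack that D allows without
changing a single curve.  Deep-quenched runs regularly return such shifted
representatives (the smeared profiles, not individual sub-layers, are what
must match the substrate — large σ lets wiggly parameters average to an
invisible region).  After the quench, any leading invisible region is
removed, the profile is re-relaxed, and the flush-to-the-wall
representative is reported.  Constrained runs are left as found, since
constraints anchor absolute positions.  This is a reporting convention
inside an exact symmetry family, not a change to the fit; it is excluded
from the search trace.

The near-mirror ambiguity of the kinematic limit (a depth-reversed profile
has the same |FT|²) shows up as a recognisable family of trapped runs with
hydration on the wrong side; unlike the translation family it is broken by
the dynamical edge region, so mirrored runs score visibly worse (f ~ 10⁻²)
and are discarded by the multi-run selection rather than repaired.

The `fast` schedule (10·N trials per temperature, cooling 0.85, freeze-out
at T = 3×10⁻⁵) runs in ~1.5 min per run; the full schedule takes on the
order of 15 minutes per run on one core.  Individual runs are not
guaranteed to land in the global basin — a fraction freeze into a
recognisable wrong-σ trap with f ~ 10⁻¹ — which is exactly why ten
independent runs are performed and the best is kept; the score gap between
the global basin (f ~ 10⁻⁴) and the traps (f ~ 10⁻¹) makes the selection
unambiguous.  Default SLD bounds are the H₂O and D₂O values (−0.56 and
6.35 ×10⁻⁶ Å⁻²), the natural limits for non-deuterated aqueous systems.

Constraints freeze the hydration or the non-solvent SLD of every sub-layer
whose centre falls in a given z-range (e.g. the native ~10 Å SiO₂ layer on
silicon: h = 0 and ρ = 3.5×10⁻⁶ Å⁻²); frozen parameters leave the move set.

Ten independent runs are performed and the lowest-f model is the solution.
Runs within 20% of the best f (the qualifying threshold is configurable)
are averaged pointwise, which damps the high-frequency ripple caused by the
finite q-range and yields a pointwise spread estimate.

## Extension estimate by IFT

In the Born approximation the q⁴-weighted reflectivity is a cosine
transform of p(z), the autocorrelation of dρ′/dz:

    q⁴R(q)/16π² = 2 ∫₀^D p(z) cos(qz) dz.

p(z) is expanded in 25 clamped uniform cubic b-splines on [0, D] and fitted
to q⁴R by weighted least squares with a smoothness penalty
N_c = Σ(c_{i+1} − c_i)² times a Lagrangian multiplier Λ (a second-difference
penalty is available).  The fit excludes the near-total-reflection region
(q < 3×the strongest critical edge, and R > 0.2) where the Born
approximation fails; weights come from dR, defaulting to 3% relative.
p(z) is not constrained to positivity — it is the autocorrelation of a
signed derivative and may oscillate.

Within the measured band the basis is strongly degenerate (a band of width
Δq carries only ~DΔq/2π independent oscillation periods), so the choice of
Λ decides everything.  Two selectors are provided:

* `select_lambda` — the classical point-of-inflection reading of the
  stability plot (log N_c and χ² versus log Λ): the inflection of log N_c
  inside the region where χ² stays within 10% of its left-plateau value,
  with a flagged plateau-midpoint fallback for featureless scans.
* `discrepancy_lambda` — the largest Λ whose per-point χ² stays below
  max(1, 2×floor).  χ²(Λ) is monotone, so this is deterministic and varies
  smoothly across trial D values; it is what `estimate_D` uses internally,
  because the curvature-based inflection can lock onto different features
  for neighbouring trial D and randomise the p(z) diagnostics.

`estimate_D` runs trial IFT fits over a D grid (separately per contrast; in
practice the two most extreme solvent contrasts).  Underestimated D shows a
poor fit and an oscillating p(z); once D comfortably covers the structure,
the fitted p approaches the z axis and stays on it, so its amplitude
support (largest z where |p| ≥ 2% of the peak) stabilises.  The per-curve
estimate is the median support over acceptable trials whose window covers
that support by at least half a resolution length 2π/q_max, snapped **up**
to the next grid value (D must cover the support).  A contrast whose χ²
cannot reject any trial D — e.g. a heavily roughness-damped curve that fits
within errors even at badly truncated D — carries no extension information
and is excluded; the final estimate is the largest per-curve value among
informative curves.  The full per-trial diagnostic table (χ², tail RMS,
p(D), support, oscillation count, acceptability) is returned for audit.

On the regenerated validation systems this yields D = 170 Å for the
three-layer stack (true extent 150 Å plus roughness tails — the 2%
amplitude support of the true autocorrelation ends at ≈ 170 Å) and
D = 500 Å for the parabolic nanoparticle layer.

## Synthetic validation systems

* **Three-layer stack on Si**: 3 × 50 Å, 5 Å roughness everywhere,
  non-solvent SLDs (5, 0, 2)×10⁻⁶ Å⁻², third layer 50% hydrated; contrasts
  D₂O (6.35), SMW (2.07, silicon-matched) and H₂O (−0.56 ×10⁻⁶ Å⁻²).
* **Parabolic nanoparticle layer**: close-packed 250 Å-radius silica
  spheres (SLD 3.5×10⁻⁶ Å⁻²); volume fraction
  φ(z) = φ_max[1 − (z−R)²/R²] on [0, 2R] with φ_max = 0.9069 (the 2-D
  hexagonal close-packing cross-section at the equator; the extension
  estimate is insensitive to this choice), discretized to 20 slabs with
  10 Å Névot–Croce roughness.

Rendering conventions: 150 log-spaced q points from 0.005 to 0.25 Å⁻¹
(mimicking a two-wavelength reflectometer), δq/q = 10%, points kept down to
R = 10⁻⁶ (the usual background limit — this carves the visible gap in the
SMW curve) and up to q = 0.25 Å⁻¹.  The default validation curves are
noise-free; optional multiplicative Gaussian noise (3% relative is the
default for stochastic tests) adds a dR column floored at 10⁻⁷.

What the generator does *not* emulate: counting statistics with realistic
q-dependence, background, imperfect footprint correction, labile-hydrogen
exchange (a contrast-dependent non-solvent SLD), absorption, or
off-specular scattering.  Passing the round-trip tests therefore shows the
estimator chain is self-consistent and robust to the truncation and
smearing of real instruments, not that these instrumental effects are
handled.

## Numerical choices

* Complex square root: principal branch, Im k ≥ 0 (decaying evanescent
  waves).  Matrix product ordered from fronting to backing; conventions
  regression-tested against the closed forms.
* erf tails truncated beyond 6 standard deviations (weight < 10⁻¹²).
* Equal-score trials are accepted (Δf = 0 ⇒ acceptance probability 1);
  a non-finite score aborts the run with its trace.
* Λ grids are log-spaced relative to the self-normalising scale
  χ²(0)/N_c(0); stability scans use 40 points over 8 decades, the
  discrepancy search 65 points over 16.
* Normal equations solved directly; a singular system falls back to
  least squares with the condition number logged.
* Annealing is bitwise reproducible given a seed; multi-run seeds are
  `base..base+9` unless given explicitly.

## Validation problem sizes

The shipped validation suite runs the full three-layer and nanoparticle
analyses at their published sizes (N = 50, 150-point curves, 10 annealing
runs, D grids 80–300 Å step 10 and 300–700 Å step 20).  The annealing runs
use the `fast` schedule; the full schedule gives the same structural
answer and can be selected with `--full-schedule` in the acceptance script
or `reflift fit` without `--fast`.  Unit tests exercise the annealing
machinery on a reduced model (N = 16, 60-point curves) where a run takes
about a second.

## Known limitations

* Individual annealing runs are not reliable: under the reduced schedule
  roughly half freeze into recognisable traps (wrong-smoothing or
  near-mirror families, or the shallow wrong-decomposition family at
  f ~ 5×10⁻⁴ whose composite profile deviates visibly from the truth).
  The method's guarantees attach to the best of ten runs, whose score
  separates cleanly from the trapped families; treat any single-run result
  as provisional.

* A single contrast-independent non-solvent SLD: labile-hydrogen exchange
  biases hydration upward for protein-like layers (the per-contrast SLD
  constraint that would address this is out of scope).
* No magnetic or absorbing (imaginary) SLD.
* The multi-run spread is a reproducibility estimate, not a posterior
  uncertainty.
* Two solvent contrasts are generally not enough to pin both profiles;
  three is the practical minimum except for simple high-contrast systems.
* The IFT stage assumes the Born approximation outside the excluded
  low-q window; strongly reflecting films (R ≳ 0.2 over most of the range)
  leave too few points to fit.
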