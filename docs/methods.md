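# Methods

This note records the models and procedures implemented in `somsorb`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions taken where the design was open.

## Free energies from non-equilibrium work

A sorbate is decoupled from its surroundings by a coupling parameter λ:
λ = 0 is the fully interacting system, λ = 1 the non-interacting "dummy".
A finite-time switching run accumulates the work W = ∫₀¹ ⟨∂H/∂λ⟩ dλ.
Forward means *removing* (λ 0→1), reverse means *growing* (λ 1→0); reverse
works are negated internally so both distributions live on the ΔG axis.
This sign convention is fixed package-wide.

**Crooks Gaussian intersection (CGI).** The Crooks fluctuation relation
implies that the forward-work density and the negated-reverse-work density
cross exactly at ΔG. Both distributions are fitted as Gaussians by sample
moments (mean, n−1 standard deviation) — at the production budget of ~75
works per direction the difference from a maximum-likelihood fit is
negligible, and moments are testable in closed form. Equal spreads give the
midpoint of the means; unequal spreads give the root of the log-density
quadratic that lies between the means. Two diagnostic regimes are flagged
rather than failed:

- `poor_overlap` — the means differ by more than 4 pooled standard
  deviations; the crossing is then an extrapolation through barely
  overlapping tails and should not be trusted.
- `crossing_outside_means` — with nearly coincident means and unequal
  spreads both real crossings can sit marginally outside the interval
  between the means. The crossing nearest the midpoint is returned: it is
  the continuous limit of the between-means root as the distributions
  merge, and the regime arises routinely in bootstrap resamples at low
  dissipation where the estimate is in fact at its most accurate. Treating
  it as a failure would abort the bootstrap precisely where the data are
  best.
- A hard `EstimationError` is reserved for a negative discriminant, which
  cannot occur for genuine Gaussian fits and indicates corrupted input.

**Jarzynski.** ΔG = −RT ln⟨exp(−W/RT)⟩ for forward works, with the sign
reversed for reverse works. The exponential average runs through a shifted
log-sum-exp so large |W|/RT never overflows. The estimator obeys the Jensen
bound (forward estimate ≤ mean forward work) and is biased at finite n when
dissipation is large — which is why the bidirectional CGI is preferred at
high σ/RT, a comparison the convergence profile makes explicit.

**Bootstrap.** Each direction is resampled with replacement at its own
size — the resampling unit is the individual work value, with runs from
independent model replicas pooled into one distribution. The default is
1,000 resamples; the reported value is the mean and the uncertainty the
sample standard deviation of the resampled estimates. Fixed seeds give
bit-identical results.

**Convergence profiles** subsample each direction *without* replacement to
a fraction of the data before bootstrapping (subsampling with replacement
is available as an option; the default is documented here because either
convention is defensible and they differ only at second order). Fraction
1.0 reproduces the plain bootstrap on the full set.

## Thermodynamic integration

Equilibrium runs at 21 equally spaced λ points yield per-run ⟨∂H/∂λ⟩
curves; each run is integrated by the composite trapezoid and the TI
estimate is the mean of the per-run integrals. The uncertainty is the
standard error over the (default 5) runs — per-run integration followed by
averaging is identical to integrating the mean curve for the trapezoid
rule, but the run-level integrals are what define the spread. The standard
error (not the standard deviation) is reported because the quantity of
interest is the uncertainty of the mean. A single run is reported with
uncertainty 0 and a `single_run` flag.

## Thermodynamic cycles and experimental scales

ΔG_sorb = ΔG_vac − ΔG_env and ΔG_hyd = ΔG_vac − ΔG_water, errors in
quadrature. Experimental matrix/air partition coefficients map to free
energies as −RT ln K + c with c an unknown additive constant; c is never
estimated. All comparisons with experiment are restricted to statistics
invariant under a constant shift: Pearson correlation, OLS slope, and the
best-fitting slope-1 offset (mean(y − x)). Experimental series are anchored
so their maximum is 0 kJ/mol; the anchoring is applied to whatever set is
given — the embedded 18-compound table carries an anchored maximum of
−1.8 kJ/mol because its source anchored a larger compound set, and the
anchoring offset cancels from every reported statistic anyway.

Constants: R = 8.314 × 10⁻³ kJ mol⁻¹ K⁻¹, default T = 300 K, Coulomb
prefactor 138.9354 kJ mol⁻¹ nm e⁻². Report rounding is one decimal in
kJ/mol (two decimals for correlation coefficients); internal arithmetic is
never rounded.

## Structural descriptors

All lengths are nm; boxes are rectangular and periodic; distances use the
minimum-image convention, which requires r_max ≤ half the smallest box
edge.

**RDF.** Shell counts between two selections, self-pairs excluded,
normalized per frame by the ideal-gas expectation n_B/V and averaged over
frames. Default bin width 0.02 nm.

**Kirkwood–Buff integrals.** G = ∫₀ᴿ 4πr²(g−1) dr by trapezoid over bin
centers, with two boundary conventions fixed here: the r = 0 anchor takes
g = 0 (the excluded origin contributes −1 over its shell), and the last
bin's g is carried to its outer edge so a boundary at exactly r_max is
integrable. Starred (non-normalized) variants multiply by x_A·x_B and act
as contact numbers comparable across systems. Default boundaries 0.3, 0.4,
0.5 nm (local environment) and 1.5 nm (correlation volume).

**Preferential solvation.** δ_B = x_B(G_AB − Σ_α x_α G_Aα)/(V_corr + Σ_α
x_α G_Aα) with V_corr = (4/3)π(1.5 nm)³. Molar fractions are normalized
heavy-atom counts (any non-hydrogen site; united-atom CHn counts as one
carbon site) over the *solvating* species — the sorbate itself is excluded
from the normalization, a choice the formula leaves open. The reference
point for the sorbate–species RDFs is the sorbate's center of geometry,
computed after unwrapping the sorbate across the periodic boundary.
Positive δ_B means species B is enriched around the sorbate relative to
bulk composition.

**Hydrogen bonds.** Geometric criterion: H···A distance ≤ 0.25 nm and
D–H···A angle ≥ 135°, both boundaries inclusive, both distances under
minimum image. The angle is measured at the hydrogen between the H→D and
H→A directions (180° = linear); an alternative angle convention can be
expressed by constructing a different `HBondCriterion`.

**SASA.** Shrake–Rupley sphere sampling with a deterministic golden-spiral
point set (default 960 points), probe radius 0.14 nm. Hydrogens carry no
surface (united-atom convention); per-atom areas are attributed to the
carbon or heteroatom class and fractions are class area over total. The
radii table is supplied per particle through the annotation sidecar rather
than hard-coded, since the appropriate united-atom radii depend on the
force field in use.

**Pair interaction energies.** Sum over unique A–B pairs within a 1.4 nm
cutoff: Lennard-Jones C12/r¹² − C6/r⁶ with geometric-mean combination of
per-particle C6/C12, plus Coulomb with a reaction-field correction for a
homogeneous dielectric (ε_RF = 61) outside the cutoff sphere at zero ionic
strength. The engine-side triple-range pair list (0.8/1.4 nm) is a
simulation-efficiency device; analysis uses the single long-range cutoff,
which differs negligibly for interaction-energy bookkeeping.

## Property ledger

Pearson r, OLS slope/intercept, and the fixed-slope-1 offset per property
column against the sorption free-energy response. Strength classes (|r| ≥
0.7 strong, 0.4–0.7 moderate, else weak) are reporting conveniences only.
Constant columns are flagged `undefined` rather than fatal. No
multiple-testing correction is applied across the ledger: the correlations
are descriptive, not hypothesis tests.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *statistical structure* the estimators assume,
with stored ground truth:

- `crooks_gaussian_workset` draws forward works from N(ΔG + σ²/2RT, σ) and
  reverse works from N(−ΔG + σ²/2RT, σ) — the unique Gaussian pair with
  common σ satisfying the Crooks relation, so the planted ΔG is exactly the
  density crossing and the dissipated work is σ²/2RT on either side. A
  Student-t option provides a heavier-tailed stress test.
- `polynomial_lambda_curve` adds iid Gaussian noise to a polynomial in λ
  and stores the analytic integral.
- `ideal_gas_box` is the structureless null (g ≡ 1, G ≡ 0, δ ≡ 0 up to
  sampling noise); `clustered_mixture_box` splits the box into a water-rich
  and a matrix-rich half, with each species falling in its own half with
  probability (1+s)/(2+s) so that s = 0 recovers the uniform box, and
  plants the sorbate in a named patch — a geometric construction sufficient
  to plant the sign of δ, not an energetic model of demixing.
- `planted_hbond_frame` places ideal D–H···A triples (H···A 0.18–0.24 nm,
  angle 150–180°) and decoys violating exactly one criterion each, on a
  grid sparse enough (1.2 nm) that no cross-triple bond can form.

What passing tests on these inputs shows: the estimators, integrals,
counters and the correlation machinery are correct on data satisfying
their stated assumptions. What it does not show: anything about force-field
accuracy, sampling convergence of real matrix trajectories, non-Gaussian
work distributions from slow degrees of freedom, or the chemistry of real
humic substances. Absolute sorption free energies in the humic-acid matrix
require ~240 ns of sampling per sorbate and enter the analyses only through
the embedded 18-compound table of previously computed values.

## Problem sizes

The shipped analyses use 75 work values per direction (25 runs × 3 model
replicas, the production budget), 1,000 bootstrap resamples, 21-point λ
grids with 5 runs, boxes of ~2,000 particles with 5–20 frames per
condition, and 18-compound correlation sets. These are the study's own
operating conditions; the recovery tests are calibrated to them (3
bootstrap standard deviations for stochastic recovery, closed forms to
stated tolerances elsewhere).

## Known limitations

- CGI assumes near-Gaussian work distributions; strongly bimodal or
  heavy-tailed works (trapped starting configurations) violate the fit and
  are only partially covered by the Student-t stress test.
- The bootstrap treats work values as iid; correlations between runs
  started from the same equilibrated model are ignored (runs are pooled).
- KB integrals from binned RDFs inherit O(bin width²) quadrature error and
  the finite-range truncation at 1.5 nm; no long-range tail correction is
  applied.
- SASA point sampling has O(1/√n_points) area noise; 960 points keep the
  isolated-sphere error well under 1%.
- Only rectangular boxes are supported.
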