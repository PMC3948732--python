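# Methods

## The statistical model

The response is the per-section follicular density of a chosen maturity
class (primordial by default), transformed as `y = log10(D + c)`.  The
offset `c` (follicles/mm², default 1) is required because sparse cortex
regularly yields sections with zero follicles and `log10(0)` is undefined;
it is a configurable analysis choice recorded in all outputs, not a fitted
quantity.  On the transformed scale the nested model is

    y_ijkl = mu + ewe_i + ovary_j(i) [+ treatment] + f_k(ij) + e_l(ijk),

with ewes, ovaries-within-ewes and treatment as fixed factors, a random
intercept per cortical fragment, `f ~ N(0, sigma2_fragment)`, and an
independent section-level residual `e ~ N(0, sigma2_section)`.  Nesting is
realized through composite labels (`ewe/ovary/fragment`), so reused
fragment ids under different ovaries never alias.

**Estimation.** Variance components are estimated by REML.  The iterative
fit is delegated to statsmodels' `MixedLM` and then *polished* on an
explicit profile restricted log-likelihood written for the two-component
compound-symmetry structure (Woodbury identities per fragment block, so
unbalanced tables cost the same as balanced ones).  The polish step —
Nelder-Mead plus a dedicated search along the `sigma2_fragment = 0`
boundary — tightens the optimum to ~1e-8 relative and makes boundary
solutions deterministic.  Negative fragment-variance solutions are
truncated at 0 and flagged; the fragment SE is reported as NaN there
because the asymptotic normal approximation breaks down on the boundary.

**Standard errors** of the components come from the numeric Hessian of the
profile REML log-likelihood at the optimum (central differences, steps
`max(1e-6, 1e-4·theta)`, kept inside the feasible region).  Proportions of
variance are `100·component/total` with first-order delta-method SEs
treating the two component estimates as independent; because the two
proportions sum to 100% exactly, they necessarily share one standard
error.  Printed decompositions elsewhere that attach unequal ±values to
the two rows are using a different (non-symmetric) convention.

**Fixed-effect tests.** Joint contrasts are tested with F statistics from
the GLS fit at the estimated components.  The denominator degrees of
freedom use the containment rule: factors that are constant within
fragments (ewe, ovary, treatment — the usual case) are tested against
`n_fragments − rank(fragment-level fixed design)`.  For a balanced
two-group design with an untruncated fragment component this F test is
*algebraically identical* to the two-sample t-test on fragment means, and
therefore exact: its null rejection rate is alpha precisely, which a
large-sample Wald chi-square version (also reported, as `pvalue_chi2`)
visibly fails at 5–20 fragments.

**Independent oracle.** For balanced tables an expected-mean-squares
estimator is provided: `sigma2_section = MS_within`, `sigma2_fragment =
(MS_between − MS_within)/S` truncated at 0, pooled across
(ewe, ovary, group) cells by degrees of freedom.  On balanced data REML and
the moments estimator coincide (verified to 1e-6 relative in the tests);
the two code paths share nothing beyond the input table.

## The synthetic cortex

**Direct mode** draws `y` straight from the model above.  Defaults mirror
the reference study's structure: 4 ewes × 2 ovaries, 15 fragments per
ovary, 34 analyzed sections per fragment, components (0.116, 0.993) in
log10 units².  The grand mean defaults to 0.56 ≈ log10(1 + 2.6), a
plausible mid-range density level; all power results are invariant to it.
Each fragment draws from an independently spawned `SeedSequence` substream
of the global seed, so any fragment can be regenerated in isolation and
tables are bit-reproducible.

**Geometric mode** emulates the histology.  A fragment is a
2.5 × 2.5 × 1 mm box; follicle count is Poisson with mean
`intensity × volume` (a homogeneous spatial point process — the paperless
default for count law), centers uniform in the box, diameters uniform per
class (primordial 20–30 µm; primary 30–60 µm and secondary 60–120 µm as
field-typical choices), class mix 92/7/1% so secondary follicles stay
under 1% of the population.  The box is tiled into 5-µm half-open slabs
`[i·t, (i+1)·t)`; every sixth slab is "analyzed" (30 µm spacing).  A
follicle is counted on a slab iff its nucleus — a sphere of 10 µm unless
configured otherwise — overlaps the open slab interval.  Half-open slabs
remove boundary ties; a 10 µm nucleus is smaller than the 25 µm gap
between analyzed slabs, so the visible-nucleus rule provably counts each
follicle at most once, which the tests assert on 10,000 random follicles.
Cortical area per section defaults to the constant 6.25 mm² face area with
optional uniform ±jitter standing in for manual outlining of an irregular
cortex.

What geometric mode does *not* emulate: spatial clustering of follicles
(real cortex shows patches and bare regions; the Poisson field is
spatially homogeneous within a fragment), follicle growth/atresia,
staining or imaging artefacts, and annotation error.  Passing tests
therefore validate the counting and aggregation machinery and the
hierarchy of variances, not the spatial realism of follicle patterns; the
fragment-to-fragment component in geometric mode arises only through the
configured intensity, so quantitative variance calibration is done in
direct mode.

## The power engine

A design is (fragments per group `F`, sections per fragment `S`, effect,
alpha, number of simulations).  Each replicate simulates a balanced
two-group experiment (control + treated, single ewe and ovary — the
recommended single-ovary setup, so no ewe/ovary fixed effects) and tests
the treatment contrast at two-sided alpha = 0.05.

**Effect parameterization.** A "p% modification of follicular density"
defaults to a multiplicative change of density, i.e. an additive
`log10(1 + p/100)` shift of `y` (`multiplicative_log10`).  Because other
readings are possible and the mapping from percent effect to mean shift in
published power tables is generally not recoverable, an `absolute_shift`
variant (p/100 log10 units) and a `raw_delta` override are exposed, and
the parameterization is recorded in outputs.  Under the default reading,
published tables showing ≈100% power for a 50% effect at these variance
components are not reproducible — the analytic power of even the largest
grid design (20 × 40) is ~30% — so grid-level checks are property-based
(calibration, monotonicity, oracle agreement), not numeric table
comparisons.

**Per-replicate test.** For the default balanced design the mixed-model
containment F test of treatment collapses to the two-sample t-test on the
`2F` fragment means (see above); the engine uses that closed form directly
(`analysis="exact"`), making a 2000-replicate run take seconds.
`analysis="reml"` refits the full mixed model per replicate; a test
asserts the two routes give the same p-value to 1e-6 on sample
replicates.  Replicates whose analysis fails are excluded and counted;
more than 10% failures aborts the run as numerically unstable.

**Analytic oracle.** The treatment contrast has variance
`2V, V = sigma2_fragment/F + sigma2_section/(F·S)`.  The default
closed form is the exact noncentral-t power of the fragment-means test
with `2(F − 1)` degrees of freedom and noncentrality `delta/sqrt(2V)`;
the classic normal approximation
`Phi(z − z_crit) + Phi(−z − z_crit)` is available as `method="normal"`.
The exact form is the one the Monte-Carlo engine is compared against
(they estimate the same quantity; the normal version overstates power by
up to a few points at F = 5).

**Seeding.** Replicate seeds derive from `SeedSequence((master, rep))`;
grid rows derive per-design seeds from
`(master, effect, fragments, sections)`, so every grid row is reproducible
in isolation and independent of grid composition.  Binomial 95% intervals
on power use the Wilson score method.

**Design recommendation** evaluates candidate `(F, S)` pairs against a
target power (analytic by default, Monte-Carlo optionally) and returns the
qualifying design minimizing total sections per group `F·S`, ties broken
toward fewer fragments; `None` if nothing qualifies.  A consequence of the
fitted components worth knowing: once `S` exceeds
`sigma2_section/sigma2_fragment ≈ 8.6`, the fragment term dominates `V`
and additional fragments buy strictly more power than additional sections
— the tests assert this diminishing-returns property on the analytic
sweep.

## Numerical and interface choices

- Convergence: polish to ~1e-12 absolute on the REML criterion; the
  statsmodels fit supplies the starting point and a moments-style fallback
  start is used if it fails outright.
- Degenerate inputs: an all-constant response returns zero components,
  zero contrasts and p = 1 rather than failing; zero-variance generation
  (for deterministic smoke cases) is allowed even though real fits require
  positive residual variance to be meaningful.
- Observation tables are plain CSV with documented headers (see
  `folliclepower.io`); unknown columns survive round trips; validation
  errors name the column and row.
- The pipeline runner records the master seed, a sha256 hash of the
  resolved configuration and component versions in every run report, and
  is byte-reproducible for a fixed configuration.
- Problem sizes used by the bundled checks (300 recovery tables; 2000
  Monte-Carlo replicates per reported power; 500 per grid cell in the full
  27-design grid) were chosen to keep Monte-Carlo error a small fraction
  of the quantities examined while remaining comfortable on one CPU.

## Known limitations

- The moments estimator requires global balance (equal `S` everywhere);
  unbalanced tables must use the REML path.
- Containment degrees of freedom are exact for fragment-level factors in
  balanced designs but only approximate under strong imbalance
  (Satterthwaite/Kenward-Roger adjustments are not implemented).
- The analytic power oracle covers two groups; multi-group designs fall
  back to Monte-Carlo with a one-way F test on fragment means.
- Proportion-of-variance SEs assume independent, asymptotically normal
  component estimates; near the `sigma2_fragment = 0` boundary they are
  not trustworthy and the fragment SE is reported as NaN.
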