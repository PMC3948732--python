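# folliclepower

Design and analysis tools for follicle-density experiments on ovarian
cortex, where the natural heterogeneity of the primordial-follicle pool —
between animals, between the two ovaries of one animal, between cortical
fragments and, above all, between histological sections of the same
fragment — can easily swamp a real treatment effect.

The package is aimed at reproductive-medicine labs quantifying follicles in
serially sectioned cortical fragments (e.g. cryopreservation or xenograft
studies on the sheep model): it tells you **how many cortical fragments and
how many sections per fragment you must analyze** to detect a given change
in follicular density.

## The model

Per-section follicular density `D` (follicles/mm² of outlined cortical
surface) is log-transformed, `y = log10(D + c)` with a configurable offset
`c` (default 1 follicle/mm²), and modelled with a nested linear mixed
model:

```
y_ijkl = mu + ewe_i + ovary_j(i) [+ treatment] + f_k(ij) + e_l(ijk)

f ~ N(0, sigma2_fragment)      fragment random effect
e ~ N(0, sigma2_section)       section-level residual
```

Fitting (REML) decomposes the total variance into a fragment component and
a section component; in the eight-ovary sheep reference dataset bundled
with the package these are 0.116 and 0.993 (log10 units²), i.e. ~10.5% and
~89.5% of the total — sections within a fragment, not fragments, dominate
the noise.

A Monte-Carlo engine then simulates balanced two-group experiments from
this model, refits the treatment contrast per replicate, and estimates the
power of any (fragments × sections) design; a closed-form noncentral-*t*
oracle gives the same answer analytically, because the balanced-design
treatment test reduces exactly to a two-sample *t*-test on fragment means
with `2(F − 1)` degrees of freedom.

A geometric simulator complements the direct model: it scatters follicles
(Poisson, 20–30 µm diameters for primordial follicles) in a 2.5 × 2.5 × 1 mm
fragment, cuts 5-µm serial sections, analyzes every sixth (30 µm apart),
and counts a follicle only on sections where its ~10 µm nucleus is visible —
verifying that the sampling scheme never counts a follicle twice.

## Worked example

```python
import folliclepower as fp

# simulate one ovary's worth of data: 20 fragments x 40 analyzed sections
params = fp.HierarchyParams(n_ewes=1, ovaries_per_ewe=1, fragments_per_ovary=20,
                            sections_per_fragment=40, seed=42)
table = fp.generate_density_table(params)

# recover the variance components
fit = fp.fit_mixed_model(table, fp.ModelSpec(fixed_factors=()))
pf, ps = fp.variance_proportions(fit.vc)
print(f"sigma2_fragment = {fit.vc.sigma2_fragment:.3f} (SE {fit.vc.se_fragment:.3f})")
print(f"sigma2_section  = {fit.vc.sigma2_section:.3f} (SE {fit.vc.se_section:.3f})")
print(f"proportions     = {pf:.2f}% fragment, {ps:.2f}% section")

# power of a 10-fragments x 20-sections design against a 25% density change
design = fp.DesignSpec(n_fragments=10, n_sections=20, effect_pct=25.0,
                       n_sims=2000, seed=0)
result = fp.run_power(design)
print(f"MC power        = {result.power:.3f} (95% CI {result.ci_low:.3f}-{result.ci_high:.3f})")
print(f"analytic power  = {fp.analytic_power(design):.3f}")
```

prints

```
sigma2_fragment = 0.123 (SE 0.048)
sigma2_section  = 0.996 (SE 0.050)
proportions     = 10.98% fragment, 89.02% section
MC power        = 0.080 (95% CI 0.069-0.093)
analytic power  = 0.080
```

The fitted components recover the simulation truth (0.116 / 0.993) within
sampling error, and the Monte-Carlo and analytic powers agree.  Under the
`multiplicative_log10` reading of a 25% effect (an additive `log10(1.25) ≈
0.097` shift of the transformed density), 200 sections per group buy only
~8% power — which is why the effect parameterization is explicit and a raw
log10 shift can be supplied instead:

```python
best = fp.recommend_design(0.8, 25.0,
                           [(5,10),(5,40),(10,20),(10,40),(20,20),(20,40)],
                           raw_delta=0.4)
print(best.n_fragments, best.n_sections)   # -> 20 20   (analytic power 0.857)
```

The same functionality is available from the shell:

```bash
folliclepower power --effect 25 --fragments 10 --sections 20 --nsims 2000 --seed 0
folliclepower pipeline --config config.yaml --out-dir run/
```

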