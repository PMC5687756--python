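# oystervid

Statistical toolkit for **towed-video surveys of the European flat oyster
(*Ostrea edulis*)** — and, more generally, for any imagery-based benthic
survey in which a camera sled is towed along transects, the footage is
scored by several observers, and the resulting counts must be turned into
defensible abundance estimates with known precision.

It is written for marine ecologists and monitoring programme designers who
need to answer three questions:

1. **How well does video scoring agree with ground truth?** Individually
   matched oysters with a field-determined and a video-determined live/dead
   status are cross-tabulated into a confusion matrix, summarised by the
   correct classification rate, sensitivity, specificity and Cohen's kappa;
   section-level counts are compared through recovery rates, correlation and
   error profiles.
2. **Where does the uncertainty come from?** Reading-level counts are fitted
   with a nested mixed linear model — Site fixed; Observer, Transect(Site)
   and Section(Transect, Site) random, with observer-by-space interactions
   and a residual that measures repeat readings by the same observer:

   ```
   y = μ + Si + Tr(Si) + Se(Tr,Si) + Ob + Ob×Si + Tr(Si)×Ob + Se(Tr,Si)×Ob + e
   ```

   The package builds the nested ANOVA table, derives expected mean squares
   by the Cornfield–Tukey algorithm (restricted or unrestricted convention),
   forms F-tests (quasi-F with Satterthwaite df where needed) and estimates
   the variance components σ²_Ob, σ²_Tr, σ²_Se, the interactions and σ²_e by
   method of moments and by REML.
3. **How should a monitoring programme be dimensioned?** The fitted
   components are propagated into the variance of a survey mean over `a`
   transects, `b` sections per transect, `c` observers and `n` readings:

   ```
   V[ȳ] = σ²_Tr/a + σ²_Se/(a·b) + σ²_Ob/c + σ²_e/(a·b·c·n)
   ```

   from which the package produces SE-versus-area curves, scenario grids,
   per-m² conversions and a required-area solver.

A hierarchical simulator closes the loop: it generates synthetic surveys
either from the Gaussian mixed model itself (for estimator validation) or
mechanistically — individual oysters placed in sections and then detected
and classified imperfectly per observer and reading — so every stage is
testable without access to field data. The bundled reference configuration
reproduces the validation study's layout: 3 sites with 5, 3 and 5 transects,
five 4 m × 0.8 m (3.2 m²) sections per 20 m transect, 2 observers and 2
readings per observer.

## Worked example

```python
import oystervid as ov

design = ov.reference_design()                      # 3 sites; 5,3,5 transects; ...
cfg = ov.reference_generator_config(seed=7)         # study-emulation preset
truth = ov.generate_field_truth(design, cfg)
readings, oysters = ov.generate_video_observations(truth, design, cfg)

print(ov.compute_metrics(ov.build_confusion(oysters)).report())

res = ov.NestedSurveyModel(readings).fit()          # ANOVA + EMS + REML
print(res.summary())

pm = res.precision_model()
print(f"SE at ~10 m2: {pm.se_per_m2((1, 3, 1, 1)):.2f} oysters/m2")
area, q = pm.required_area(target_se_per_m2=0.5)
print(f"area for SE <= 0.5 /m2: {area:.0f} m2 (a={q.a}, b={q.b})")
```

prints

```
statistic               value
ccr                     0.82
sensitivity             0.81
specificity             0.83
kappa                   0.63
false_negative_share    11%
false_positive_share    6%
Nested mixed-model analysis of video survey counts
method: reml  (REML loglike -499.282)
EMS convention: restricted  [coefficients approximate: unbalanced transects]

Source             df        MS       p      VC
Ob                  1       0.2    0.66     0.0
Si                  2      49.9    0.18       -
Tr(Si)             10      22.5    0.59     0.0
Se(Tr,Si)          52      27.0    0.00     6.2
Ob*Si               2       3.3    0.07     0.0
Tr(Si)*Ob          10       0.9    0.69     0.0
Se(Tr,Si)*Ob       52       1.2    0.66     0.0
Residual          130       1.4       -     1.3

total random variability: 7.6 (counts/section)^2; largest component s_se2 = 82%
SE at ~10 m2: 0.50 oysters/m2
area for SE <= 0.5 /m2: 10 m2 (a=1, b=3)
```

The classification block says the simulated video observer calls live/dead
correctly 82% of the time with balanced error types (kappa 0.63, substantial
agreement). The ANOVA table shows the video counts' df bookkeeping for the
reference layout (65 sections × 2 observers × 2 readings = 260 readings)
and that nearly all random variability sits between sections within
transects — spatial patchiness, not observer error — which is why the
precision solver then tells you that sampled area, not repeated readings,
buys precision.

The same pipeline is scriptable from the shell:

```sh
oystervid simulate --seed 42 --out-dir out/            # bundled preset
oystervid validate-classification --oysters out/oysters.csv
oystervid fit-vc --readings out/readings.csv --vc-out out/vc.csv
oystervid precision --vc-file out/vc.csv --a 1,2,3,4,5 --b 5 --curve
oystervid design --vc-file out/vc.csv --target-se 0.3
oystervid run-all --config my_survey.yaml --out-dir out/
```

## Layout

- `src/oystervid/design.py` — survey layout, variance components, generator
  configuration, reference presets
- `src/oystervid/simulate.py` — gaussian-model and mechanistic generators
- `src/oystervid/classification.py` — confusion matrix and agreement statistics
- `src/oystervid/validation.py` — section-level field-vs-video comparison
- `src/oystervid/anova.py`, `reml.py`, `model.py` — nested ANOVA, EMS,
  F-tests, MoM and REML behind `NestedSurveyModel` / `NestedSurveyResults`
- `src/oystervid/precision.py` — error propagation and design planning
- `src/oystervid/io.py`, `cli.py` — CSV/XLSX/YAML interchange and the CLI

See `docs/methods.md` for the statistical methods, model assumptions,
numerical choices and known limitations.
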