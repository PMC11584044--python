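# leafmorph

Pseudo-landmark morphometrics of lobed leaf outlines, with downstream
climate-window modeling.

## The problem

Some species — shepherd's purse (*Capsella bursa-pastoris*) is the motivating
case — have rosette leaves so variable in lobe number, depth, and
architecture that classical landmark analysis fails: apart from the tip and
the base there are no homologous points to digitize. `leafmorph` implements
the standard workaround for such species: every traced outline is resampled
to a fixed number of *pseudo-landmarks* at equal arc-length spacing (100 per
side by default, base → tip → base, 2S = 200 points), so point *k* on one
leaf corresponds to point *k* on every other leaf along the proximal-distal
axis. The configurations are then

* superimposed by **generalized Procrustes analysis** (full Procrustes:
  translation, unit centroid size, SVD rotation; iterated against an evolving
  mean shape until the mean moves less than a tolerance),
* embedded in a **PCA morphospace** whose inverse map
  `mean + Σ score_j · loading_j` renders theoretical ("eigen") leaves on a
  5 × 5 grid spanning the observed PC1/PC2 cloud,
* classified into historical **shape types** (4 Shull types; 11 Iannetta
  panels, groupable into 7 coarse types) by smallest Procrustes distance to
  archetypal configurations,
* and summarized by the traditional descriptors **circularity**
  `Circ = 4π·A/P²` (1 for a circle, falling with lobing) and **aspect
  ratio** `AR = length/width` (tip-base extent over perpendicular extent;
  larger = longer and narrower).

On the environmental side, daily station weather is averaged per site,
converted from archive tenths-units, and aggregated over three windows
anchored on each specimen's collection date — the growing season (**GS**, 6
calendar months), the year-long window (**YL**, 365 days, with mean
temperature defined as (hottest-month mean + coldest-month mean)/2), and the
date of collection (**DOC**) — into AT/MAX/MIN temperature and log1p
precipitation covariates. Each shape descriptor is regressed on each
window's covariates with and without a climate-region categorical and with
temperature × precipitation interactions, and the nine fits are ranked by
ΔAIC; χ²/Cramér's V, one-way ANOVA, Tukey HSD, and per-region trend
regressions round out the battery.

Because the method is aimed at herbarium pipelines whose raw data cannot be
bundled, the package ships a first-class **synthetic generator**: parametric
lobed leaves with half-width profile
`h(t) = W·sin(πt)·(1 − d·sin²(c·πt))` (lobe count *c*, depth *d*), specimen
metadata placed in 8 NOAA climate regions, sinusoidal daily site weather,
and a *planted* linear effect of GS mean temperature on lobe depth — so
every downstream stage, up to and including AIC model selection and
confidence-interval coverage, is testable against known ground truth.

## Worked example

```sh
leafmorph simulate demo -n 150 --seed 42 --no-render
leafmorph run-all demo demo_out --seed 42 --no-render
```

or equivalently in Python:

```python
from leafmorph.pipeline import PipelineConfig, run_simulate, run_all

cfg = PipelineConfig(n_specimens=150, seed=42, render=False)
run_simulate("demo", config=cfg)
res = run_all("demo", "demo_out", config=cfg)
```

With this seed the run prints/produces (see `demo_out/*.csv`):

```
n = 150 leaves
circ range: 0.066 - 0.554
AR range:   1.64 - 9.16
GPA iterations: 3 converged: True
PC1 58.0%, PC2 13.4%
      model    response   n        llf         AIC  delta_AIC
GS_noregion circularity 150 158.854189 -305.708377   0.000000
         GS circularity 150 162.148907 -298.297814   7.410563
       INGS circularity 150 163.018869 -298.037739   7.670638
best_type: Tenius 61, Rhomboidea 42, Simplex 34, Heteris 13
```

Reading this: deeply lobed leaves have low circularity (down to 0.066) and
entire ones approach 0.55; GPA converges in 3 iterations; PC1 carries 58% of
aligned-shape variance. The ΔAIC table correctly selects a growing-season
model (the generator planted its temperature effect on the GS window): the
best model has ΔAIC = 0 by definition, and the GS family beats the YL and
DOC windows. Type frequencies refer to the packaged synthetic archetypes,
not to any real herbarium sample. The planted temperature→lobing slope is
positive on the circularity scale (warmer growing seasons → shallower lobes
→ rounder leaves) but at n = 150 it is buried under the deliberately wide
lobe-count prior; the acceptance suite recovers it with 95% CI coverage at
n = 300 with the prior held fixed.

## Layout

```
src/leafmorph/
  synthetic.py    leaf/specimen/weather generators, planted climate effect
  outline_io.py   outline text-file I/O, shape descriptors
  landmarking.py  tip/base detection, orientation, equidistant resampling
  procrustes.py   pairwise + generalized Procrustes, distance matrices
  morphospace.py  PCA, inverse PCA, theoretical-leaf grid
  archetypes.py   Shull/Iannetta classification, frequency tables
  climate.py      weather windows, shape~climate models, ΔAIC, region tests
  pipeline.py     end-to-end orchestration
  cli.py          `leafmorph` command-line interface
```

See `docs/methods.md` for the model details, parameter choices, and known
limitations.
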