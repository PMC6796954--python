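# traitfilter

Trait-based detection of environmental filtering in pollinator communities
along elevation gradients.

High elevations are harsh: only a narrow band of functional strategies is
viable where growing seasons are short and temperatures low. For
flower-visiting insects, two thermal traits matter most — **body size**
(better heat retention and thoracic thermoregulation) and **body darkness**
(faster radiative warm-up). `traitfilter` implements the full analysis
chain used to ask whether such *environmental filtering* intensifies with
elevation, and whether it acts differently on bees and flies:

1. **Morphometrics** — specimen traits from three-view images or linear
   measurements: ellipsoid body volume `V = π/6 · L · W · H` (length and
   width from the dorsal view, height from the lateral view, head
   excluded), and body darkness, the median of an inverted-intensity
   channel rescaled to **[0, 222]** (0 = all white, 222 = all black) over
   the face/thorax/abdomen region.
2. **Community metrics** — per pollinator-cup (pan-trap) samples:
   community-weighted mean `CWM = (1/k) Σᵢ tᵢ` over the k captured
   individuals, and the trait range `obsRange = max(tᵢ) − min(tᵢ)`.
3. **Null model (sesRange)** — for each cup of k individuals, draw k
   individuals without replacement from the regional pool (all captured
   individuals of that taxon) B = 1,000 times; record the range of each
   draw. The standardized effect size is reported in two normalizations:

       sesRange = (obsRange − nullRange) / nullRange        (ratio form)
       ses_sd   = (obsRange − nullMean) / nullSD            (z form)

   with `nullRange` the null-mean range. Significance uses the two-tailed
   rule |SES| ≥ 1.96 on the z form (the default mode, the only one under
   which 1.96 is probabilistically meaningful). Significantly **negative**
   values mean narrower-than-expected trait ranges — a **strong
   environmental filter**; significantly positive values, a weak filter.
   When `C(pool, k)` is small the null is enumerated exhaustively instead
   of sampled.
4. **Inference** — one-way ANOVAs of CWM and sesRange against life zone
   (ponderosa ≈ 2,400 m, mixed conifer ≈ 2,600 m, spruce-fir ≈ 3,200 m)
   with Tukey HSD post-hoc tests, plus intraspecific trend tests for
   species spanning all three zones.
5. **Synthetic survey generator** — a fully parameterized emulation of the
   underlying pan-trap design (3 life zones × 3 sites × 12-cup arrays ×
   2 seasons; 178 bee / 96 fly species; 1,283 bee + 639 fly specimens)
   with per-zone trait targets, declining richness and bee abundance with
   elevation, overdispersed catches, and a tunable filtering strength that
   narrows bee trait ranges at high elevation while only shifting fly
   means. Every downstream stage is therefore testable with no external
   data.

The package is aimed at community ecologists who want a reproducible,
seedable reference implementation of the CWM + sesRange workflow, and at
methodologists who want to probe the statistical behavior of range-based
filtering tests under known generating conditions.

## Worked example

```python
import traitfilter as tf

bundle = tf.run_pipeline(seed=0, B=1000)   # default study design
zs = bundle.zone_stats
print(zs[zs.metric == "ses_range"][["taxon", "trait", "life_zone", "mean", "sd"]])
```

which prints (cup-level means ± SD of the z-form SES per life zone):

```
taxon    trait     life_zone  mean   sd
  bee darkness     ponderosa -0.98 1.43
  bee darkness mixed_conifer -1.40 1.07
  bee darkness    spruce_fir -3.32 1.90
  bee   volume     ponderosa -0.07 1.72
  bee   volume mixed_conifer -0.66 0.89
  bee   volume    spruce_fir -1.60 0.39
  fly darkness     ponderosa -0.83 0.68
  fly darkness mixed_conifer -0.06 1.02
  fly darkness    spruce_fir -0.42 0.88
  fly   volume     ponderosa -0.97 0.57
  fly   volume mixed_conifer -0.23 1.01
  fly   volume    spruce_fir  0.23 0.95
```

Read: bee darkness ranges at spruce-fir are 3.3 null SDs narrower than
random draws from the regional pool predict (mean SES −3.32 < −1.96, a
strong environmental filter), while no fly SES approaches the ±1.96
bounds — the bee-specific high-elevation filter the generator encodes.
The matching CWM table shows the mean-trait side of the same story (bee
darkness ≈ 33/29/78 across the three zones, bee volume ≈ 274/260/603 mm³),
and `bundle.anova_table` confirms the zone effect for every response, e.g.
CWM bee darkness `F(2,186) = 493.9, p < 0.001`. Of the 18 species present
in all three zones, 35 of 36 species × trait combinations with a
significant zone effect trend upward (`bundle.intraspecific_table`).

The same pipeline runs from the shell:

```bash
traitfilter run --config my_design.yaml --seed 0 --B 1000 --out results/
traitfilter generate --seed 1 --out survey/ --render 5   # with images
traitfilter ses --in survey/specimens.csv --taxon bee --trait darkness \
    --B 1000 --mode sd --seed 1 --out ses.csv
```

External specimen tables in the documented CSV schema (see
`traitfilter.io`) can be ingested with `traitfilter.read_specimen_table`
and analyzed with `traitfilter.analyze_specimen_table`.

## Layout

- `src/traitfilter/config.py` — study-design / generator configuration
- `src/traitfilter/synthetic.py`, `rendering.py` — survey generator and
  three-view specimen renderer
- `src/traitfilter/morphometrics.py` — volume and darkness measurement
- `src/traitfilter/community.py` — cup samples, CWM, ranges, correlations
- `src/traitfilter/nullmodel.py` — null distributions and sesRange
- `src/traitfilter/inference.py` — ANOVA/Tukey battery, intraspecific trends
- `src/traitfilter/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI, I/O
- `docs/methods.md` — model assumptions, parameter choices, limitations
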