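# ncptkit

Preprocessing, census-reweighted score normalization, normative tables, and
cohort simulation for web-based cognitive test batteries.

Large self-administered cognitive assessments — batteries of brief subtests
(go/no-go, memory span, progressive matrices, trail making, ...) taken in a
browser — produce score tables whose demographic composition is nothing
like the general population: volunteers skew educated, female, and
self-selected. `ncptkit` is for researchers who need to turn such raw
session records into population-referenced scores and norms: it implements
the exclusion filtering, the reweighted inverse normal transformation, the
Grand Index composite, the 13-column normative tables, and the
residual-correlation validation used for the NeuroCognitive Performance
Test (NCPT) data releases, plus a synthetic-cohort generator so the whole
pipeline is testable end to end with no external data.

## The core transformation

Participants are assigned to K = 18 demographic bins (six age bins × three
education bins). Given sample bin proportions f_k and target (reference
population) proportions f\*_k, each observation i in bin k — with scores
sorted ascending after orienting time-based scores so higher is better —
receives a reweighted percentile width and centered rank

    w_i  = f*_k / (N f_k),     r~_i = w_i/2 + Σ_{j<i} w_j,

and the normalized score y_i = Φ⁻¹(r~_i), the quantile of a normal with
mean 100 and SD 15. With f\* = f this is the standard centered-rank inverse
normal transformation; with a census-like f\* it expresses each score as
standing in the *general* population rather than in the skewed sample. The
**Grand Index (GI)** of a complete test run is the mean of its normalized
subtest scores, mapped through the same reweighted transformation to mean
100, SD 15 — so GI 100 means average overall performance relative to the
reference population.

## Worked example

Simulate a 2,000-participant battery-39 cohort with a few percent of
contaminated sessions, and run every stage:

```sh
ncptkit run-all --config examples/cohort_battery39.yaml --out-dir out/
```

which prints the per-stage record counts from the manifest:

```
simulate: 0 -> 15781
preprocess: 15781 -> 15005
normalize: 15005 -> 15005
grand_index: 15005 -> 1847
norms: 15005 -> 0
validate: 15005 -> 1671
manifest -> out/manifest.json
```

15,781 score rows are simulated (2,000 participants × 8 subtests, minus
failed go/no-go sessions and mid-battery dropouts). The exclusion report
(`out/exclusion_report.json`) shows the filters caught the injected
defects — 49 users paused over 24 h between subtests, 22 interleaved a
second test inside their first, 26 took over 15 minutes on a trail making
subtest — leaving 15,005 rows. Every row gets a normalized score; the 1,847
runs that completed all 8 subtests get a Grand Index (here mean 101.4,
SD 14.2 against the shipped census-like reference: this simulated cohort is
slightly more able than the reference population because it is younger and
more educated, which is exactly what the reweighting is supposed to
surface). The norms stage emits nothing because at n = 2,000 not every of
the 36 demographic cells reaches the 20-participant minimum a published
norms table requires. The validation report confirms the positive manifold:
all residual subtest-subtest correlations are positive (min 0.17, max 0.75,
the largest between the two trail making subtests).

The same stages are available individually (`ncptkit simulate`,
`preprocess`, `normalize`, `gi`, `norms`, `validate`) and as library
functions (`ncptkit.normalize_scores`, `ncptkit.compute_grand_index`, ...);
see `docs/methods.md` for the full model description and design choices.

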