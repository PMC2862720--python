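# ihcflow

Quantitative analysis for multiplexed immunohistochemistry (IHC).

Pathologists grade breast-cancer biomarkers (ER, PR, HER2, Ki-67) from
DAB-stained tissue by eye — a subjective, hard-to-multiplex readout.
When several biomarkers are stained in parallel microchannels on one
tissue section, two computational questions follow, and this package
answers both:

1. **Quantification.** Segment each micrograph into stained cell area
   (SP, brown DAB), unstained cell area (NSP, blue hematoxylin) and
   background (BG) by Bayesian classification over per-class Gaussian
   mixture color models f(x; λ) = Σⱼ pⱼ N(x; μⱼ, Σⱼ) fit with EM
   (5/10/2 components for SP/NSP/BG), then score each field as

       expression level = staining ratio × staining intensity,

   with ratio = |SP|/(|SP|+|NSP|) and intensity the mean staining
   signal over SP, averaged over ≥ 5 fields per channel.

2. **Validation statistics.** Translate clinical scores (Allred 0–8,
   HER2 0–3+, Ki-67 %) onto a common 4-level ordinal scale and measure
   agreement between scoring routes: tie-corrected Kendall's W with its
   χ² = m(n−1)W test, Cohen's and Fleiss' κ, percent concordance with
   an exact binomial 95% CI, plus Pearson/Levene/t tests for
   quantitative comparisons and a Latin-square design for
   slide-reproducibility runs.

A transport module additionally simulates antibody binding in a
microchannel (2-D advection–diffusion with a Langmuir reactive tissue
wall) to show why flowing a diluted antibody outperforms static
incubation, and a synthetic-data module generates IHC-like fields and
paired ordinal ratings with exact ground truth so the whole pipeline is
testable without external data.

## Worked example

```sh
ihcflow generate --out fields --n-fields 5 --fraction-stained 0.3 --seed 7
ihcflow train    --images fields --out model.json --seed 0
ihcflow quantify --images fields --model model.json --out expression.csv
```

```
sp: 5 components, 48 EM iterations, converged=True
nsp: 10 components, 50 EM iterations, converged=True
bg: 2 components, 46 EM iterations, converged=True
wrote model.json
mean expression 0.2407 over 5 fields
```

`expression.csv` holds the per-field breakdown; the first field:

```
field_id,n_sp,n_nsp,n_bg,ratio,intensity,expression
field_000,1705,2994,4517,0.36284,0.65622,0.23810
```

36.3% of that field's cell area is stained (the generator placed ~30%
of cells as stained, and this field's exact truth mask agrees — the
classifier recovers the generated labels essentially pixel-perfectly),
the stained pixels have mean darkness 0.656, and their product, 0.238,
is the field's expression level; 0.2407 is the 5-field channel mean.

Agreement between two scoring methods over 105 cases (here generated
with 95% copy probability):

```sh
ihcflow generate-ratings --out ratings_er.csv --n-cases 105 --agreement 0.95 --seed 1
# add a biomarker column, then:
ihcflow concordance --ratings ratings.csv --out report.csv
```

```
biomarker      KCC       chi2   p_KCC    kappa p_kappa  concordance_pct   ci95_lo   ci95_hi   n
       ER 0.958587 199.386066 <0.0001 0.959449 <0.0001        97.142857 91.876807 99.406868 105
```

Read: the two methods rank the 105 cases almost identically (W = 0.96;
its χ² test rejects independence), chance-corrected categorical
agreement is κ = 0.96, and 97.1% of cases received identical categories
(exact 95% CI 91.9–99.4). Note χ² = 2·104·W holds exactly.

The same statistics are available as library functions
(`ihcflow.kendalls_w`, `ihcflow.cohens_kappa`,
`ihcflow.agreement_report`, …), as are the segmentation
(`ihcflow.fit_em`, `ihcflow.classify_pixels`), the quantification
(`ihcflow.expression_level`), and the channel simulation
(`ihcflow.simulate_transport`, `ihcflow.compare_static_vs_flow`).

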