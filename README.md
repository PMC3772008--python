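# mnox — community analysis of soil Mn(II)-oxidizing bacteria

`mnox` re-implements, as a tested and fully reproducible pipeline, the
computational workflow of a stratified-soil survey of manganese(II)-oxidizing
bacteria: colorimetric activity quantification, restriction-pattern typing of
isolates, gel-fingerprint diversity analysis, and 16S rRNA phylogenetics.  It
is aimed at environmental microbiologists who work with culture collections
and DGGE community fingerprints and want every number in such a study to be
recomputable from code.

The pipeline has five stages, each an importable module with a matching CLI
subcommand:

1. **Activity assay** (`mnox.oxidation`).  Leucoberbelin-blue (LBB) readings
   at 620 nm are converted through a KMnO4 standard curve to equivalent MnO2
   concentrations (1 µM MnO2 ↔ 0.4 µM KMnO4) and categorized as
   high (≥ 50 µM), medium ([10, 50)), low ([1, 10)) or none (< 1 µM); isolates
   are cross-tabulated by soil horizon (A/B/C) and category.
2. **In-silico ARDRA** (`mnox.ardra`).  16S amplicons are digested with
   HaeIII (GG^CC) and grouped by fragment pattern; each group is re-digested
   and regrouped with Sau3AI (^GATC), and one representative per final
   pattern is flagged for sequencing.
3. **DGGE fingerprints** (`mnox.dgge`).  Bands are called from 1-D
   densitometric lane traces (moving-average smoothing, top-hat baseline,
   1% relative-peak-height detection rule).  Each band *i* carries a weight
   *P*ᵢ = *n*ᵢ/*N* (peak height over summed peak heights); lane diversity is
   the Shannon index *H* = −Σᵢ *P*ᵢ ln *P*ᵢ, and two lanes are compared by
   *D* = Σᵢ |*A*ᵢ − *B*ᵢ| / *P* over their *P* = *n*_A + *n*_B − *c* union
   bands, where a band absent from a lane counts as probability zero.
4. **Ordination** (`mnox.ordination`).  The lane-distance matrix is embedded
   in two dimensions by classical (Torgerson) or non-metric MDS (Kruskal
   stress-1 with isotonic regression of disparities).
5. **Phylogenetics** (`mnox.phylo`).  Sequences are clustered into
   phylotypes at < 3% uncorrected divergence (complete linkage), distances
   are computed under the Kimura two-parameter model
   *d* = −½ ln(1 − 2*P* − *Q*) − ¼ ln(1 − 2*Q*), trees are built by
   Saitou–Nei neighbor joining, and node confidence comes from
   column-resampling bootstrap.

A synthetic-data generator (`mnox.simulate`) produces every input the
pipeline assumes — Yule trees, K2P-evolved alignments, gel lanes as Gaussian
band mixtures, and activity tables with a prescribed horizon × category
structure — so the whole analysis runs with no external data.

## Worked example

The numbered scripts under `analysis/` run the full survey re-analysis on
synthetic inputs (about 15 s in total):

```bash
python analysis/01_simulate_inputs.py
python analysis/02_activity_table.py
python analysis/03_ardra_grouping.py
python analysis/04_dgge_diversity.py
python analysis/05_phylogenetics.py
```

`02_activity_table.py` tabulates 503 isolate records whose horizon ×
category structure is the survey's, and prints:

```
          high  medium  low  none  total
A            8      32  143     9    192
B           22      17   54    67    160
C           20      29   19    83    151
compiled    50      78  216   159    503

total isolates: 503
share of all isolates (%): {'high': 9.9, 'medium': 15.5, 'low': 42.9, 'none': 31.6}
low-activity isolates by horizon (%): {'A': 66.2, 'B': 25.0, 'C': 8.8}
high-activity isolates by horizon (%): {'A': 16.0, 'B': 44.0, 'C': 40.0}
isolates with any activity: 68.4%
```

i.e. 344 of 503 isolates (68.4%) show Mn(II)-oxidizing activity; low-activity
isolates concentrate in the surface (A) horizon while high-activity isolates
dominate the deeper B and C horizons.  `04_dgge_diversity.py` then reports
the per-horizon fingerprint diversity of lanes with band richness 20/12/8:

```
lane_id  n_bands  shannon_H
      A       20   2.960328
      B       12   2.449598
      C        8   2.049702
depth ordering H_A > H_B > H_C: True
```

and `05_phylogenetics.py` clusters the 24 synthetic amplicons into 24
phylotypes and writes a neighbor-joining tree whose internal branches carry
1000-replicate bootstrap supports (21/21 branches ≥ 50% on these data).

The same stages are available as shell commands (`mnox digest`,
`mnox ardra-group`, `mnox bands`, `mnox diversity`, `mnox distance`,
`mnox mds`, `mnox phylotype`, `mnox njtree`, `mnox activity`,
`mnox simulate …`), and `mnox run config.yaml --out-dir run/` executes a
configured pipeline end to end, writing a manifest with seeds, parameters
and SHA-256 digests of all inputs and outputs.

## Layout

```
src/mnox/        library (assay, ARDRA, DGGE, ordination, phylogenetics,
                 simulation, reference tables, CLI)
analysis/        numbered narrative drivers writing to results/
tests/           pytest suite, including the acceptance checks
scripts/         acceptance.py
docs/methods.md  models, parameter choices, and limitations
```
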