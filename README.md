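# glycopotency

Comparability analysis toolkit for recombinant human FSH (follitropin alfa)
products: site-specific glycopeptide quantitation from LC-MS peak lists,
glycosylation summary metrics (Z-number / A-index), and parallel-line
in-vivo bioassay potency analysis with batch-comparison statistics.

## What it does

- **glycan_model** — parse/render complex N-glycan shorthand
  (`[F]AxGySz[LacN]`), validate compositions, compute residue masses.
- **ms_mapping** — in-silico chymotryptic digestion of the FSH α/β subunits,
  glycopeptide candidate enumeration for the four glycosites (α-Asn52,
  α-Asn78, β-Asn7, β-Asn24), nearest-in-ppm ion matching, XIC ion-count
  integration, and per-site relative glycan distributions.
- **glyco_metrics** — Z-number (percentage-weighted sialic-acid count) and
  A-index (percentage-weighted antenna count) per site, antennarity /
  fucosylation / sialylation class summaries, the whole-molecule
  glycan-release-simulation average, and Ph. Eur. Z-number range checks.
- **bioassay_potency** — 3×3 parallel-line (Steelman–Pohley) analysis:
  common-slope fit, validity ANOVA (regression / parallelism / linearity),
  relative potency with 95% Fieller fiducial limits, weighted combination of
  replicate assays, specific activity (IU/mg) and percent-of-nominal.
- **batch_comparison** — one-way ANOVA with Fisher-LSD pairwise verdicts,
  Bartlett's variance check, CVs, and a seeded cross-validation subgroup
  analysis for unbalanced group sizes.
- **synthetic_data** — seeded generators for glycopeptide peak lists with
  prescribed site distributions (plus ground truth) and parallel-line assay
  datasets with a prescribed true relative potency.
- **datasets** — bundled CSV transcriptions of the published batch table,
  the α-Asn52 class distributions, and the site-metric table, so the metric
  computations can be exercised offline.

## CLI

```bash
# simulate a glycopeptide run, then analyse it
glycopotency simulate ms --seed 7 --out-peaks peaks.csv --out-truth truth.csv
glycopotency assign --peaks peaks.csv --peptides peptides.csv \
    --glycans glycans.csv --ppm 10 --out assignments.csv
glycopotency quantify --assignments assignments.csv --out dist.csv
glycopotency metrics --dist dist.csv --out metrics.csv

# simulate and analyse parallel-line bioassays
glycopotency simulate assay --rho 1.056 --n-assays 8 --seed 7 --out assays.csv
glycopotency potency --assay assays.csv --assumed 147.5

# compare batch potency groups, with cross-validation subgrouping
glycopotency compare --groups groups.csv --crossval 7,7,8 --seed 17
```

File dialects: peak lists are `rt_min,mz,intensity` CSVs; assays are
`assay_id,preparation,dose_iu,animal_id,ovary_weight_mg`; groups are
`batch_id,product,relative_percent`.

## Notes on defaults

The matching tolerance (10 ppm) and charge states (1–4 within the
100–2000 m/z scan range) are analysis defaults, not method-stated values;
reports carry a header noting this. Quantitation pools charge states of one
(peptide, glycan) pair before normalising, and by default restricts to a
single backbone peptide per site (ionisation efficiency is comparable only
within one peptide carrying different glycans); pooling across backbones is
opt-in. Metric rounding is half-away-from-zero, which reproduces every
checkable published table cell.
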