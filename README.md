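# apmsflow

Analysis pipeline for affinity-purification mass-spectrometry (AP-MS)
complexome experiments separated into native molecular-weight bands:

- **psm_io** — PSM/protein data model, FASTA and PSM-table readers,
  peptide→protein mapping, in-silico tryptic digestion.
- **quantify** — peptide counts, spectral index (SI) and spectral index
  normalized to global intensity (SI_GI), sequence coverage. SI_GI is a
  protein's share of the summed retained PSM intensity within one sample;
  shared peptides count toward the denominator but no protein's numerator,
  and proteins with fewer than two distinct peptides are zeroed.
- **enrichment** — per-band Welch t-tests of bait vs IgG-control SI_GI
  (zero-filled), all-replicates consistency flag, Venn-region counting.
- **multivariate** — per-protein z-transformation and PCA with samples as
  observations (scores per band-replicate, loadings per protein,
  deterministic sign convention).
- **network** — trace filter (drop proteins below 2% ≡ 50-fold of the
  bait's SI_GI), offline STRING detailed-links evidence loading
  (experimental channel ≥ 700), abundance-scaled network assembly with one
  imputed bait edge per retained protein.
- **phospho** — A-score phosphosite localization: singly charged
  monoisotopic b/y ions (+79.9663 Da per phospho), per-100-m/z-window peak
  depth reduction, cumulative-binomial scoring, site-determining-ion
  contrasts, confidence mapping `100·(1−10^(−A/10))`, and cross-replicate
  site aggregation with composite labels ("S25/26") for adjacent
  ambiguous residues.
- **synthetic** — fully deterministic fixture generator: toy proteome,
  planted-partner AP-MS experiment with log-normal intensities and IgG
  background, phosphopeptide MGF spectra with planted sites, plus
  ground-truth JSON.
- **cli/config** — YAML-configured orchestration with a machine-readable
  run report.

## Test

```bash
python -m pytest -q
```

The suite includes property-based tests (hypothesis) and an acceptance
suite (`tests/test_acceptance.py`). Two acceptance tests check externally
deposited reference data (the UniProt Q91V14 canonical FASTA and the
supplementary SI_GI z-matrix); they run only when local copies are placed
at `data/Q91V14.fasta` and `data/supplementary_s2_si_gi.tsv`, and are
skipped otherwise because the build environment has no network access.

## Command line

```bash
# generate a complete synthetic experiment (deterministic in --seed)
apmsflow simulate --seed 7 -o fixture/

# run every stage end-to-end from the generated config
apmsflow run-all -c fixture/config.yaml
```

Outputs land in the configured output directory: `quant_matrix.tsv`,
`bait_coverage.tsv`, `enrichment_<band>.tsv`, `venn.json`, PCA
scores/loadings/variance TSVs, `network_<band>.graphml` plus node/edge
tables, `phospho_sites.tsv`, and `report.json` (per-stage input/output and
filter counts, parameter echo, version, seed).

Stage subcommands (`quantify`, `enrich`, `pca`, `network`, `phospho`)
accept the same `-c/--config` plus targeted overrides such as `--alpha`,
`--trace-fraction`, `--min-evidence-score`, `--tolerance-da` and
`--mature-offset`.

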