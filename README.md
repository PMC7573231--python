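# sealmito

Analysis toolkit for high-resolution respirometry of permeabilized muscle
under SUIT (substrate–uncoupler–inhibitor titration) protocols, a fasting
mass-loss bioenergetic budget model, and gene-set enrichment of
differential-expression tables — together with seeded synthetic-data
generators so the entire pipeline is testable without instrument or
sequencing data.

## What it does

- **respirometry** — converts annotated oxygen-concentration traces into
  per-state steady fluxes (L_n, OXPHOS, L_Omy, ETS, CI, CII): local
  quadratic (Savitzky–Golay) derivative estimation per inter-event
  segment, backward-sliding steady-window detection, chamber-baseline
  correction, the cytochrome-c membrane-integrity check (runs failing the
  strict >10% flux-increase rule are excluded), oxygen operating-window
  QC, per-sample aggregation with OXPHOS-anchored standardization of
  single-measure states, control ratios (SCR_CI, SCR_CII, CCR_Ln, FCR),
  and paired pre/post t-tests.
- **bioenergetics** — apportions daily mass loss into pelage / water /
  fat-free mass / fat (defaults 14/25/20/41%), converts to daily energy
  expenditure via fixed energy equivalents (9 and 1 kcal g⁻¹; 37.7 and
  4.2 kJ g⁻¹), and extrapolates whole-muscle leak respiratory capacity
  from a mass-specific flux (22.4 L mol⁻¹ molar volume, 19.7 kJ per L O₂,
  28% muscle fraction, 106.5 kJ kg⁻¹ day⁻¹ field rate).
- **enrichment** — strict DE filter (padj < 0.05, |log₂FC| > 1),
  one-sided Fisher exact enrichment against GMT gene sets,
  Benjamini–Hochberg adjustment, permutation rank-deviation z-scores, and
  the combined score −ln(p)·z.
- **synthetic** — seeded generators for piecewise-steady oxygen traces
  (with titrations, reoxygenation events and Gaussian noise), molt
  cohorts, and DE tables with spiked true positives.
- **io / pipeline / cli** — CSV/TSV/GMT/YAML readers and writers and a
  deterministic end-to-end driver.

## CLI

```sh
# simulate inputs
sealmito simulate traces --out traces/ --animals 6 --seed 1
sealmito simulate cohort --out cohort.csv --animals 6 --seed 1
sealmito simulate de --out de.tsv --genes 1000 --seed 1

# analyze
sealmito respiro --traces traces/ --out states.tsv
sealmito energetics --cohort cohort.csv --leak-flux 13 --out budget.tsv
sealmito enrich --de de.tsv --gmt sets.gmt --direction up --perms 1000 \
    --seed 1 --out enrichment.tsv

# full pipeline
sealmito run --config config.yaml
```

Exit codes: 0 ok, 2 validation/configuration error, 3 stage failure.

A run configuration is a YAML file; stages are enabled by the inputs you
provide:

```yaml
traces_dir: traces            # respirometry stage
cohort_file: cohort.csv       # energetics stage
de_file: de.tsv               # enrichment stage (needs gmt_file too)
gmt_file: sets.gmt
out_dir: results
leak_flux: 13.0               # optional; defaults to the lowest measured leak
seed: 1
detector: {stability_tol: 0.02, steady_window: 60, smoothing_window: 20}
equivalents: {muscle_mass_fraction: 0.28}   # any constant is overridable
composition: {frac_pelage: 0.14, frac_fat: 0.41, frac_water: 0.25, frac_ffm: 0.20}
enrichment: {padj_cut: 0.05, lfc_cut: 1.0, n_permutations: 1000}
```

Outputs: `states.tsv`, `ratios.tsv`, `prepost.tsv`, `budget.tsv`,
`enrichment_{up,down}.tsv`, a machine-readable `qc.json` (excluded runs
with reasons, oxygen-window warnings, the OXPHOS pooling check), and
`manifest.json`. Reruns with the same configuration are byte-identical.

### File dialects

- Trace: CSV `time_s,o2_nmol_per_ml` with metadata in a leading
  `# key: value` comment block or a `<stem>.meta.yaml`/`.meta.json`
  sidecar; titration events in `<stem>.events.csv`
  (`time_s,agent,target_conc,unit`).
- Cohort: CSV `animal_id,mass_pre_kg,mass_post_kg,days_ashore`.
- DE table: TSV `gene_id log2fc pvalue padj`; gene sets: standard GMT.
- Protocol table: YAML (see `src/sealmito/data/protocols.yaml`),
  user-overridable via `--protocols` / `protocols_file`.

## Units

Fluxes are pmol O₂ s⁻¹ mg⁻¹ wet tissue throughout the respirometry
modules; conversions (ml O₂ kg⁻¹ min⁻¹, MJ day⁻¹) happen only in the
bioenergetics layer.
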