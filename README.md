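# warmsoil

Analysis toolkit for long-term warming × agricultural-management soil
experiments. It reimplements, as a tested and reusable pipeline, the
quantitative analysis of a 2 managements × 2 warming levels × 4 blocks ×
6 biennial sampling years factorial field design:

- **physiology** — microbial growth, respiration, carbon uptake and carbon
  use efficiency (CUE = G / (G + R)) from ¹⁸O-H₂O incubation raw data
  (proportional DNA-labeling model, ideal-gas CO₂ conversion), plus
  whole-growth-period root exudation from cuvette-trap measurements.
- **necromass** — amino-sugar biomarker accounting: bacterial necromass
  (muramic acid × 45), fungal necromass ((mmol glucosamine − 2 × mmol
  muramic acid) × 179.2 × 9), totals and contribution to SOC.
- **community** — rarefaction, Bray-Curtis similarity, moving-window
  time-decay relationships (log-log similarity vs time lag, within-plot
  pairs only), plot-level permutation comparison of TDR slopes, per-lineage
  TDRs with (warming − control)/control relative changes, and
  warming-vs-control divergence trajectories per block and year.
- **effects** — Cohen's d of warming per year (blocks as replicates), OLS
  and standardized-major-axis trend fits, ln response ratios, and
  early/late stage contrasts.
- **synthetic** — a fully seeded generator producing the complete
  experiment (design, bacterial/fungal count tables, isotope incubations,
  amino-sugar profiles, soil measurements) with exported ground truth:
  geometric-replacement community turnover with analytically known decay,
  linear-in-time warming divergence drift, an SOC warming effect ramping in
  after an onset year, and a CUE effect-size trajectory crossing zero
  mid-study. Noise-free generated data invert exactly through the
  physiology and necromass modules.

## CLI

```bash
warmsoil simulate --seed 1 --out data/            # synthetic experiment + ground_truth.json
warmsoil cue --incubations data/inputs/incubations.csv --f-co 2.0 --out cue.tsv
warmsoil necromass --profiles data/inputs/amino_sugars.csv \
    --measurements data/inputs/measurements.csv --out necromass.tsv
warmsoil tdr --table data/inputs/fungi_table.tsv \
    --taxonomy data/inputs/fungi_taxonomy.tsv \
    --metadata data/inputs/metadata.tsv --out tdr/
warmsoil divergence --table ... --taxonomy ... --metadata ... --out div/
warmsoil effects --measurements ... --metadata ... --variable soc --out eff/
warmsoil run --config pipeline.yaml                # full pipeline + manifest
warmsoil report --out run_dir/                     # Markdown report
warmsoil exudation --input exudation.csv --out exu.tsv
```

`warmsoil run` takes a YAML config with exactly one of an `inputs:` section
(paths to the TSV/CSV tables) or a `simulate:` section (generator
overrides), e.g.

```yaml
out_dir: run/
seed: 7
simulate:
  n_taxa: 200
  depth: 25000
effects:
  variables: [soc, cue]
```

Note: converting ¹⁸O incorporation to biomass carbon requires an explicit,
soil-specific factor `f_co` (µg biomass C per µg newly synthesized DNA-O).
There is no default; supply it via `--f-co` or the config.

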