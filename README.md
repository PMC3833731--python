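# karyo

Comparative analysis of polytene-chromosome banding sequences for
*Chironomus*-style karyotype studies:

- **band_model** — Keyl-notation banding formulas (`"1-7 15-12 8-11 16-19"`,
  descending interval = inverted block), species karyotype records (haploid
  number, whole-arm combination, per-arm sequence pools, annotations) with a
  JSON dialect and TSV export, and a registry of basic/standard sequences.
- **block_refine** — reduction of two comparable arm sequences to a signed
  permutation of maximal common oriented blocks.
- **reversal** — exact inversion-step distance (breakpoint-graph method with
  cycles, hurdles and fortress) plus optimal reversal scenarios, breakpoint
  bounds, and an exhaustive BFS oracle for n ≤ 8 used to validate the engine.
- **cytocomplex** — whole-arm combination canonicalisation, cytocomplex
  classification (including fused "modified" variants), and whole-arm
  translocation distance by exhaustive search over arm partitions.
- **pool_analysis** — per-species pool statistics: pool size (unmapped
  monomorphic arms count once), polymorphic arms, basic vs endemic split
  against the registry, study-level aggregates.
- **phylogeny** — per-arm inversion-step distance matrices, minimum spanning
  tree networks (DOT export), neighbor-joining trees (Newick), PHYLIP writer.
- **synthetic_data** — generators for reference band lists, inversion
  evolution with replayable logs, and whole studies with ground-truth
  ledgers; used throughout the test suite in place of figure-locked photomap
  data.
- **examples** — a bundled six-species example study whose code lists, arm
  combinations and basic/endemic structure are transcribed from the
  literature (band formulas are synthetic placeholders).

## CLI

```sh
karyo examples --out study/          # write the bundled example study
karyo validate study/*.json
karyo show study/chironomus_alluaudi.json
karyo classify study/*.json
karyo summary study/*.json --registry study/basic.json --out summary.tsv
karyo dist study/chironomus_alluaudi.json --arm C --pair allC1,allC2 --scenario
karyo net study/*.json --arm E --registry study/basic.json --format dot
karyo simulate --species 6 --seed 42 --out sim/   # synthetic study + truth.tsv
```

Results go to stdout, logs to stderr; exit codes are 0 (success),
1 (validation error), 2 (usage error).

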