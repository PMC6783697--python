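# cytocomp

Deriving the minimal macromolecular contents of a cytoplasm simulation cell
from protein copy-number data.

## The problem

Molecular simulations of a crowded cytoplasm cannot include every protein a
cell expresses: systems must stay small enough to simulate, yet still carry a
realistic mass density and a realistic balance between ribosomes and the rest
of the cytoplasmic proteome. A practical compromise is a cubic box of
cytoplasm containing exactly **one ribosome**, its share of tRNA, and the
smallest set of the most mass-dominant cytoplasmic proteins — scaled up just
enough to restore the macromolecular density and ribosomal/cytoplasmic mass
ratio lost when the long tail of rare proteins is dropped.

Getting there requires several ingredients this package provides:

- **`synth`** — a generator of synthetic multi-dataset protein-abundance
  studies (absolute/normalized mass spectrometry, GFP, TAP) with per-technique
  bias and dispersion and a known ground truth, for benchmarking every
  estimator downstream.
- **`io_ingest`** — reading abundance/metadata/annotation tables, filtering to
  the cytoplasmic proteome, and ranking proteins by total mass contribution.
- **`concordance`** — how well independent datasets agree: coefficients of
  variation per technique, per-dataset ribosome-count estimates from the 79
  ribosomal proteins (1:1 with the ribosome), pairwise Welch and exact
  Mann–Whitney tests with Bonferroni and Benjamini–Hochberg correction, and
  functional-profile similarity of each dataset's most abundant proteins.
- **`cell_model`** — cell-level physics: cytoplasm volume, one-ribosome box
  edge, tRNA copies per box, mass-density targets and unit conversions.
- **`composition`** — the builder: the smallest scaling factor and the
  shortest rank prefix of proteins that satisfy the density and mass-ratio
  constraints, found by exhaustive grid search with half-away-from-zero
  integer rounding.
- **`pipeline` / CLI** — one configuration drives synth → ingest →
  concordance → cell parameters → composition, with a markdown report
  rendered purely from the artifact files.

## Worked example

Physical parameters of the box, for a cell measured at 42 μm³ with 65%
cytoplasm and 126,213 ribosomes (`examples/03_cell_parameters.py`):

```text
cell volume:        42.0 um^3
cytoplasm volume:   27.30 um^3 (fraction 0.65)
box edge:           600.3 A
tRNA per box:       24 (average tRNA mass 25,500 Da)
density target:     90.0 g/L
rib/cyt target:     0.2229
```

Building a composition from a synthetic study
(`examples/04_build_composition.py`): copy numbers per cell are converted to
copies per ribosome, proteins are ranked by total mass, and the builder
searches for the smallest scaling factor whose rank prefix meets both targets
within 2%:

```text
scaling factor:   1.135
composition:      69 protein types, 129 molecules (+1 ribosome, 20 tRNA)
box edge:         566.7 A
density:          99.32 g/L (target 100.56)
rib/cyt ratio:    0.1965 (target 0.1928)
```

Cross-dataset concordance on the same synthetic study
(`examples/02_concordance.py`) recovers the configured technique ordering —
fluorescence-based abundances disperse more than mass-spectrometry ones:

```text
mean CV by group:
  ribosomal_within_dataset_GFP: 94.2%
  ribosomal_within_dataset_MS_absolute: 73.0%
  ...
ribosome estimates from 21 datasets: 40,210 - 204,557 (truth 150,000)
pairwise Welch tests: 210 pairs
  significant after Bonferroni: 105
  significant after Benjamini-Hochberg: 144
```

The same steps are available from the command line:

```bash
cytocomp run --seed 7 --out run7      # full pipeline, synthetic input
cytocomp report --artifacts run7      # markdown summary of the artifacts
```

or stage by stage (`synth`, `ingest`, `concordance`, `cell-params`, `build`).
See `examples/` for narrative scripts covering each capability, and
`docs/methods.md` for the model, parameter choices and limitations.

## Working with real data

Point `ingest` (or a `RunConfig` with `synthesize: false`) at three TSV
tables: an abundance matrix (`protein_id` × dataset columns, copies per
cell), dataset metadata (`dataset_id`, `technique`, `medium`, `phase`,
`units`) and protein annotations (`protein_id`, `molecular_mass_da`,
`compartments`, `is_ribosomal`, `go_classes`). The packaged list of 79
ribosomal protein families is available via
`cytocomp.default_ribosomal_proteins()`.

## Reproduction

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

computes the package's headline quantities — the desk-checkable constants and
unit checks, the end-to-end composition for the given seed, and the Monte
Carlo calibration rates (grid-search agreement with exhaustive enumeration,
ribosome-count recovery, builder feasibility under self-consistent targets,
Welch null rejection rate, technique-CV ordering) — and writes them as JSON,
one entry per quantity with its sample size. All randomness derives from
`--seed`.
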