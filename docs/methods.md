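# Methods

This note records the model behind `cytocomp`, the parameter choices and
their defaults, what the synthetic data generator does and does not emulate,
the numerical conventions, and the package's limitations.

## The simulation-cell model

The simulation cell is a cube of cytoplasm containing exactly one ribosome.
Its volume is the cell's cytoplasm volume divided by the number of ribosomes
per cell:

- cytoplasm volume `V_cyt = V_cell × f_cyt`;
- box volume `V_box = V_cyt / N_rib`; box edge `L = V_box^(1/3)`;
- tRNA copies per box = round(`N_tRNA_cell / N_rib`);
- macromolecular density = total mass in the box (proteins + one rRNA-inclusive
  ribosome + tRNA) divided by the box volume, in g/L;
- ribosomal/cytoplasmic mass ratio = ribosomal **protein** mass divided by the
  summed mass of the non-ribosomal cytoplasmic protein copies.

Defaults (all overridable in `CellParameters`):

| parameter | default | unit | rationale |
|---|---|---|---|
| `cell_volume_um3` | 42.0 | μm³ | typical haploid budding-yeast cell volume |
| `cytoplasm_fraction` | 0.65 | — | cytoplasm share after organelles |
| `n_trna_cell` | 3×10⁶ | copies | total cellular tRNA pool |
| `trna_nucleotides` | 75 | nt | average tRNA length |
| `nucleotide_mass_da` | 340 | Da | average nucleotide mass → 25,500 Da per tRNA |
| `target_density_g_per_l` | 90 | g/L | macromolecular (protein+RNA) density of cytoplasm |
| `target_rib_cyt` | 0.2229 | — | ribosomal/cytoplasmic protein mass ratio |

The ribosome masses (`ribosome_protein_mass_da`, `ribosome_total_mass_da`)
have **no library defaults**: they depend on the chosen ribosome structure.
The example config ships literature-scale approximations (~1.4 MDa protein,
~3.25 MDa with rRNA) that are not tied to any specific structure.

Measured cell geometry does not always agree with the naive cube root of
`V_cyt / N_rib` (rounding conventions, alternative volume estimates), so
`CellParameters` accepts explicit overrides for the box edge
(`box_length_override_angstrom`) and the tRNA count (`n_trna_box_override`);
when the edge is overridden, the box volume used for density follows the
override.

## Composition building

Per-cell copy numbers become per-box abundances by dividing by `N_rib`.
Proteins are ranked by total mass contribution (summary abundance × molecular
mass), descending, ties broken alphabetically. The builder searches the grid
`s ∈ [1, 5]` (step 0.001) of scaling factors, and for each `s` the shortest
rank prefix `K` such that the rounded copy numbers `round_half_away(s × a_i)`
meet **both** the density target and the mass-ratio target within relative
tolerance bands (default 2%). The search minimizes `s` first, then `K`;
entries rounded to zero copies are dropped. Grid search rather than
root-finding because rounding makes both constraint functions stepwise in
`s`. If no grid point is feasible the builder raises an error naming the
binding constraint.

Targets can come from configuration or be computed *self-consistently* as the
density and ratio of the full (unrounded) proteome — useful when benchmarking
the builder itself, since those targets are reachable by construction up to
rounding.

## Concordance statistics

- CVs are `100 × sd/mean` (sample sd). Group CVs average per-dataset CVs of
  the ribosomal proteins within a technique.
- Each of the 79 ribosomal proteins is assumed present at one copy per
  ribosome, so its abundance estimates the ribosome count; the pooled
  estimator takes the median over all ribosomal protein × dataset values,
  robust to the long-tailed noise.
- Pairwise dataset comparisons use Welch's t-test on log-abundances and the
  Mann–Whitney U test: exact, tie-aware enumeration of the rank-sum
  distribution when the combined sample size is ≤ 20, the normal
  approximation with tie correction beyond. Multiple testing is controlled
  both ways: Bonferroni (α divided by the number of pairs, e.g. 190 for 20
  datasets) and Benjamini–Hochberg.
- Functional similarity of each dataset's top-N proteins is measured on
  ontology-class count profiles (Pearson) and class sets (Jaccard).

Degenerate Welch inputs follow fixed conventions: two zero-variance samples
give p = 1 when the means are equal and p = 0 (with a warning) otherwise.

## The synthetic generator

`synth` emulates a collection of copy-number studies:

- true abundances are log-normal (median ≈ 36,500 copies, log-sd 1.2), with
  79 ribosomal proteins pinned exactly to the true ribosome count;
- each technique applies a multiplicative bias (separately for ribosomal and
  non-ribosomal proteins) and multiplicative log-normal noise with
  `σ = sqrt(ln(1 + CV²))` and **log-mean 0**. The noise is therefore
  median-unbiased — medians converge to bias × truth, which is why the
  package's ribosome estimator uses medians; means carry the known
  `exp(σ²/2)` inflation;
- default technique models: absolute MS (bias 1, CV 0.69), normalized MS
  (bias 0.25, CV 0.69), GFP (bias 0.8, ribosomal bias 0.4, CV 1.03), TAP
  (bias 1, CV 0.8) — dispersions chosen so fluorescence-based data scatter
  more than MS data, the pattern reported across real yeast abundance
  compilations;
- values are missing completely at random (default 25%), with at least one
  observation guaranteed per protein;
- a configurable fraction of non-ribosomal proteins is annotated to
  non-cytoplasmic compartments (some dually localized) to exercise the
  ingestion filter.

It does **not** emulate: intensity-dependent (non-MCAR) missingness,
correlated errors between datasets that share a lab or protocol, growth-rate
dependence of expression, protein complexes beyond the ribosome, or
compartment mis-annotation.

## Numerical conventions

- 1 Da = 1/6.0221408×10²³ g (the inverse of the Avogadro constant), so one
  mole of daltons in a litre is exactly 1 g/L; 1 μm³ = 10⁻¹⁵ L.
- Copy numbers round half away from zero.
- All random draws flow from a single integer seed through NumPy generators;
  derived seeds are below 2³¹. Identical seeds give byte-identical artifacts.
- Estimator-calibration checks in the test suite run the recovery benchmark
  at technique CV 0.3 (five unbiased datasets, 79 ribosomal proteins): at
  that dispersion the pooled-median standard error (≈ 1.25 σ/√n on the log
  scale) keeps ≥ 95% of runs within a 5% band, a margin that the package's
  noisiest default technique (CV ≈ 1) deliberately does not meet — with that
  noise, single-study estimates genuinely scatter widely, as the concordance
  module is designed to show.

## Problem sizes

Typical runs: 400 proteins × 21 datasets synthesize and ingest in tens of
milliseconds; the 4,001-point scaling grid with prefix search over ~300
cytoplasmic proteins completes in ~10 ms (the density curve is vectorized);
the exact Mann–Whitney enumeration is limited to combined samples of 20 by
design. A full pipeline run is under one second.

## Limitations

- The composition always takes a rank prefix of the mass ranking; skipping
  proteins mid-ranking is not explored.
- The builder models only proteins, one ribosome and tRNA — no mRNA, DNA,
  lipids, metabolites or water.
- The mass-ratio and density constraints are enforced as bands, not exactly;
  with integer copies exact satisfaction is generally impossible.
- The pooled ribosome estimate treats every ribosomal protein as strictly
  1:1 with the ribosome; paralog pairs sharing one slot and extra-ribosomal
  pools violate this in real data.
- No 3D coordinates or packing: the output is a parts list with box
  dimensions, not a structure.
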