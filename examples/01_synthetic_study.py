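"""Generate a synthetic multi-dataset proteomics study with known truth.

The generator emulates a collection of yeast protein copy-number datasets
measured with different techniques (absolute and normalized mass spectrometry,
GFP fluorescence, TAP immunoblotting).  Each technique carries its own
multiplicative bias and dispersion; the ground truth behind every value is
kept, so estimators can be benchmarked against it.
"""

from cytocomp import SynthParams, generate_dataset

params = SynthParams(seed=42)
matrix, annotations, metadata, truth = generate_dataset(params)

print(f"proteins: {len(matrix)} ({params.n_ribosomal} ribosomal)")
print(f"datasets: {matrix.shape[1]} across "
      f"{metadata['technique'].nunique()} techniques")
print(f"true ribosome count: {truth.true_ribosome_count:,.0f} per cell")
print(f"missing values: {matrix.isna().to_numpy().mean():.1%}")

# ribosomal proteins are 1:1 with the ribosome, so each one's row estimates
# the ribosome count; technique bias shifts those estimates per dataset
rib_ids = annotations.loc[annotations["is_ribosomal"] == 1, "protein_id"]
medians = matrix.loc[rib_ids].median()
print("\nper-dataset median ribosomal-protein abundance:")
for dataset_id in ("MS01", "MSN01", "GFP01"):
    print(f"  {dataset_id}: {medians[dataset_id]:>10,.0f}")
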