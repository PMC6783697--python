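# Example cell-parameter configuration for budding yeast.
#
# The per-ribosome masses below are literature-style approximations, NOT
# values taken from any single proteomics study: the 80S ribosome carries
# roughly 1.4 MDa of protein (79 r-proteins) and roughly 3.25 MDa in total
# once the four rRNAs (~5,470 nucleotides) are included.  Supply your own
# values when they matter.
ribosome_protein_mass_da: 1.4e6     # Da, protein-only (enters the rib/cyt numerator)
ribosome_total_mass_da: 3.25e6      # Da, protein + rRNA (enters the density)
n_ribosomes_cell: 150000            # copies/cell; replace with a data-derived estimate
cell_volume_um3: 42.0               # um^3
cytoplasm_fraction: 0.65            # unitless; cytoplasm = 27.3 um^3
n_trna_cell: 3000000                # copies/cell
trna_nucleotides: 75                # average length
nucleotide_mass_da: 340.0           # Da per nucleotide -> 25,500 Da per tRNA
target_density_g_per_l: 90.0        # g/L macromolecular density target
target_rib_cyt: 0.2229              # ribosomal / cytoplasmic protein mass ratio
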