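"""Derive the physical parameters of a one-ribosome simulation cell.

The simulation cell is a cube of cytoplasm containing exactly one ribosome.
Its volume is the cell's cytoplasm volume divided by the number of ribosomes
per cell; everything else (box edge, tRNA copies, mass targets) follows from
a handful of measured cell-level quantities.
"""

from cytocomp import CellParameters

params = CellParameters(
    ribosome_protein_mass_da=1.4e6,   # protein portion of one ribosome
    ribosome_total_mass_da=3.25e6,    # with rRNA included
    n_ribosomes_cell=126_213,
)

print(f"cell volume:        {params.cell_volume_um3} um^3")
print(f"cytoplasm volume:   {params.cytoplasm_volume_um3:.2f} um^3 "
      f"(fraction {params.cytoplasm_fraction})")
print(f"box edge:           {params.box_length_angstrom:.1f} A")
print(f"tRNA per box:       {params.n_trna_box} "
      f"(average tRNA mass {params.trna_mass_da:,.0f} Da)")
print(f"density target:     {params.target_density_g_per_l} g/L")
print(f"rib/cyt target:     {params.target_rib_cyt}")

# measured cell geometry can disagree with the naive cube root; overrides
# let the box follow an externally chosen edge length
adjusted = CellParameters(
    ribosome_protein_mass_da=1.4e6,
    ribosome_total_mass_da=3.25e6,
    n_ribosomes_cell=126_213,
    box_length_override_angstrom=560.0,
)
print(f"\nwith a 560 A override the box volume becomes "
      f"{adjusted.box_volume_um3:.3e} um^3")
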