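"""Physical parameters of the yeast cytoplasm and the one-ribosome simulation cell.

The simulation cell is the cubic periodic unit holding a single 80S ribosome
plus that ribosome's per-cell share of cytoplasmic proteins and tRNAs.  Its
geometry and mass bookkeeping follow from a handful of cell-scale quantities:
the cell volume, the cytoplasmic volume fraction, the number of ribosomes and
tRNAs per cell, and the per-ribosome protein and total (rRNA-inclusive)
masses.  This module holds those quantities and the unit-correct arithmetic
between them; nothing here touches abundance tables.

Units are explicit in every name: volumes in cubic micrometres, masses in
daltons, lengths in angstroms, densities in grams per litre.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

#: Avogadro constant, 1/mol.  The dalton-to-gram factor is defined as its
#: reciprocal so that mass and amount conversions are exactly consistent.
AVOGADRO = 6.0221408e23

#: grams per dalton
DA_TO_GRAM = 1.0 / AVOGADRO

#: litres per cubic micrometre
UM3_TO_L = 1e-15

#: angstroms per micrometre
ANGSTROM_PER_UM = 1e4


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero.

    This is the single rounding convention used wherever a molecule count is
    produced, chosen over banker's rounding so that the count of any species
    with a half-integer expected copy number is never silently dropped.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def cytoplasm_volume(cell_volume_um3: float, cytoplasm_fraction: float) -> float:
    """Cytoplasmic volume (um^3) as cell volume times the cytoplasmic fraction.

    The defaults elsewhere (42 um^3, 0.65) come from cell-size and tomography
    measurements of budding yeast and give 27.3 um^3.
    """
    if cell_volume_um3 <= 0:
        raise ValueError(f"cell_volume_um3 must be positive, got {cell_volume_um3}")
    if not (0 < cytoplasm_fraction <= 1):
        raise ValueError(
            f"cytoplasm_fraction must be in (0, 1], got {cytoplasm_fraction}"
        )
    return cell_volume_um3 * cytoplasm_fraction


def average_trna_mass(n_nucleotides: float, nucleotide_mass_da: float) -> float:
    """Average tRNA mass in Da: nucleotide count times average nucleotide mass."""
    if n_nucleotides <= 0:
        raise ValueError(f"n_nucleotides must be positive, got {n_nucleotides}")
    if nucleotide_mass_da <= 0:
        raise ValueError(f"nucleotide_mass_da must be positive, got {nucleotide_mass_da}")
    return n_nucleotides * nucleotide_mass_da


def macromolecular_density(total_mass_da: float, volume_um3: float) -> float:
    """Macromolecular density in g/L from a mass in Da and a volume in um^3."""
    if volume_um3 <= 0:
        raise ValueError(f"volume_um3 must be positive, got {volume_um3}")
    if total_mass_da < 0:
        raise ValueError(f"total_mass_da must be non-negative, got {total_mass_da}")
    return (total_mass_da * DA_TO_GRAM) / (volume_um3 * UM3_TO_L)


def rib_cyt_ratio(ribosomal_protein_mass_da: float, cytoplasmic_protein_mass_da: float) -> float:
    """Mass ratio of ribosomal protein to (non-ribosomal) cytoplasmic protein."""
    if cytoplasmic_protein_mass_da <= 0:
        raise ValueError(
            "cytoplasmic protein mass must be positive, got "
            f"{cytoplasmic_protein_mass_da}"
        )
    if ribosomal_protein_mass_da < 0:
        raise ValueError(
            f"ribosomal protein mass must be non-negative, got {ribosomal_protein_mass_da}"
        )
    return ribosomal_protein_mass_da / cytoplasmic_protein_mass_da


def box_length(
    cytoplasm_volume_um3: float,
    n_ribosomes: float,
    override_angstrom: Optional[float] = None,
) -> float:
    """Edge length (angstrom) of the cubic cell holding one ribosome's share
    of the cytoplasm.

    The box volume is cytoplasm_volume / n_ribosomes; the edge is its cube
    root.  ``override_angstrom`` forces an arbitrary length (the published
    cell-size figures for yeast are not exactly recoverable from their stated
    inputs, so a caller may want to pin the value).
    """
    if override_angstrom is not None:
        if override_angstrom <= 0:
            raise ValueError(f"override length must be positive, got {override_angstrom}")
        return float(override_angstrom)
    if cytoplasm_volume_um3 <= 0:
        raise ValueError(f"cytoplasm_volume_um3 must be positive, got {cytoplasm_volume_um3}")
    if n_ribosomes <= 0:
        raise ValueError(f"n_ribosomes must be positive, got {n_ribosomes}")
    return (cytoplasm_volume_um3 / n_ribosomes) ** (1.0 / 3.0) * ANGSTROM_PER_UM


def trna_count_box(
    n_trna_cell: float,
    n_ribosomes: float,
    override: Optional[int] = None,
) -> int:
    """tRNA copies in the one-ribosome box: the cell total split evenly over
    ribosomes (equivalently, scaled by box volume / cytoplasm volume when the
    box is one ribosome's share), rounded half away from zero."""
    if override is not None:
        if override <= 0:
            raise ValueError(f"override tRNA count must be positive, got {override}")
        return int(override)
    if n_trna_cell <= 0:
        raise ValueError(f"n_trna_cell must be positive, got {n_trna_cell}")
    if n_ribosomes <= 0:
        raise ValueError(f"n_ribosomes must be positive, got {n_ribosomes}")
    return round_half_away(n_trna_cell / n_ribosomes)


@dataclass
class CellParameters:
    """Cell-scale quantities driving the simulation-cell definition.

    Defaults are the values for exponentially growing budding yeast used
    throughout this package: a 42 um^3 cell of which 65% is cytoplasm,
    3 million tRNAs per cell averaging 75 nucleotides of 340 Da each, a
    target macromolecular density of 90 g/L and a target ribosomal-to-
    cytoplasmic protein mass ratio of 0.2229.

    The two per-ribosome masses have **no defaults**: the protein-only mass
    enters the rib/cyt numerator and the total (rRNA-inclusive) mass enters
    the density, and both must be supplied explicitly by the caller or the
    config file.
    """

    ribosome_protein_mass_da: float
    ribosome_total_mass_da: float
    n_ribosomes_cell: float
    cell_volume_um3: float = 42.0
    cytoplasm_fraction: float = 0.65
    n_trna_cell: float = 3_000_000
    trna_nucleotides: int = 75
    nucleotide_mass_da: float = 340.0
    target_density_g_per_l: float = 90.0
    target_rib_cyt: float = 0.2229
    box_length_override_angstrom: Optional[float] = None
    n_trna_box_override: Optional[int] = None

    def __post_init__(self) -> None:
        for name in (
            "ribosome_protein_mass_da",
            "ribosome_total_mass_da",
            "n_ribosomes_cell",
            "cell_volume_um3",
            "n_trna_cell",
            "trna_nucleotides",
            "nucleotide_mass_da",
            "target_density_g_per_l",
            "target_rib_cyt",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.cytoplasm_fraction <= 1):
            raise ValueError(
                f"cytoplasm_fraction must be in (0, 1], got {self.cytoplasm_fraction}"
            )
        if self.ribosome_total_mass_da < self.ribosome_protein_mass_da:
            raise ValueError(
                "ribosome_total_mass_da (protein + rRNA) cannot be smaller than "
                "ribosome_protein_mass_da"
            )

    @property
    def cytoplasm_volume_um3(self) -> float:
        return cytoplasm_volume(self.cell_volume_um3, self.cytoplasm_fraction)

    @property
    def trna_mass_da(self) -> float:
        return average_trna_mass(self.trna_nucleotides, self.nucleotide_mass_da)

    @property
    def box_volume_um3(self) -> float:
        """Volume of the one-ribosome box.

        When a box-length override is set the geometric volume follows the
        override, keeping length and volume consistent in downstream density
        arithmetic.
        """
        if self.box_length_override_angstrom is not None:
            return (self.box_length_override_angstrom / ANGSTROM_PER_UM) ** 3
        return self.cytoplasm_volume_um3 / self.n_ribosomes_cell

    @property
    def box_length_angstrom(self) -> float:
        return box_length(
            self.cytoplasm_volume_um3,
            self.n_ribosomes_cell,
            override_angstrom=self.box_length_override_angstrom,
        )

    @property
    def n_trna_box(self) -> int:
        return trna_count_box(
            self.n_trna_cell, self.n_ribosomes_cell, override=self.n_trna_box_override
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cytoplasm_volume_um3"] = self.cytoplasm_volume_um3
        d["trna_mass_da"] = self.trna_mass_da
        d["box_length_angstrom"] = self.box_length_angstrom
        d["n_trna_box"] = self.n_trna_box
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_config(cls, path: str | Path, **overrides) -> "CellParameters":
        """Load parameters from a flat YAML config file.

        Keys match the field names exactly; ``overrides`` win over the file.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        # YAML 1.1 reads exponent literals without a sign ("1.4e6") as strings
        for key, value in raw.items():
            if isinstance(value, str):
                raw[key] = float(value)
        raw.update(overrides)
        return cls(**raw)
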