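"""Constraint-based construction of the one-ribosome simulation-cell contents.

Starting from per-cell protein copy numbers, the builder:

1. scales each protein's abundance down to its share of a single ribosome's
   volume (a_i = n_i / N_ribosomes);
2. ranks proteins by mass contribution and keeps a rank prefix of the top K
   types;
3. multiplies the per-box abundances by a scaling factor s >= 1 before
   rounding to integer copies, compensating the mass lost by truncating the
   long tail of low-abundance proteins and by rounding fractional copies;
4. searches a grid of scaling factors for the smallest s (then smallest K)
   such that the box simultaneously hits the target ribosomal-to-cytoplasmic
   protein mass ratio and the target macromolecular density, both within
   relative tolerance bands.

Minimising s first keeps the composition as close as possible to the
measured proteome: larger factors reach the ratio with fewer, more abundant
protein types, distorting the relative composition.  A grid search is used
rather than root finding because rounding makes every achieved quantity a
step function of s.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cell_model import CellParameters, DA_TO_GRAM, UM3_TO_L, macromolecular_density
from .io_ingest import ProteinRecord, rank_by_mass

logger = logging.getLogger(__name__)


class InfeasibleCompositionError(RuntimeError):
    """No (scaling factor, type count) on the grid satisfies the constraints."""

    def __init__(self, message: str, binding_constraint: str):
        super().__init__(message)
        self.binding_constraint = binding_constraint


@dataclass(frozen=True)
class BuilderConfig:
    """Search grid and constraint tolerances for the composition builder."""

    s_min: float = 1.0
    s_max: float = 5.0
    s_step: float = 0.001
    density_tolerance: float = 0.02  # relative band around the density target
    ratio_tolerance: float = 0.02    # relative band around the rib/cyt target
    rounding: str = "half_away_from_zero"

    def __post_init__(self) -> None:
        if not (self.s_min < self.s_max):
            raise ValueError(f"s_min must be < s_max, got {self.s_min}, {self.s_max}")
        if self.s_step <= 0:
            raise ValueError(f"s_step must be positive, got {self.s_step}")
        if self.density_tolerance <= 0 or self.ratio_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.rounding != "half_away_from_zero":
            raise ValueError(f"unsupported rounding convention {self.rounding!r}")

    def grid(self) -> np.ndarray:
        n = int(np.floor((self.s_max - self.s_min) / self.s_step + 1e-9)) + 1
        return self.s_min + self.s_step * np.arange(n)


def per_ribosome_abundance(abundance_cell, n_ribosomes_cell: float):
    """Per-box (fractional) copies: cellular abundance / ribosomes per cell."""
    if n_ribosomes_cell <= 0:
        raise ValueError(f"n_ribosomes_cell must be positive, got {n_ribosomes_cell}")
    arr = np.asarray(abundance_cell, dtype=float)
    if np.any(arr < 0):
        raise ValueError("abundances must be non-negative")
    out = arr / n_ribosomes_cell
    return float(out) if np.isscalar(abundance_cell) else out


def integer_copies(a: float, s: float) -> int:
    """Integer copy number: round s*a half away from zero.

    Zero-copy results mean the protein is dropped from the composition.
    """
    if a < 0:
        raise ValueError(f"per-box abundance must be non-negative, got {a}")
    if s <= 0:
        raise ValueError(f"scaling factor must be positive, got {s}")
    return int(np.floor(s * a + 0.5))


def _copies_vector(abundances: np.ndarray, s: float) -> np.ndarray:
    return np.floor(s * abundances + 0.5)


def _achieved(
    cum_protein_mass: np.ndarray, params: CellParameters
) -> tuple[np.ndarray, np.ndarray]:
    """Achieved rib/cyt ratio and density (g/L) for every prefix length K.

    The ribosome contributes its protein-only mass to the rib/cyt numerator
    and its total (rRNA-inclusive) mass to the density; the box also contains
    the scaled-down tRNA complement.
    """
    with np.errstate(divide="ignore"):
        rib_cyt = np.where(
            cum_protein_mass > 0,
            params.ribosome_protein_mass_da / cum_protein_mass,
            np.inf,
        )
    fixed_mass = params.ribosome_total_mass_da + params.n_trna_box * params.trna_mass_da
    # vectorised form of macromolecular_density over all prefix masses
    density = (cum_protein_mass + fixed_mass) * DA_TO_GRAM / (params.box_volume_um3 * UM3_TO_L)
    return rib_cyt, density


def feasible_K(
    per_box_abundances: Sequence[float],
    masses: Sequence[float],
    s: float,
    params: CellParameters,
    config: BuilderConfig,
) -> Optional[int]:
    """Smallest prefix length K meeting both constraints at scaling factor s.

    ``per_box_abundances`` and ``masses`` must be ordered by descending
    per-cell mass contribution (the rank-by-mass order).  Returns None when no
    K in [1, len] satisfies both the rib/cyt and the density band.
    """
    a = np.asarray(per_box_abundances, dtype=float)
    m = np.asarray(masses, dtype=float)
    if a.size == 0:
        raise ValueError("empty ranking")
    copies = _copies_vector(a, s)
    cum_mass = np.cumsum(copies * m)
    rib_cyt, density = _achieved(cum_mass, params)
    ratio_ok = (
        np.abs(rib_cyt - params.target_rib_cyt) / params.target_rib_cyt
        <= config.ratio_tolerance
    )
    density_ok = (
        np.abs(density - params.target_density_g_per_l) / params.target_density_g_per_l
        <= config.density_tolerance
    )
    ok = ratio_ok & density_ok
    idx = np.flatnonzero(ok)
    return int(idx[0]) + 1 if idx.size else None


@dataclass
class CompositionSpec:
    """The final simulation-cell contents and the constraint values achieved."""

    entries: pd.DataFrame  # protein_id, copy_number, molecular_mass_da, mass_fraction_of_cytoplasmic
    scaling_factor: float
    prefix_types: int  # K: ranked types considered (including rounded-to-zero ones)
    n_trna: int
    box_length_angstrom: float
    achieved_density_g_per_l: float
    achieved_rib_cyt: float
    target_density_g_per_l: float
    target_rib_cyt: float
    feasible: bool
    n_ribosomes: int = 1

    @property
    def n_types(self) -> int:
        return len(self.entries)

    @property
    def n_molecules(self) -> int:
        return int(self.entries["copy_number"].sum())

    def summary(self) -> dict:
        return {
            "scaling_factor": self.scaling_factor,
            "n_types": self.n_types,
            "n_molecules": self.n_molecules,
            "n_trna": self.n_trna,
            "box_length_angstrom": self.box_length_angstrom,
            "achieved_density_g_per_l": self.achieved_density_g_per_l,
            "achieved_rib_cyt": self.achieved_rib_cyt,
            "target_density_g_per_l": self.target_density_g_per_l,
            "target_rib_cyt": self.target_rib_cyt,
            "feasible": self.feasible,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.entries.to_csv(out / "composition.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary(), indent=2, sort_keys=True) + "\n"
        )


def _assemble(
    ids: Sequence[str],
    per_box_abundances: np.ndarray,
    masses: np.ndarray,
    s: float,
    k: int,
    params: CellParameters,
) -> CompositionSpec:
    copies = _copies_vector(per_box_abundances[:k], s).astype(int)
    keep = copies >= 1
    entry_ids = [ids[i] for i in range(k) if keep[i]]
    entry_copies = copies[keep]
    entry_masses = masses[:k][keep]
    total_protein_mass = float(np.sum(entry_copies * entry_masses))
    mass_fraction = (
        entry_copies * entry_masses / total_protein_mass
        if total_protein_mass > 0
        else np.zeros_like(entry_masses)
    )
    entries = pd.DataFrame(
        {
            "protein_id": entry_ids,
            "copy_number": entry_copies,
            "molecular_mass_da": entry_masses,
            "mass_fraction_of_cytoplasmic": mass_fraction,
        }
    )
    fixed_mass = params.ribosome_total_mass_da + params.n_trna_box * params.trna_mass_da
    achieved_density = macromolecular_density(
        total_protein_mass + fixed_mass, params.box_volume_um3
    )
    achieved_ratio = (
        params.ribosome_protein_mass_da / total_protein_mass
        if total_protein_mass > 0
        else float("inf")
    )
    return CompositionSpec(
        entries=entries,
        scaling_factor=float(s),
        prefix_types=int(k),
        n_trna=params.n_trna_box,
        box_length_angstrom=params.box_length_angstrom,
        achieved_density_g_per_l=float(achieved_density),
        achieved_rib_cyt=float(achieved_ratio),
        target_density_g_per_l=params.target_density_g_per_l,
        target_rib_cyt=params.target_rib_cyt,
        feasible=True,
    )


def search_min_scaling(
    ids: Sequence[str],
    per_box_abundances: Sequence[float],
    masses: Sequence[float],
    params: CellParameters,
    config: Optional[BuilderConfig] = None,
) -> CompositionSpec:
    """Find the smallest scaling factor (then smallest type count) that
    satisfies both constraints, and assemble the composition.

    Inputs must be in rank-by-mass order.  Raises
    :class:`InfeasibleCompositionError` naming the binding constraint when no
    grid point works.  Refining the grid step can only ever find a smaller or
    equal s*, never a larger one, because every coarse grid point remains on
    the refined grid when the refinement divides the step.
    """
    config = config or BuilderConfig()
    a = np.asarray(per_box_abundances, dtype=float)
    m = np.asarray(masses, dtype=float)
    if a.size == 0:
        raise ValueError("empty ranking")
    if a.size != m.size or a.size != len(ids):
        raise ValueError("ids, abundances and masses must have equal length")

    ratio_ever = False
    density_ever = False
    for s in config.grid():
        copies = _copies_vector(a, s)
        cum_mass = np.cumsum(copies * m)
        rib_cyt, density = _achieved(cum_mass, params)
        ratio_ok = (
            np.abs(rib_cyt - params.target_rib_cyt) / params.target_rib_cyt
            <= config.ratio_tolerance
        )
        density_ok = (
            np.abs(density - params.target_density_g_per_l)
            / params.target_density_g_per_l
            <= config.density_tolerance
        )
        ratio_ever = ratio_ever or bool(ratio_ok.any())
        density_ever = density_ever or bool(density_ok.any())
        ok = np.flatnonzero(ratio_ok & density_ok)
        if ok.size:
            return _assemble(ids, a, m, float(s), int(ok[0]) + 1, params)

    if not ratio_ever and not density_ever:
        binding = "both"
    elif not ratio_ever:
        binding = "rib_cyt_ratio"
    elif not density_ever:
        binding = "density"
    else:
        binding = "joint"
    raise InfeasibleCompositionError(
        f"no (s, K) on the grid [{config.s_min}, {config.s_max}] step {config.s_step} "
        f"satisfies the constraints (binding constraint: {binding}); "
        f"targets rib/cyt={params.target_rib_cyt} +/- {config.ratio_tolerance:.0%}, "
        f"density={params.target_density_g_per_l} g/L +/- {config.density_tolerance:.0%}",
        binding_constraint=binding,
    )


def self_consistent_targets(
    per_box_abundances: Sequence[float],
    masses: Sequence[float],
    params: CellParameters,
) -> tuple[float, float]:
    """(density, rib/cyt) targets implied by the unrounded full proteome.

    These are the values an exact (fractional-copy, no-truncation) box built
    from the same data would achieve — useful when no independent
    experimental targets exist, e.g. for synthetic studies.
    """
    a = np.asarray(per_box_abundances, dtype=float)
    m = np.asarray(masses, dtype=float)
    total = float(np.sum(a * m))
    if total <= 0:
        raise ValueError("proteome has zero mass")
    fixed_mass = params.ribosome_total_mass_da + params.n_trna_box * params.trna_mass_da
    density = macromolecular_density(total + fixed_mass, params.box_volume_um3)
    ratio = params.ribosome_protein_mass_da / total
    return float(density), float(ratio)


def build_composition(
    matrix: pd.DataFrame,
    records: Mapping[str, ProteinRecord],
    params: CellParameters,
    config: Optional[BuilderConfig] = None,
    datasets: Optional[Sequence[str]] = None,
    abundance_statistic: str = "median",
) -> CompositionSpec:
    """End-to-end composition build from a cytoplasmic abundance matrix.

    Abundances are summarised per protein (default: median across the chosen
    ``datasets``), ranked by per-cell mass, scaled to one ribosome's share and
    passed to the minimal-scaling-factor search.  Box geometry (length, tRNA
    count) comes from ``params``.
    """
    ranked = rank_by_mass(
        matrix, dict(records), abundance_statistic=abundance_statistic, datasets=datasets
    )
    if ranked.empty:
        raise ValueError("no proteins with abundance data to build a composition from")
    a_box = per_ribosome_abundance(
        ranked["abundance"].to_numpy(), params.n_ribosomes_cell
    )
    return search_min_scaling(
        list(ranked.index),
        a_box,
        ranked["molecular_mass_da"].to_numpy(),
        params,
        config,
    )
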