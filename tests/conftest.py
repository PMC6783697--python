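"""Shared fixtures: tiny handcrafted study tables and a reference cell setup."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pandas as pd
import pytest

from cytocomp import CellParameters, SynthParams, generate_dataset


@pytest.fixture
def tiny_study(tmp_path: Path) -> dict[str, Path]:
    """A minimal well-formed three-protein, two-dataset study on disk."""
    paths = {
        "abundance_path": tmp_path / "abundances.tsv",
        "metadata_path": tmp_path / "datasets.tsv",
        "annotation_path": tmp_path / "annotations.tsv",
    }
    paths["abundance_path"].write_text(
        textwrap.dedent(
            """\
            protein_id\tDS1\tDS2
            AAA1\t100\t120
            BBB1\t50\t
            CCC1\t10\t12
            """
        )
    )
    paths["metadata_path"].write_text(
        textwrap.dedent(
            """\
            dataset_id\ttechnique\tmedium\tphase\tunits
            DS1\tMS_absolute\tSC\texponential\tmolecules_per_cell
            DS2\tGFP\tYPD\tstationary\tnormalized_units
            """
        )
    )
    paths["annotation_path"].write_text(
        textwrap.dedent(
            """\
            protein_id\tmolecular_mass_da\tcompartments\tis_ribosomal\tgo_classes
            AAA1\t50000\tcytoplasm\t0\tglycolysis
            BBB1\t30000\tcytoplasm;nucleus\t0\tglycolysis;protein folding
            CCC1\t20000\tribosome;cytoplasm\t1\tcytoplasmic translation
            """
        )
    )
    return paths


@pytest.fixture(scope="session")
def default_study():
    """One default synthetic study (seed 0), shared read-only across tests."""
    params = SynthParams(seed=0)
    matrix, annotations, metadata, truth = generate_dataset(params)
    return params, matrix, annotations, metadata, truth


@pytest.fixture
def cell_params() -> CellParameters:
    """Reference yeast-like cell parameters with example ribosome masses."""
    return CellParameters(
        ribosome_protein_mass_da=1.4e6,
        ribosome_total_mass_da=3.25e6,
        n_ribosomes_cell=150_000,
    )
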