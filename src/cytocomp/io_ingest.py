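"""Reading abundance/metadata/annotation tables and compartment filtering.

Three tab-separated files describe a study: a protein x dataset abundance
matrix, a per-dataset metadata table (technique, medium, growth phase, units)
and a per-protein annotation table (molecular mass, GO-slim compartments,
ribosomal flag, functional classes).  This module joins them into in-memory
objects, restricts the proteome to the cytoplasm by removing proteins
annotated to organelles and other excluded compartments, and ranks proteins
by their per-cell mass contribution (molecular mass x abundance).

Dialect: UTF-8, tab-delimited, one header row, '.' decimal separator, empty
cell = missing.  Protein identifiers are matched case-insensitively (they are
upper-cased on read); no alias or synonym resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TECHNIQUES = ("MS_absolute", "MS_normalized", "GFP", "TAP")

#: Compartments whose proteins are removed from the cytoplasmic set.
DEFAULT_EXCLUDED_COMPARTMENTS = frozenset(
    {
        "nucleus",
        "cell wall",
        "ribosome",
        "mitochondrion",
        "endoplasmic reticulum",
        "vacuole",
    }
)


class FormatError(ValueError):
    """A table violates the expected dialect or vocabulary."""


@dataclass(frozen=True)
class ProteinRecord:
    """Identity and annotation of a single protein."""

    id: str
    molecular_mass_da: float
    compartments: frozenset[str]
    is_ribosomal: bool
    go_classes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.molecular_mass_da <= 0:
            raise ValueError(
                f"protein {self.id}: molecular mass must be positive, "
                f"got {self.molecular_mass_da}"
            )


@dataclass(frozen=True)
class DatasetMeta:
    """Provenance of one abundance column."""

    id: str
    technique: str
    medium: str
    phase: str
    units: str

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise FormatError(
                f"dataset {self.id}: unknown technique {self.technique!r}; "
                f"expected one of {TECHNIQUES}"
            )


@dataclass
class CytoplasmPartition:
    """Result of compartment filtering.

    ``cytoplasmic`` holds the non-ribosomal proteins retained for the
    simulation-cell composition; ``ribosomal`` holds the ribosomal proteins,
    kept apart for stoichiometry analysis and never mixed back into the
    cytoplasmic set; ``excluded_ids`` are the organelle-annotated proteins
    that were dropped.  Cytoplasmic + ribosomal + excluded partition the input.
    """

    cytoplasmic_matrix: pd.DataFrame
    cytoplasmic_records: list[ProteinRecord]
    ribosomal_matrix: pd.DataFrame
    ribosomal_records: list[ProteinRecord]
    excluded_ids: list[str]


def _split_semicolons(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(part.strip() for part in str(cell).split(";") if part.strip())


def read_tables(
    abundance_path: str | Path,
    metadata_path: str | Path,
    annotation_path: str | Path,
) -> tuple[pd.DataFrame, list[DatasetMeta], dict[str, ProteinRecord]]:
    """Read and join the three study tables.

    Returns the abundance matrix (rows = protein ids, columns = dataset ids,
    NaN = missing), the dataset metadata and a mapping of protein id to
    annotation record.  Proteins present in the abundance table but absent
    from the annotation table are dropped with a warning naming them; row and
    column order is otherwise preserved from the input files.
    """
    abundance = pd.read_csv(abundance_path, sep="\t", dtype={"protein_id": str})
    if "protein_id" not in abundance.columns:
        raise FormatError(f"{abundance_path}: missing 'protein_id' column")
    abundance["protein_id"] = abundance["protein_id"].str.upper()
    dupes = abundance["protein_id"][abundance["protein_id"].duplicated()]
    if not dupes.empty:
        raise FormatError(
            f"{abundance_path}: duplicate protein ids {sorted(set(dupes))}"
        )
    matrix = abundance.set_index("protein_id").astype(float)

    for col in matrix.columns:
        bad = matrix.index[matrix[col] < 0]
        if len(bad):
            raise ValueError(
                f"{abundance_path}: negative abundance for protein {bad[0]!r} "
                f"in dataset {col!r}"
            )

    meta_df = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"dataset_id", "technique", "medium", "phase", "units"}
    if not required.issubset(meta_df.columns):
        raise FormatError(
            f"{metadata_path}: missing columns {sorted(required - set(meta_df.columns))}"
        )
    if meta_df["dataset_id"].duplicated().any():
        raise FormatError(f"{metadata_path}: duplicate dataset ids")
    metadata = [
        DatasetMeta(
            id=row.dataset_id,
            technique=row.technique,
            medium=row.medium,
            phase=row.phase,
            units=row.units,
        )
        for row in meta_df.itertuples()
    ]
    meta_ids = {m.id for m in metadata}
    unmatched = [c for c in matrix.columns if c not in meta_ids]
    if unmatched:
        raise FormatError(
            f"{abundance_path}: dataset columns {unmatched} absent from metadata"
        )

    ann_df = pd.read_csv(annotation_path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "molecular_mass_da", "compartments", "is_ribosomal"}
    if not required.issubset(ann_df.columns):
        raise FormatError(
            f"{annotation_path}: missing columns {sorted(required - set(ann_df.columns))}"
        )
    ann_df["protein_id"] = ann_df["protein_id"].str.upper()
    if ann_df["protein_id"].duplicated().any():
        raise FormatError(f"{annotation_path}: duplicate protein ids")
    records: dict[str, ProteinRecord] = {}
    for row in ann_df.itertuples():
        records[row.protein_id] = ProteinRecord(
            id=row.protein_id,
            molecular_mass_da=float(row.molecular_mass_da),
            compartments=_split_semicolons(row.compartments),
            is_ribosomal=bool(int(row.is_ribosomal)),
            go_classes=_split_semicolons(getattr(row, "go_classes", "")),
        )

    unannotated = [pid for pid in matrix.index if pid not in records]
    if unannotated:
        logger.warning(
            "dropping %d protein(s) without annotation: %s",
            len(unannotated),
            ", ".join(unannotated),
        )
        matrix = matrix.drop(index=unannotated)

    all_missing = matrix.index[matrix.isna().all(axis=1)]
    if len(all_missing):
        logger.warning(
            "dropping %d protein(s) with no abundance value in any dataset: %s",
            len(all_missing),
            ", ".join(all_missing),
        )
        matrix = matrix.drop(index=all_missing)

    kept = {pid: rec for pid, rec in records.items() if pid in set(matrix.index)}
    return matrix, metadata, kept


def filter_cytoplasmic(
    records: dict[str, ProteinRecord] | Iterable[ProteinRecord],
    matrix: pd.DataFrame,
    excluded_compartments: Iterable[str] = DEFAULT_EXCLUDED_COMPARTMENTS,
) -> CytoplasmPartition:
    """Partition proteins into cytoplasmic, ribosomal and excluded sets.

    A non-ribosomal protein is removed iff its compartment set intersects
    ``excluded_compartments`` — a protein annotated to both the cytoplasm and
    an organelle is excluded, the conservative choice that avoids counting
    organellar mass as cytoplasmic.  Ribosomal proteins are always routed to
    the separate ribosomal set (their compartment annotation includes the
    ribosome itself), which feeds stoichiometry analysis only.
    """
    excluded_set = {c.strip() for c in excluded_compartments}
    if not excluded_set:
        raise ValueError("excluded_compartments must be non-empty")
    if not isinstance(records, dict):
        records = {r.id: r for r in records}

    cyto_ids: list[str] = []
    rib_ids: list[str] = []
    dropped: list[str] = []
    for pid in matrix.index:
        rec = records.get(pid)
        if rec is None:
            dropped.append(pid)
            continue
        if rec.is_ribosomal:
            rib_ids.append(pid)
        elif rec.compartments & excluded_set:
            dropped.append(pid)
        else:
            cyto_ids.append(pid)

    return CytoplasmPartition(
        cytoplasmic_matrix=matrix.loc[cyto_ids],
        cytoplasmic_records=[records[p] for p in cyto_ids],
        ribosomal_matrix=matrix.loc[rib_ids],
        ribosomal_records=[records[p] for p in rib_ids],
        excluded_ids=dropped,
    )


def rank_by_mass(
    matrix: pd.DataFrame,
    records: dict[str, ProteinRecord] | Iterable[ProteinRecord],
    abundance_statistic: str = "median",
    datasets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Rank proteins by per-cell mass = molecular mass x abundance.

    ``abundance_statistic`` is either ``"median"`` (per-protein median across
    the chosen ``datasets``, the default measure of abundance) or the id of a
    single dataset column.  Proteins with no non-missing abundance among the
    chosen datasets are excluded with a warning.  The result is sorted by
    descending mass, ties broken by protein id (lexicographic), with columns
    ``abundance``, ``molecular_mass_da`` and ``mass_da``.
    """
    if not isinstance(records, dict):
        records = {r.id: r for r in records}
    sub = matrix if datasets is None else matrix[list(datasets)]
    if abundance_statistic == "median":
        abundance = sub.median(axis=1, skipna=True)
    elif abundance_statistic in matrix.columns:
        abundance = matrix[abundance_statistic]
    else:
        raise ValueError(
            f"abundance_statistic must be 'median' or a dataset id, "
            f"got {abundance_statistic!r}"
        )

    missing = abundance.index[abundance.isna()]
    if len(missing):
        logger.warning(
            "excluding %d protein(s) with no abundance in the chosen datasets",
            len(missing),
        )
    abundance = abundance.dropna()

    masses = pd.Series({pid: records[pid].molecular_mass_da for pid in abundance.index})
    ranked = pd.DataFrame(
        {
            "abundance": abundance,
            "molecular_mass_da": masses,
            "mass_da": abundance * masses,
        }
    )
    # descending mass; ties broken by ascending id via a stable sort
    ranked = ranked.sort_index().sort_values("mass_da", ascending=False, kind="stable")
    ranked.index.name = "protein_id"
    return ranked


def cumulative_mass_fraction(ranked: pd.DataFrame, n: int) -> float:
    """Fraction of total per-cell protein mass carried by the top ``n`` proteins."""
    if len(ranked) == 0:
        raise ValueError("empty ranking")
    if not (1 <= n <= len(ranked)):
        raise ValueError(f"n must be in [1, {len(ranked)}], got {n}")
    total = float(ranked["mass_da"].sum())
    return float(ranked["mass_da"].iloc[:n].sum()) / total


def records_from_annotations(annotations: pd.DataFrame) -> dict[str, ProteinRecord]:
    """Build ProteinRecords from an in-memory annotation table.

    The table uses the annotations.tsv columns (protein_id,
    molecular_mass_da, compartments, is_ribosomal, go_classes); this is the
    in-memory twin of the annotation branch of :func:`read_tables`.
    """
    records = {}
    for row in annotations.itertuples():
        pid = str(row.protein_id).upper()
        if pid in records:
            raise FormatError(f"duplicate protein id {pid!r} in annotation table")
        records[pid] = ProteinRecord(
            id=pid,
            molecular_mass_da=float(row.molecular_mass_da),
            compartments=_split_semicolons(row.compartments),
            is_ribosomal=bool(int(row.is_ribosomal)),
            go_classes=_split_semicolons(getattr(row, "go_classes", "")),
        )
    return records


def default_ribosomal_proteins() -> frozenset[str]:
    """The packaged list of 79 yeast ribosomal-protein gene names.

    Family-level names (paralogs collapsed): 33 small-subunit proteins
    including ASC1 and 46 large-subunit proteins including the P-stalk
    proteins P0/P1/P2.  Override by supplying your own annotation table or
    id list when working with systematic names.
    """
    text = (
        resources.files("cytocomp.data").joinpath("ribosomal_proteins.txt").read_text()
    )
    names = frozenset(
        line.strip().upper()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    )
    return names
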