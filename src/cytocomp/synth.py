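"""Synthetic multi-dataset proteomics studies with known ground truth.

Real unified proteomics compendia integrate many datasets that differ in
measurement technique (absolute or normalized mass spectrometry, GFP-tagging
fluorescence, TAP-immunoblot), growth medium and growth phase, and that
disagree substantially in the absolute copy numbers they report.  This
generator emulates that structure with a fully known ground truth so that
every downstream stage — ingestion, concordance statistics, ribosome-count
inference and composition building — can be tested end to end:

* per-protein true abundances are log-normal (copy numbers are heavy-tailed);
* each of the 79 ribosomal proteins has true abundance equal to the true
  ribosome count (1:1 stoichiometry with the 80S ribosome);
* each technique applies a multiplicative reporting bias (separately for
  ribosomal and non-ribosomal proteins — GFP tagging is known to depress
  reported ribosomal-protein counts) and multiplicative log-normal noise
  whose scale is the technique's coefficient of variation;
* entries are masked missing completely at random.

The noise factor has log-mean zero, i.e. it is *median*-unbiased: the median
of many noisy observations converges to truth x bias, which is what makes
the median-based ribosome estimator consistent.  (Its mean is inflated by
exp(sigma^2/2), so mean-based estimates carry a small known upward bias.)

Default technique CVs (MS 0.69, GFP 1.03) and biases (GFP ribosomal bias
0.4, normalized-MS bias 0.25) reproduce the qualitative pattern seen in real
yeast compendia: GFP datasets noisier for ribosomal proteins and
under-reporting them, normalized MS datasets yielding far lower apparent
ribosome counts than absolute MS.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_ingest import DEFAULT_EXCLUDED_COMPARTMENTS, TECHNIQUES


class ParameterError(ValueError):
    """A synthetic-study parameter is out of its valid range."""


@dataclass(frozen=True)
class TechniqueModel:
    """Reporting behaviour of one measurement technique."""

    bias: float = 1.0            # multiplicative bias, non-ribosomal proteins
    ribosomal_bias: float = 1.0  # multiplicative bias, ribosomal proteins
    cv: float = 0.5              # coefficient of variation of the noise factor


@dataclass(frozen=True)
class DatasetSpec:
    """One dataset column: identity plus experimental provenance labels."""

    id: str
    technique: str
    medium: str = "SC"
    phase: str = "exponential"

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ParameterError(
                f"datasets: unknown technique {self.technique!r} for {self.id}"
            )


def default_technique_models() -> dict[str, TechniqueModel]:
    return {
        "MS_absolute": TechniqueModel(bias=1.0, ribosomal_bias=1.0, cv=0.69),
        "MS_normalized": TechniqueModel(bias=0.25, ribosomal_bias=0.25, cv=0.69),
        "GFP": TechniqueModel(bias=0.8, ribosomal_bias=0.4, cv=1.03),
        "TAP": TechniqueModel(bias=1.0, ribosomal_bias=1.0, cv=0.8),
    }


def default_datasets() -> list[DatasetSpec]:
    """A 21-dataset layout: 5 absolute-MS, 6 normalized-MS, 9 GFP, 1 TAP."""
    media = ["SC", "YPD", "SD"]
    phases = ["exponential", "stationary"]
    specs = []
    for i in range(5):
        specs.append(DatasetSpec(f"MS{i+1:02d}", "MS_absolute", media[i % 3], phases[i % 2]))
    for i in range(6):
        specs.append(DatasetSpec(f"MSN{i+1:02d}", "MS_normalized", media[i % 3], phases[i % 2]))
    for i in range(9):
        specs.append(DatasetSpec(f"GFP{i+1:02d}", "GFP", media[i % 3], phases[i % 2]))
    specs.append(DatasetSpec("TAP01", "TAP", "YPD", "exponential"))
    return specs


#: small functional-class vocabulary for synthetic GO annotations
GO_CLASS_VOCABULARY = (
    "glycolysis",
    "amino acid biosynthesis",
    "protein folding",
    "proteolysis",
    "oxidative stress response",
    "lipid metabolism",
    "nucleotide metabolism",
    "vesicle transport",
    "signal transduction",
    "carbohydrate metabolism",
    "tRNA aminoacylation",
    "cytoskeleton organization",
)

RIBOSOMAL_GO_CLASSES = ("cytoplasmic translation", "structural constituent of ribosome")


@dataclass
class SynthParams:
    """Parameters of a synthetic multi-dataset proteomics study.

    Defaults emulate a yeast-like study: 400 proteins of which 79 are
    ribosomal, 21 datasets across four techniques, a true ribosome count of
    150,000 per cell, log-normal copy numbers with median 36,500 copies/cell
    and log-sd 1.2, protein masses uniform on 5-100 kDa, 25% missing entries
    and 25% of non-ribosomal proteins annotated to excluded compartments.

    The abundance scale is set so that the expected per-ribosome share of
    cytoplasmic protein mass (~6 MDa against a 1.4 MDa ribosomal protein
    complement) puts the implied rib/cyt ratio near the experimental ~0.22,
    i.e. the synthetic cell is a scaled-down but physically sensible yeast.
    """

    n_proteins: int = 400
    n_ribosomal: int = 79
    datasets: Sequence[DatasetSpec] = field(default_factory=default_datasets)
    true_ribosome_count: float = 150_000.0
    abundance_logmean: float = math.log(36_500.0)
    abundance_logsd: float = 1.2
    technique_models: dict[str, TechniqueModel] = field(
        default_factory=default_technique_models
    )
    missing_rate: float = 0.25
    mass_range: tuple[float, float] = (5_000.0, 100_000.0)
    noncytoplasmic_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0:
            raise ParameterError(f"n_proteins must be positive, got {self.n_proteins}")
        if not (0 < self.n_ribosomal <= self.n_proteins):
            raise ParameterError(
                f"n_ribosomal must be in (0, n_proteins], got {self.n_ribosomal}"
            )
        if not self.datasets:
            raise ParameterError("datasets must be non-empty")
        ids = [d.id for d in self.datasets]
        if len(set(ids)) != len(ids):
            raise ParameterError("datasets: ids must be unique")
        if self.true_ribosome_count <= 0:
            raise ParameterError(
                f"true_ribosome_count must be positive, got {self.true_ribosome_count}"
            )
        if self.abundance_logsd < 0:
            raise ParameterError(
                f"abundance_logsd must be non-negative, got {self.abundance_logsd}"
            )
        for tech, model in self.technique_models.items():
            if model.bias <= 0 or model.ribosomal_bias <= 0:
                raise ParameterError(f"technique_models[{tech}]: biases must be positive")
            if model.cv < 0:
                raise ParameterError(f"technique_models[{tech}]: cv must be non-negative")
        if not (0 <= self.missing_rate < 1):
            raise ParameterError(
                f"missing_rate must be in [0, 1), got {self.missing_rate}"
            )
        lo, hi = self.mass_range
        if not (0 < lo <= hi):
            raise ParameterError(f"mass_range must satisfy 0 < min <= max, got {self.mass_range}")
        if not (0 <= self.noncytoplasmic_fraction < 1):
            raise ParameterError(
                "noncytoplasmic_fraction must be in [0, 1), "
                f"got {self.noncytoplasmic_fraction}"
            )
        missing_models = {d.technique for d in self.datasets} - set(self.technique_models)
        if missing_models:
            raise ParameterError(
                f"technique_models: no model for technique(s) {sorted(missing_models)}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth recorded alongside a generated study."""

    seed: int
    true_ribosome_count: float
    dataset_bias: dict[str, dict[str, float]]  # id -> {bias, ribosomal_bias, cv}
    true_abundance: dict[str, float]           # protein id -> copies per cell

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _noise_sigma(cv: float) -> float:
    """Log-sd of a log-normal factor with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def generate_dataset(
    params: SynthParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one synthetic study.

    Returns (abundance matrix, annotation table, dataset metadata table,
    truth).  The abundance matrix has protein ids as index and dataset ids as
    columns, NaN marking missing entries; the annotation and metadata tables
    follow the TSV dialects used by :mod:`cytocomp.io_ingest`.  Identical
    parameters (including seed) give byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    n, n_rib = params.n_proteins, params.n_ribosomal
    n_nonrib = n - n_rib

    rib_ids = [f"RIB{i+1:03d}" for i in range(n_rib)]
    other_ids = [f"PRO{i+1:04d}" for i in range(n_nonrib)]
    ids = rib_ids + other_ids
    is_rib = np.array([True] * n_rib + [False] * n_nonrib)

    true_abundance = np.empty(n)
    true_abundance[:n_rib] = params.true_ribosome_count
    true_abundance[n_rib:] = rng.lognormal(
        mean=params.abundance_logmean, sigma=params.abundance_logsd, size=n_nonrib
    )

    lo, hi = params.mass_range
    masses = rng.uniform(lo, hi, size=n)

    # compartments: ribosomal proteins carry the ribosome compartment; a
    # configurable fraction of the rest is assigned to an excluded compartment
    excluded_pool = sorted(DEFAULT_EXCLUDED_COMPARTMENTS - {"ribosome"})
    n_noncyto = int(round(params.noncytoplasmic_fraction * n_nonrib))
    noncyto_idx = set(rng.choice(n_nonrib, size=n_noncyto, replace=False).tolist())
    compartments = []
    for i in range(n):
        if is_rib[i]:
            compartments.append("ribosome;cytoplasm")
        elif (i - n_rib) in noncyto_idx:
            comp = excluded_pool[int(rng.integers(len(excluded_pool)))]
            # some organellar proteins are dual-localized; the filter must
            # still exclude them
            dual = rng.random() < 0.3
            compartments.append(f"{comp};cytoplasm" if dual else comp)
        else:
            compartments.append("cytoplasm")

    go_classes = []
    for i in range(n):
        if is_rib[i]:
            go_classes.append(";".join(RIBOSOMAL_GO_CLASSES))
        else:
            k = int(rng.integers(1, 4))
            chosen = rng.choice(len(GO_CLASS_VOCABULARY), size=k, replace=False)
            go_classes.append(";".join(GO_CLASS_VOCABULARY[j] for j in sorted(chosen)))

    annotations = pd.DataFrame(
        {
            "protein_id": ids,
            "molecular_mass_da": masses,
            "compartments": compartments,
            "is_ribosomal": is_rib.astype(int),
            "go_classes": go_classes,
        }
    )

    metadata = pd.DataFrame(
        {
            "dataset_id": [d.id for d in params.datasets],
            "technique": [d.technique for d in params.datasets],
            "medium": [d.medium for d in params.datasets],
            "phase": [d.phase for d in params.datasets],
            "units": [
                "molecules_per_cell" if d.technique == "MS_absolute" else "normalized_units"
                for d in params.datasets
            ],
        }
    )

    values = {}
    dataset_bias = {}
    for spec in params.datasets:
        model = params.technique_models[spec.technique]
        bias = np.where(is_rib, model.ribosomal_bias, model.bias)
        sigma = _noise_sigma(model.cv)
        noise = np.exp(sigma * rng.standard_normal(n))  # log-mean 0: median-unbiased
        col = true_abundance * bias * noise
        if params.missing_rate > 0:
            mask = rng.random(n) < params.missing_rate
            col = np.where(mask, np.nan, col)
        values[spec.id] = col
        dataset_bias[spec.id] = {
            "bias": model.bias,
            "ribosomal_bias": model.ribosomal_bias,
            "cv": model.cv,
        }
    matrix = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"))

    # guarantee every protein retains at least one observation
    all_missing = matrix.isna().all(axis=1)
    if all_missing.any():
        cols = list(matrix.columns)
        for pid in matrix.index[all_missing]:
            keep = cols[int(rng.integers(len(cols)))]
            row_pos = matrix.index.get_loc(pid)
            model = params.technique_models[
                params.datasets[cols.index(keep)].technique
            ]
            bias = model.ribosomal_bias if is_rib[row_pos] else model.bias
            sigma = _noise_sigma(model.cv)
            matrix.loc[pid, keep] = (
                true_abundance[row_pos] * bias * math.exp(sigma * rng.standard_normal())
            )

    truth = SyntheticTruth(
        seed=params.seed,
        true_ribosome_count=params.true_ribosome_count,
        dataset_bias=dataset_bias,
        true_abundance={pid: float(a) for pid, a in zip(ids, true_abundance)},
    )
    return matrix, annotations, metadata, truth


def write_study(
    matrix: pd.DataFrame,
    annotations: pd.DataFrame,
    metadata: pd.DataFrame,
    truth: Optional[SyntheticTruth],
    out_dir: str | Path,
) -> None:
    """Write a study as abundances.tsv / annotations.tsv / datasets.tsv
    (+ truth.json when truth is given) in the ingest TSV dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(out / "abundances.tsv", sep="\t", index=True, na_rep="")
    annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
    metadata.to_csv(out / "datasets.tsv", sep="\t", index=False)
    if truth is not None:
        truth.to_json(out / "truth.json")
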