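"""End-to-end pipeline: synth (optional) -> ingest -> concordance ->
cell parameters -> composition, plus a human-readable run report.

One configuration object drives everything; each stage writes its artifacts
into a subdirectory of the output directory and logs what it consumed.  The
report renderer only reads artifact files back — it never recomputes, so
every number in the report traces to a file on disk.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import synth as synth_mod
from .cell_model import CellParameters
from .composition import BuilderConfig, build_composition, per_ribosome_abundance, self_consistent_targets
from .concordance import estimate_ribosome_count, run_concordance
from .io_ingest import filter_cytoplasmic, rank_by_mass, read_tables

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``synthesize`` is true (a synthetic study is generated under the
    output directory) or the three input table paths must point to existing
    files.  ``selected_datasets`` names the dataset ids used for abundance
    summarisation and composition building; when empty, all MS_absolute
    datasets are selected.  ``targets`` chooses where the density and rib/cyt
    targets come from: the cell config itself, or self-consistently from the
    ingested proteome.
    """

    out_dir: str = "cytocomp_run"
    synthesize: bool = True
    seed: int = 0
    abundances: Optional[str] = None
    datasets: Optional[str] = None
    annotations: Optional[str] = None
    selected_datasets: list[str] = field(default_factory=list)
    alpha: float = 0.05
    top_n: int = 200
    targets: str = "self_consistent"  # or "config"
    ribosomes_from: str = "estimate"  # or a number (copies per cell)
    ribosome_estimate_method: str = "pooled"
    # CellParameters fields; the per-ribosome masses have no library-level
    # defaults, so the run config must state them (these are the literature
    # approximations from the packaged example config: ~1.4 MDa protein,
    # ~3.25 MDa with rRNA)
    cell: dict = field(
        default_factory=lambda: {
            "ribosome_protein_mass_da": 1.4e6,
            "ribosome_total_mass_da": 3.25e6,
        }
    )
    builder: dict = field(default_factory=dict)   # BuilderConfig fields
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise PipelineError(f"config {path} must be a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        if self.targets not in ("self_consistent", "config"):
            raise PipelineError(f"targets must be 'self_consistent' or 'config', got {self.targets!r}")
        if not self.synthesize:
            for name in ("abundances", "datasets", "annotations"):
                path = getattr(self, name)
                if path is None or not Path(path).exists():
                    raise PipelineError(f"input file for {name!r} missing: {path}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory.

    Artifacts: ``input/`` (synthetic study, when generated), ``ingest/``
    (filtered matrices), ``concordance/`` (the report TSVs), ``params.json``
    and ``composition/`` (composition.tsv + summary.json).
    """
    config.validate()
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: synth / input ------------------------------------------------
    if config.synthesize:
        params = synth_mod.SynthParams(seed=config.seed)
        matrix_in, annotations, metadata_df, truth = synth_mod.generate_dataset(params)
        input_dir = out / "input"
        synth_mod.write_study(matrix_in, annotations, metadata_df, truth, input_dir)
        abundances = input_dir / "abundances.tsv"
        datasets = input_dir / "datasets.tsv"
        annotations_path = input_dir / "annotations.tsv"
        logger.info("synth: generated %d proteins x %d datasets (seed %d)",
                    len(matrix_in), matrix_in.shape[1], config.seed)
    else:
        abundances, datasets, annotations_path = (
            Path(config.abundances), Path(config.datasets), Path(config.annotations)
        )

    # --- stage: ingest -------------------------------------------------------
    try:
        matrix, metadata, records = read_tables(abundances, datasets, annotations_path)
    except Exception as exc:
        raise PipelineError(f"ingest: {exc}") from exc
    part = filter_cytoplasmic(records, matrix)
    ingest_dir = out / "ingest"
    ingest_dir.mkdir(exist_ok=True)
    part.cytoplasmic_matrix.to_csv(ingest_dir / "cytoplasmic_abundances.tsv", sep="\t")
    part.ribosomal_matrix.to_csv(ingest_dir / "ribosomal_abundances.tsv", sep="\t")
    (ingest_dir / "excluded_ids.txt").write_text("\n".join(part.excluded_ids) + "\n")
    logger.info(
        "ingest: %d cytoplasmic, %d ribosomal, %d excluded proteins across %d datasets",
        len(part.cytoplasmic_matrix), len(part.ribosomal_matrix),
        len(part.excluded_ids), matrix.shape[1],
    )

    selected = list(config.selected_datasets) or [
        m.id for m in metadata if m.technique == "MS_absolute"
    ]
    missing = set(selected) - set(matrix.columns)
    if missing:
        raise PipelineError(f"ingest: selected datasets absent from matrix: {sorted(missing)}")

    # --- stage: concordance --------------------------------------------------
    try:
        report = run_concordance(matrix, metadata, records,
                                 alpha=config.alpha, top_n=config.top_n)
    except Exception as exc:
        raise PipelineError(f"concordance: {exc}") from exc
    report.write(out / "concordance")
    logger.info("concordance: %d pairwise tests at alpha %.3g",
                report.pairwise_welch.n_pairs, config.alpha)

    # --- stage: cell parameters ----------------------------------------------
    rib_ids = [pid for pid, rec in records.items() if rec.is_ribosomal]
    if config.ribosomes_from == "estimate":
        n_rib = estimate_ribosome_count(
            matrix, rib_ids, datasets=selected, method=config.ribosome_estimate_method
        )
    else:
        n_rib = float(config.ribosomes_from)
    try:
        cell_params = CellParameters(n_ribosomes_cell=n_rib, **config.cell)
    except TypeError as exc:
        raise PipelineError(f"cell-params: {exc}") from exc
    logger.info("cell-params: %d ribosomes/cell, box %.1f A, %d tRNA/box",
                n_rib, cell_params.box_length_angstrom, cell_params.n_trna_box)

    # --- stage: composition --------------------------------------------------
    builder = BuilderConfig(**config.builder)
    if config.targets == "self_consistent":
        ranked = rank_by_mass(part.cytoplasmic_matrix, records,
                              abundance_statistic="median", datasets=selected)
        a_box = per_ribosome_abundance(ranked["abundance"].to_numpy(), n_rib)
        density, ratio = self_consistent_targets(
            a_box, ranked["molecular_mass_da"].to_numpy(), cell_params
        )
        cell_params = CellParameters(
            n_ribosomes_cell=n_rib,
            **{**config.cell,
               "target_density_g_per_l": density, "target_rib_cyt": ratio},
        )
        logger.info("cell-params: self-consistent targets density=%.2f g/L rib/cyt=%.4f",
                    density, ratio)
    cell_params.to_json(out / "params.json")

    try:
        spec = build_composition(
            part.cytoplasmic_matrix, records, cell_params, builder, datasets=selected
        )
    except Exception as exc:
        raise PipelineError(f"build: {exc}") from exc
    spec.write(out / "composition")
    logger.info(
        "build: feasible at s=%.3f with %d types / %d molecules "
        "(density %.2f g/L, rib/cyt %.4f)",
        spec.scaling_factor, spec.n_types, spec.n_molecules,
        spec.achieved_density_g_per_l, spec.achieved_rib_cyt,
    )
    return out


def render_report(artifacts_dir: str | Path) -> str:
    """Render a markdown run report from the artifact files.

    Missing artifacts are listed as absent; the report is still produced.
    Every number comes straight from a file — nothing is recomputed here.
    """
    root = Path(artifacts_dir)
    lines = ["# cytocomp run report", ""]
    absent: list[str] = []

    cv_path = root / "concordance" / "cv_summary.tsv"
    if cv_path.exists():
        cv = pd.read_csv(cv_path, sep="\t")
        lines += ["## Coefficients of variation", ""]
        for row in cv.itertuples():
            lines.append(f"- {row.group}: {row.mean_cv_percent:.1f}%")
        lines.append("")
    else:
        absent.append("concordance/cv_summary.tsv")

    est_path = root / "concordance" / "ribosome_estimates.tsv"
    if est_path.exists():
        est = pd.read_csv(est_path, sep="\t")
        avail = est[est["available"]]
        lines += ["## Ribosome estimates", ""]
        if len(avail):
            lines.append(
                f"- {len(avail)}/{len(est)} datasets usable; per-dataset estimates "
                f"range {avail['value'].min():,.0f} - {avail['value'].max():,.0f} ribosomes/cell"
            )
        lines.append("")
    else:
        absent.append("concordance/ribosome_estimates.tsv")

    for test in ("welch", "mwu"):
        p = root / "concordance" / f"pairwise_{test}.tsv"
        if p.exists():
            tab = pd.read_csv(p, sep="\t")
            lines += [
                f"## Pairwise {test} tests",
                "",
                f"- {len(tab)} pairs; significant under Bonferroni: "
                f"{int(tab['bonferroni_sig'].sum())}; under Benjamini-Hochberg: "
                f"{int(tab['bh_sig'].sum())}",
                "",
            ]
        else:
            absent.append(f"concordance/pairwise_{test}.tsv")

    for name in ("ontology_pearson", "ontology_jaccard"):
        p = root / "concordance" / f"{name}.tsv"
        if p.exists():
            mat = pd.read_csv(p, sep="\t", index_col=0)
            vals = mat.where(~pd.DataFrame(
                [[a == b for b in mat.columns] for a in mat.index],
                index=mat.index, columns=mat.columns)).stack()
            if len(vals):
                lines += [
                    f"## {name.replace('_', ' ').title()}",
                    "",
                    f"- off-diagonal range {vals.min():.3f} - {vals.max():.3f}",
                    "",
                ]
        else:
            absent.append(f"concordance/{name}.tsv")

    summary_path = root / "composition" / "summary.json"
    if summary_path.exists():
        s = json.loads(summary_path.read_text())
        lines += [
            "## Simulation-cell composition",
            "",
            f"- scaling factor: {s['scaling_factor']:.3f}",
            f"- protein types / molecules: {s['n_types']} / {s['n_molecules']}",
            f"- tRNAs: {s['n_trna']}; box length: {s['box_length_angstrom']:.1f} A",
            f"- density: {s['achieved_density_g_per_l']:.2f} g/L "
            f"(target {s['target_density_g_per_l']:.2f})",
            f"- rib/cyt: {s['achieved_rib_cyt']:.4f} (target {s['target_rib_cyt']:.4f})",
            f"- feasible: {s['feasible']}",
            "",
        ]
    else:
        absent.append("composition/summary.json")

    if absent:
        lines += ["## Missing artifacts", ""] + [f"- {a}" for a in absent] + [""]
    return "\n".join(lines)
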