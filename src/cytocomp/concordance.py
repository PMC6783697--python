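"""Cross-dataset concordance statistics for proteomics abundance tables.

Proteomics datasets for the same organism disagree widely in the absolute
copy numbers they report, even when the functional make-up of their most
abundant proteins is similar.  This module quantifies that (dis)agreement:

* coefficients of variation of protein abundance across datasets and, for
  ribosomal proteins, across proteins within each dataset;
* per-dataset ribosome-count estimates, exploiting the 1:1 stoichiometry of
  each of the 79 ribosomal proteins with the 80S ribosome — every ribosomal
  protein's abundance is an independent observation of the cellular ribosome
  count;
* pairwise two-sample tests (Welch's unequal-variance t, Mann-Whitney U)
  between datasets with Bonferroni and Benjamini-Hochberg multiple-testing
  control;
* similarity of gene-ontology profiles of the top-by-mass proteins (Pearson
  correlation of class counts, Jaccard index of class sets);
* median-divergence screening between dataset groups (e.g. GFP vs MS).

Missing values are dropped pairwise per computation and never imputed.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_ingest import DatasetMeta, ProteinRecord, rank_by_mass

logger = logging.getLogger(__name__)

#: combined sample size at or below which the Mann-Whitney p-value is exact
EXACT_MWU_MAX_N = 20


# ---------------------------------------------------------------------------
# coefficients of variation
# ---------------------------------------------------------------------------

def cv_percent(values: Iterable[float]) -> float:
    """Coefficient of variation as a percentage.

    100 x sample standard deviation (n-1 denominator) / mean, over the
    non-missing values.  Requires at least two values and a non-zero mean.
    """
    arr = np.asarray([v for v in values if not (v is None or np.isnan(v))], dtype=float)
    if arr.size < 2:
        raise ValueError(f"cv_percent needs >= 2 non-missing values, got {arr.size}")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("cv_percent undefined for zero mean")
    return 100.0 * arr.std(ddof=1) / mean


def protein_cv_across_datasets(matrix: pd.DataFrame) -> pd.Series:
    """Per-protein CV (%) of abundance across datasets.

    Proteins with fewer than two non-missing values (or zero mean) get NaN.
    """
    out = {}
    for pid, row in matrix.iterrows():
        vals = row.dropna().to_numpy(dtype=float)
        if vals.size < 2 or vals.mean() == 0:
            out[pid] = np.nan
        else:
            out[pid] = 100.0 * vals.std(ddof=1) / vals.mean()
    return pd.Series(out, name="cv_percent")


def dataset_cv(matrix: pd.DataFrame, protein_ids: Sequence[str]) -> pd.Series:
    """Per-dataset CV (%) across the given proteins (e.g. the ribosomal set)."""
    sub = matrix.loc[[p for p in protein_ids if p in matrix.index]]
    out = {}
    for col in sub.columns:
        vals = sub[col].dropna().to_numpy(dtype=float)
        out[col] = (
            100.0 * vals.std(ddof=1) / vals.mean()
            if vals.size >= 2 and vals.mean() != 0
            else np.nan
        )
    return pd.Series(out, name="cv_percent")


def technique_group_cv(
    matrix: pd.DataFrame,
    protein_ids: Sequence[str],
    metadata: Sequence[DatasetMeta],
) -> dict[str, float]:
    """Average per-dataset CV (%) by technique group.

    The per-dataset CV is computed across ``protein_ids`` (normally the
    ribosomal proteins, whose true abundances are identical), then averaged
    over the datasets of each technique.  This is the statistic whose
    ordering distinguishes internally consistent techniques (lower CV) from
    noisy ones.
    """
    per_ds = dataset_cv(matrix, protein_ids)
    groups: dict[str, list[float]] = {}
    for meta in metadata:
        if meta.id in per_ds.index and not np.isnan(per_ds[meta.id]):
            groups.setdefault(meta.technique, []).append(float(per_ds[meta.id]))
    return {tech: float(np.mean(v)) for tech, v in groups.items() if v}


# ---------------------------------------------------------------------------
# ribosome-count estimates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RibosomeEstimate:
    """Ribosome count per cell inferred from one dataset's ribosomal proteins."""

    dataset_id: str
    statistic: str  # "mean" or "median"
    value: Optional[float]
    sd: Optional[float]
    n_proteins: int

    @property
    def available(self) -> bool:
        return self.value is not None


def ribosome_estimates(
    matrix: pd.DataFrame,
    ribosomal_ids: Sequence[str],
    statistic: str = "mean",
) -> list[RibosomeEstimate]:
    """Per-dataset ribosome-count estimates from ribosomal-protein abundances.

    Each ribosomal protein is present once per ribosome, so the mean (or
    median) of the ribosomal-protein abundances reported by a dataset
    estimates the ribosome count per cell.  Datasets reporting fewer than two
    ribosomal proteins are marked unavailable (and are excluded from any
    downstream pairwise testing).
    """
    if statistic not in ("mean", "median"):
        raise ValueError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    present = [p for p in ribosomal_ids if p in matrix.index]
    sub = matrix.loc[present]
    estimates = []
    for col in sub.columns:
        vals = sub[col].dropna().to_numpy(dtype=float)
        if vals.size < 2:
            estimates.append(RibosomeEstimate(col, statistic, None, None, int(vals.size)))
            continue
        value = float(np.mean(vals)) if statistic == "mean" else float(np.median(vals))
        estimates.append(
            RibosomeEstimate(col, statistic, value, float(vals.std(ddof=1)), int(vals.size))
        )
    return estimates


def estimate_ribosome_count(
    matrix: pd.DataFrame,
    ribosomal_ids: Sequence[str],
    datasets: Optional[Sequence[str]] = None,
    method: str = "pooled",
) -> float:
    """Single ribosome-count estimate from the chosen datasets.

    ``method="pooled"`` (default) takes the median of all ribosomal
    protein x dataset values pooled together; ``method="per_protein"`` takes
    the median across proteins of each protein's median across datasets.
    Both are exposed because either reading is defensible; they coincide in
    the noise-free limit.
    """
    present = [p for p in ribosomal_ids if p in matrix.index]
    sub = matrix.loc[present]
    if datasets is not None:
        sub = sub[list(datasets)]
    if method == "pooled":
        vals = sub.to_numpy(dtype=float).ravel()
        vals = vals[~np.isnan(vals)]
        if vals.size == 0:
            raise ValueError("no ribosomal-protein abundance values available")
        return float(np.median(vals))
    if method == "per_protein":
        per_protein = sub.median(axis=1, skipna=True).dropna()
        if per_protein.empty:
            raise ValueError("no ribosomal-protein abundance values available")
        return float(per_protein.median())
    raise ValueError(f"method must be 'pooled' or 'per_protein', got {method!r}")


# ---------------------------------------------------------------------------
# two-sample tests
# ---------------------------------------------------------------------------

def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Returns (t, Welch-Satterthwaite df, p).  When both samples have zero
    variance the test is degenerate: p = 1 if the means are equal, otherwise
    the difference is treated as extreme (p = 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError(f"welch_t_test needs >= 2 values per sample, got {x.size}, {y.size}")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        warnings.warn(
            "zero variance in both samples with unequal means; reporting p = 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return math.copysign(math.inf, x.mean() - y.mean()), float(x.size + y.size - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney p by enumeration of group labelings.

    Handles ties via midranks.  Two-sided p is 2 x min(P(U <= u), P(U >= u))
    capped at 1, under the permutation distribution of U for the first sample.
    """
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)  # midranks for ties
    offset = n1 * (n1 + 1) / 2.0
    u_obs = ranks[:n1].sum() - offset
    u_all = np.array(
        [sum(ranks[i] for i in combo) - offset
         for combo in itertools.combinations(range(n1 + n2), n1)]
    )
    n_total = u_all.size
    p_le = np.count_nonzero(u_all <= u_obs + 1e-12) / n_total
    p_ge = np.count_nonzero(u_all >= u_obs - 1e-12) / n_total
    return float(u_obs), min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for the first sample, p).

    The p-value is exact (full enumeration of the permutation distribution,
    tie-aware) for combined sample sizes up to 20, and uses the normal
    approximation with tie correction beyond that.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("mann_whitney_u needs >= 1 value per sample")
    if x.size + y.size <= EXACT_MWU_MAX_N:
        return _exact_mwu_p(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


@dataclass
class PairwiseTestMatrix:
    """All-pairs test results with Bonferroni and Benjamini-Hochberg control.

    ``table`` is long-format with one row per unordered dataset pair:
    dataset_a, dataset_b, p_raw, bonferroni_sig, p_bh, bh_sig.
    """

    test: str
    alpha: float
    n_pairs: int
    table: pd.DataFrame
    excluded: list[str] = field(default_factory=list)

    @property
    def bonferroni_alpha(self) -> float:
        return self.alpha / self.n_pairs

    def square(self, column: str = "p_raw") -> pd.DataFrame:
        """Symmetric dataset x dataset matrix of the given column (diagonal NaN)."""
        ids = sorted(set(self.table["dataset_a"]) | set(self.table["dataset_b"]))
        mat = pd.DataFrame(np.nan, index=ids, columns=ids)
        for row in self.table.itertuples():
            mat.loc[row.dataset_a, row.dataset_b] = getattr(row, column)
            mat.loc[row.dataset_b, row.dataset_a] = getattr(row, column)
        return mat


def pairwise_matrix(
    samples: Mapping[str, Sequence[float]],
    test: str = "welch",
    alpha: float = 0.05,
) -> PairwiseTestMatrix:
    """Test every unordered pair of datasets for a difference in level.

    ``samples`` maps dataset id to its vector of observations (e.g. ribosomal
    protein abundances).  Datasets with fewer than two observations are
    excluded up front.  The Bonferroni flag compares each raw p against
    alpha / n_pairs; the Benjamini-Hochberg step-up adjustment is applied
    across the full vector of pair p-values and flagged at the same alpha.
    """
    if test not in ("welch", "mannwhitney"):
        raise ValueError(f"test must be 'welch' or 'mannwhitney', got {test!r}")
    min_n = 2
    usable, excluded = {}, []
    for ds, vals in samples.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[~np.isnan(arr)]
        if arr.size >= min_n:
            usable[ds] = arr
        else:
            excluded.append(ds)
    if len(usable) < 2:
        raise ValueError("pairwise_matrix needs >= 2 datasets with usable samples")
    if excluded:
        logger.warning("excluding datasets with < 2 observations: %s", excluded)

    ids = list(usable)
    pairs = list(itertools.combinations(ids, 2))
    p_raw = []
    for a, b in pairs:
        if test == "welch":
            _, _, p = welch_t_test(usable[a], usable[b])
        else:
            _, p = mann_whitney_u(usable[a], usable[b])
        p_raw.append(p)
    p_raw = np.asarray(p_raw)
    n_pairs = len(pairs)
    bonf_sig = p_raw < alpha / n_pairs
    bh_sig, p_bh, _, _ = multipletests(p_raw, alpha=alpha, method="fdr_bh")

    table = pd.DataFrame(
        {
            "dataset_a": [a for a, _ in pairs],
            "dataset_b": [b for _, b in pairs],
            "p_raw": p_raw,
            "bonferroni_sig": bonf_sig,
            "p_bh": p_bh,
            "bh_sig": bh_sig,
        }
    )
    return PairwiseTestMatrix(test=test, alpha=alpha, n_pairs=n_pairs, table=table,
                              excluded=excluded)


# ---------------------------------------------------------------------------
# ontology profiles
# ---------------------------------------------------------------------------

@dataclass
class OntologyProfile:
    """Functional-class census of one dataset's top-by-mass proteins."""

    dataset_id: str
    counts: Counter

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(c for c, n in self.counts.items() if n > 0)


def ontology_profiles(
    top_lists: Mapping[str, Sequence[str]],
    go_classes: Mapping[str, Iterable[str]],
) -> dict[str, OntologyProfile]:
    """Count, per dataset, how many of its top proteins carry each class.

    A protein contributes to every class it is annotated with; proteins with
    empty class sets contribute nothing.
    """
    profiles = {}
    for ds, proteins in top_lists.items():
        counts: Counter = Counter()
        for pid in proteins:
            for cls in go_classes.get(pid, ()):  # empty set allowed
                counts[cls] += 1
        profiles[ds] = OntologyProfile(dataset_id=ds, counts=counts)
    return profiles


def profile_pearson(p1: OntologyProfile, p2: OntologyProfile) -> Optional[float]:
    """Pearson correlation of two class-count profiles, aligned on the union
    of classes (absent class = 0).  Returns None when either aligned vector
    has zero variance or fewer than two classes exist."""
    classes = sorted(p1.classes | p2.classes)
    if len(classes) < 2:
        return None
    v1 = np.array([p1.counts.get(c, 0) for c in classes], dtype=float)
    v2 = np.array([p2.counts.get(c, 0) for c in classes], dtype=float)
    if v1.std() == 0 or v2.std() == 0:
        return None
    return float(stats.pearsonr(v1, v2).statistic)


def ontology_jaccard(set1: Iterable[str], set2: Iterable[str]) -> float:
    """Jaccard index |A n B| / |A u B|; 1.0 when both sets are empty."""
    a, b = set(set1), set(set2)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


# ---------------------------------------------------------------------------
# group screening
# ---------------------------------------------------------------------------

def median_divergence(
    medians_a: pd.Series,
    medians_b: pd.Series,
    threshold: float = 0.25,
    denominator: str = "mean",
) -> tuple[float, pd.Series]:
    """Fraction of proteins whose group medians diverge by more than
    ``threshold`` in relative terms.

    The relative difference defaults to the symmetric form
    |mA - mB| / ((mA + mB)/2); ``denominator`` may instead be ``"a"`` or
    ``"b"`` to normalise by one group.  Pairs where both medians are zero are
    non-divergent by convention; pairs with a missing median are skipped.
    Returns (divergent fraction, per-protein boolean flags).
    """
    if not (0 <= threshold):
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    joined = pd.concat([medians_a.rename("a"), medians_b.rename("b")], axis=1).dropna()
    a = joined["a"].to_numpy(dtype=float)
    b = joined["b"].to_numpy(dtype=float)
    if denominator == "mean":
        denom = (a + b) / 2.0
    elif denominator == "a":
        denom = a.copy()
    elif denominator == "b":
        denom = b.copy()
    else:
        raise ValueError(f"denominator must be 'mean', 'a' or 'b', got {denominator!r}")
    diff = np.abs(a - b)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(diff == 0, 0.0, diff / denom)
    flags = pd.Series(rel > threshold, index=joined.index, name="divergent")
    fraction = float(flags.mean()) if len(flags) else 0.0
    return fraction, flags


def extra_ribosomal_comparison(
    set_i_ids: Sequence[str],
    set_ii_ids: Sequence[str],
    matrix: pd.DataFrame,
) -> tuple[float, float]:
    """Compare two groups of ribosomal proteins (e.g. those with known
    extra-ribosomal functions vs the rest) on their cross-dataset summaries.

    Each protein is first reduced to its mean (and median) abundance across
    datasets; a Welch t-test then compares the two groups' summary vectors.
    Returns (p for means, p for medians).
    """
    for name, ids in (("set I", set_i_ids), ("set II", set_ii_ids)):
        if len(ids) < 2:
            raise ValueError(f"{name} must contain >= 2 proteins, got {len(ids)}")
    sub_i = matrix.loc[[p for p in set_i_ids if p in matrix.index]]
    sub_ii = matrix.loc[[p for p in set_ii_ids if p in matrix.index]]
    means_i = sub_i.mean(axis=1, skipna=True).dropna()
    means_ii = sub_ii.mean(axis=1, skipna=True).dropna()
    medians_i = sub_i.median(axis=1, skipna=True).dropna()
    medians_ii = sub_ii.median(axis=1, skipna=True).dropna()
    _, _, p_means = welch_t_test(means_i, means_ii)
    _, _, p_medians = welch_t_test(medians_i, medians_ii)
    return p_means, p_medians


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceReport:
    """All concordance outputs for one study, writable as a TSV directory."""

    cv_summary: pd.DataFrame
    ribosome_estimates: pd.DataFrame
    pairwise_welch: PairwiseTestMatrix
    pairwise_mwu: PairwiseTestMatrix
    ontology_pearson: pd.DataFrame
    ontology_jaccard: pd.DataFrame
    median_divergence: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.cv_summary.to_csv(out / "cv_summary.tsv", sep="\t", index=False)
        self.ribosome_estimates.to_csv(out / "ribosome_estimates.tsv", sep="\t", index=False)
        self.pairwise_welch.table.to_csv(out / "pairwise_welch.tsv", sep="\t", index=False)
        self.pairwise_mwu.table.to_csv(out / "pairwise_mwu.tsv", sep="\t", index=False)
        self.ontology_pearson.to_csv(out / "ontology_pearson.tsv", sep="\t")
        self.ontology_jaccard.to_csv(out / "ontology_jaccard.tsv", sep="\t")
        self.median_divergence.to_csv(out / "median_divergence.tsv", sep="\t", index=False)


def run_concordance(
    matrix: pd.DataFrame,
    metadata: Sequence[DatasetMeta],
    records: Mapping[str, ProteinRecord],
    alpha: float = 0.05,
    top_n: int = 200,
    divergence_threshold: float = 0.25,
) -> ConcordanceReport:
    """Run the full concordance analysis on one study's tables."""
    ribosomal_ids = [pid for pid, rec in records.items() if rec.is_ribosomal]
    cyto_ids = [pid for pid in matrix.index if pid in records and not records[pid].is_ribosomal]

    # CV summary: per-protein cross-dataset CV averaged over proteins, plus
    # per-technique average of per-dataset ribosomal CVs.
    cyto_cv = protein_cv_across_datasets(matrix.loc[cyto_ids]).dropna()
    rib_cv = protein_cv_across_datasets(matrix.loc[[p for p in ribosomal_ids if p in matrix.index]]).dropna()
    group_cv = technique_group_cv(matrix, ribosomal_ids, metadata)
    rows = [
        {"group": "cytoplasmic_proteins_across_datasets", "mean_cv_percent": float(cyto_cv.mean()) if len(cyto_cv) else np.nan},
        {"group": "ribosomal_proteins_across_datasets", "mean_cv_percent": float(rib_cv.mean()) if len(rib_cv) else np.nan},
    ]
    rows += [
        {"group": f"ribosomal_within_dataset_{tech}", "mean_cv_percent": v}
        for tech, v in sorted(group_cv.items())
    ]
    cv_summary = pd.DataFrame(rows)

    # per-dataset ribosome estimates (mean statistic, as used for the tests)
    estimates = ribosome_estimates(matrix, ribosomal_ids, statistic="mean")
    est_df = pd.DataFrame(
        [
            {
                "dataset_id": e.dataset_id,
                "statistic": e.statistic,
                "value": e.value,
                "sd": e.sd,
                "n_proteins": e.n_proteins,
                "available": e.available,
            }
            for e in estimates
        ]
    )

    # pairwise tests on the ribosomal-protein abundance vectors per dataset
    present_rib = [p for p in ribosomal_ids if p in matrix.index]
    samples = {col: matrix.loc[present_rib, col].dropna().to_numpy() for col in matrix.columns}
    welch = pairwise_matrix(samples, test="welch", alpha=alpha)
    mwu = pairwise_matrix(samples, test="mannwhitney", alpha=alpha)

    # ontology similarity of the top-N-by-mass proteins per dataset
    top_lists = {}
    for meta in metadata:
        if meta.id not in matrix.columns:
            continue
        ranked = rank_by_mass(matrix, dict(records), abundance_statistic=meta.id)
        top_lists[meta.id] = list(ranked.index[:top_n])
    go_map = {pid: rec.go_classes for pid, rec in records.items()}
    profiles = ontology_profiles(top_lists, go_map)
    ids = sorted(profiles)
    pearson = pd.DataFrame(np.nan, index=ids, columns=ids)
    jaccard = pd.DataFrame(np.nan, index=ids, columns=ids)
    for a in ids:
        for b in ids:
            r = profile_pearson(profiles[a], profiles[b])
            pearson.loc[a, b] = np.nan if r is None else r
            jaccard.loc[a, b] = ontology_jaccard(profiles[a].classes, profiles[b].classes)

    # GFP vs MS median divergence, separately for cytoplasmic and ribosomal proteins
    gfp_cols = [m.id for m in metadata if m.technique == "GFP" and m.id in matrix.columns]
    ms_cols = [
        m.id
        for m in metadata
        if m.technique in ("MS_absolute", "MS_normalized") and m.id in matrix.columns
    ]
    div_rows = []
    if gfp_cols and ms_cols:
        for label, ids_ in (("cytoplasmic", cyto_ids), ("ribosomal", present_rib)):
            med_gfp = matrix.loc[ids_, gfp_cols].median(axis=1, skipna=True)
            med_ms = matrix.loc[ids_, ms_cols].median(axis=1, skipna=True)
            frac, _ = median_divergence(med_gfp, med_ms, threshold=divergence_threshold)
            div_rows.append(
                {
                    "protein_group": label,
                    "group_a": "GFP",
                    "group_b": "MS",
                    "threshold": divergence_threshold,
                    "divergent_fraction": frac,
                }
            )
    divergence = pd.DataFrame(
        div_rows,
        columns=["protein_group", "group_a", "group_b", "threshold", "divergent_fraction"],
    )

    return ConcordanceReport(
        cv_summary=cv_summary,
        ribosome_estimates=est_df,
        pairwise_welch=welch,
        pairwise_mwu=mwu,
        ontology_pearson=pearson,
        ontology_jaccard=jaccard,
        median_divergence=divergence,
    )
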