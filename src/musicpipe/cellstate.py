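"""Per-cell transcriptome and chromatin-state metrics.

Covers the cell-level QC filter (>=100 RNA and >=5,000 DNA reads),
library-size log-normalisation, marker-based cell-type assignment for
pre-computed clusters, the LCS-erosion score read from the log-binned
distance profile (eroded above 3e5 bp), the transcriptomic-age model
(a weighted sum of ageing-gene expression z-scores), and the selection
of genes whose expression tracks the LCS-erosion score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import LogBinProfile

MIN_RNA_READS = 100
MIN_DNA_READS = 5_000
LCS_ERODED_THRESHOLD = 3e5


def filter_cells(cell_counts: pd.DataFrame) -> tuple[pd.Index, dict]:
    """QC filter on per-cell read totals.

    ``cell_counts`` needs columns ``n_rna`` and ``n_dna``; a cell is
    kept iff n_rna >= 100 and n_dna >= 5,000.
    """
    keep = (cell_counts["n_rna"] >= MIN_RNA_READS) & (
        cell_counts["n_dna"] >= MIN_DNA_READS
    )
    report = {
        "input": int(len(cell_counts)),
        "kept": int(keep.sum()),
        "removed_low_rna": int((cell_counts["n_rna"] < MIN_RNA_READS).sum()),
        "removed_low_dna": int((cell_counts["n_dna"] < MIN_DNA_READS).sum()),
    }
    return cell_counts.index[keep], report


def lognormalize(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    """Library-size normalisation then log transform.

    ``x -> ln(1 + scale * x / library_size)`` per cell (rows are cells,
    columns genes).  Cells with zero library size stay all-zero.
    """
    lib = counts.sum(axis=1).to_numpy(dtype=float)
    lib[lib == 0] = 1.0
    return np.log1p(scale * counts.div(lib, axis=0))


def assign_cell_types(
    cluster_labels: pd.Series,
    markers: Mapping[str, list[str]],
    expr: pd.DataFrame,
) -> tuple[dict, list[str]]:
    """Marker-score assignment of a cell type to each cluster.

    For cluster c and candidate type A the score is
    ``2 * mean(normalised expression of A's markers over cells of c) +
    proportion of cells of c expressing (value > 0) at least one A
    marker``; the argmax wins, ties broken lexicographically and
    logged.  Types with no marker present in the matrix are ineligible.
    """
    ties: list[str] = []
    assignment: dict = {}
    usable = {
        t: [g for g in gs if g in expr.columns] for t, gs in markers.items()
    }
    usable = {t: gs for t, gs in usable.items() if gs}
    if not usable:
        raise ValueError("no marker genes present in the expression matrix")
    for clust in sorted(cluster_labels.unique()):
        cells = cluster_labels.index[cluster_labels == clust]
        sub = expr.loc[cells]
        scores = {}
        for t, gs in usable.items():
            mean_expr = float(sub[gs].to_numpy().mean())
            prop = float((sub[gs] > 0).any(axis=1).mean())
            scores[t] = 2.0 * mean_expr + prop
        best = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best)
        if len(winners) > 1:
            ties.append(f"cluster {clust}: tie between {winners}")
        assignment[clust] = winners[0]
    return assignment, ties


# ------------------------------------------------------------ LCS erosion

@dataclass
class LcsResult:
    score: float
    eroded: bool
    low_confidence: bool  # fewer than 10 non-empty bins


def lcs_erosion(profile: LogBinProfile, top_n: int = 10) -> LcsResult:
    """LCS-erosion score: the middle of the top contact-distance bins.

    Takes the ``top_n`` log-spaced bins with the highest width-
    normalised contact frequency (ties resolved toward shorter
    distances), and scores the cell as the median of their geometric-
    mean midpoints.  Cells scoring above 3e5 bp are LCS-eroded.  Cells
    with fewer than ``top_n`` non-empty bins use all non-empty bins and
    are flagged low-confidence.
    """
    mids = profile.midpoints
    nonempty = np.nonzero(profile.values > 0)[0]
    if nonempty.size == 0:
        raise ValueError("empty profile: no contacts")
    order = sorted(nonempty, key=lambda i: (-profile.values[i], mids[i]))
    low_conf = len(order) < top_n
    top = order[: min(top_n, len(order))]
    score = float(np.median(mids[np.array(top)]))
    return LcsResult(score=score, eroded=score > LCS_ERODED_THRESHOLD, low_confidence=low_conf)


# ------------------------------------------------------ transcriptomic age

def transcriptomic_age(
    counts: pd.DataFrame,
    ageing_genes: list[str],
    sample_ids: pd.Series,
    sample_ages: Mapping[str, float],
    expr: pd.DataFrame | None = None,
) -> tuple[pd.Series, dict]:
    """Weighted z-score age of every cell from ageing-gene expression.

    Per gene: the direction is the sign of the correlation between
    per-sample mean expression and sample chronological age; the weight
    is the proportion of cells expressing the gene (raw count > 0)
    times the direction.  A cell's age is the dot product of its
    expression z-scores (over cells) with the gene weights.  Requires
    at least two distinct sample ages; zero-variance genes are skipped
    and counted.
    """
    ages = pd.Series({s: sample_ages[s] for s in sample_ids.unique()})
    if ages.nunique() < 2:
        raise ValueError("need >= 2 distinct chronological ages to sign directions")
    genes = [g for g in ageing_genes if g in counts.columns]
    if expr is None:
        expr = lognormalize(counts)
    x = expr[genes]

    by_sample = x.groupby(sample_ids).mean()
    age_vec = ages.loc[by_sample.index].to_numpy(dtype=float)
    skipped = 0
    weights = pd.Series(0.0, index=genes)
    for g in genes:
        col = x[g].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            skipped += 1
            continue
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(by_sample[g].to_numpy(dtype=float), age_vec)[0, 1]
        if not np.isfinite(r) or r == 0:
            skipped += 1
            continue
        direction = 1.0 if r > 0 else -1.0
        prop = float((counts[g] > 0).mean())
        weights[g] = prop * direction

    z = (x - x.mean(axis=0)) / x.std(axis=0, ddof=0)
    z = z.fillna(0.0)
    age = z.to_numpy() @ weights.to_numpy()
    return pd.Series(age, index=counts.index, name="transcriptomic_age"), {
        "n_genes_used": int((weights != 0).sum()),
        "n_genes_skipped": skipped,
        "weights": weights,
    }


# --------------------------------------------- LCS-associated gene selection

def lcs_gene_assoc(
    expr: pd.DataFrame,
    scores: pd.Series,
    p_threshold: float = 0.01,
    f_threshold: float = 1.0,
    rho_threshold: float = 0.1,
) -> pd.DataFrame:
    """Genes whose expression tracks the LCS-erosion score.

    Per gene: the F-test of a univariate linear regression of
    expression on score (F = t^2 of the slope, df (1, n-2)) and the
    Spearman correlation; a gene passes with P < 0.01, F > 1 and
    |rho| > 0.1.  Constant genes are skipped (NaN statistics,
    pass = False).
    """
    s = scores.loc[expr.index].to_numpy(dtype=float)
    n = len(s)
    if n < 3:
        raise ValueError("need at least 3 cells")
    rows = []
    for g in expr.columns:
        y = expr[g].to_numpy(dtype=float)
        if y.std(ddof=0) == 0 or s.std(ddof=0) == 0:
            rows.append((g, np.nan, np.nan, np.nan, False))
            continue
        r = float(np.corrcoef(s, y)[0, 1])
        r2 = min(r * r, 1.0 - 1e-15)
        f = r2 * (n - 2) / (1.0 - r2)
        p = float(stats.f.sf(f, 1, n - 2))
        rho = float(stats.spearmanr(s, y).statistic)
        passed = (p < p_threshold) and (f > f_threshold) and (abs(rho) > rho_threshold)
        rows.append((g, f, p, rho, passed))
    return pd.DataFrame(rows, columns=["gene", "F", "P", "rho", "pass"]).set_index("gene")
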