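"""Immune-transcript scores and association with dMMR signature activity.

Per-gene expression (TPM) is correlated with per-sample dMMR mutational
signature activity by Pearson's r, with Benjamini-Hochberg control over the
gene set at FDR 0.1; a gene is called *consistently* associated when it also
reaches nominal P < 0.05 within every biopsy-site stratum of sufficient size.
Also provides the 32-gene immune-checkpoint panel geometric-mean score,
pooled lymphocyte density (LD-TIL), and crude 2x2 contingency odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "checkpoint_panel",
    "load_panel",
    "geometric_mean_score",
    "pearson_with_outlier_policy",
    "bh_fdr",
    "associate_genes",
    "ldtil_density",
    "contingency_odds_ratio",
]


def load_panel(path) -> list[str]:
    """Read a gene panel file (one gene symbol per line; '#' comments)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    if len(genes) != len(set(genes)):
        raise ValueError("panel contains duplicate genes")
    return genes


def checkpoint_panel() -> list[str]:
    """The bundled 32-gene immune checkpoint / T cell activity panel."""
    ref = resources.files("dmmrkit").joinpath("data/checkpoint32.txt")
    with resources.as_file(ref) as path:
        return load_panel(path)


def geometric_mean_score(expr: pd.DataFrame, panel: list[str],
                         exclude: str | None = None, offset: float = 1.0) -> pd.Series:
    """Per-sample geometric mean of panel-gene expression.

    ``expr`` is genes x samples (TPM).  Computed as
    ``exp(mean(log(TPM + offset)))``; with ``offset=0`` this is the plain
    geometric mean (and errors on zero values), while the default offset 1
    keeps zero-inflated TPMs finite.  ``exclude`` drops one panel gene
    (e.g. scoring the other 31 genes against CD8A).
    """
    genes = [g for g in panel if g != exclude]
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {', '.join(missing)}")
    values = expr.loc[genes].to_numpy(dtype=float)
    if offset == 0 and np.any(values <= 0):
        raise ValueError("offset 0 requires strictly positive expression values")
    score = np.exp(np.log(values + offset).mean(axis=0))
    return pd.Series(score, index=expr.columns, name="panel_score")


def pearson_with_outlier_policy(x, y, policy: str = "none"):
    """Pearson r with an automated stand-in for manual outlier review.

    ``policy='none'`` is the plain two-sided Pearson test.  ``policy='robust-z'``
    fits the least-squares line, removes points whose absolute residual
    exceeds 3.5 MAD-scaled units, and recomputes; the number of removed points
    is always reported.  Returns ``(r, p, n_outliers_removed)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    removed = 0
    if policy == "robust-z":
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        mad = np.median(np.abs(resid - np.median(resid)))
        scale = 1.4826 * mad
        if scale > 0:
            inliers = np.abs(resid - np.median(resid)) / scale <= 3.5
            removed = int((~inliers).sum())
            x, y = x[inliers], y[inliers]
    elif policy != "none":
        raise ValueError(f"unknown outlier policy {policy!r}")
    if len(x) < 3:
        raise ValueError("need at least 3 points after outlier removal")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), removed


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, stable under ties)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


@dataclass
class AssociationResult:
    """Tidy per-gene association table plus the strata actually tested."""

    table: pd.DataFrame
    sites_tested: list[str]
    sites_skipped: list[str]


def associate_genes(expr: pd.DataFrame, activity: pd.Series, sites: pd.Series,
                    genes: list[str] | None = None, fdr: float = 0.1,
                    site_p: float = 0.05, min_n: int = 10,
                    outlier_policy: str = "none") -> AssociationResult:
    """Correlate each gene's expression with dMMR signature activity.

    Overall Pearson r/p per gene with BH correction across ``genes``;
    per-site r/p within each biopsy-site stratum holding >= ``min_n``
    samples (smaller strata are excluded from the consistency requirement
    and reported in ``sites_skipped``).  ``passes_overall`` is q < ``fdr``;
    ``passes_consistent`` additionally requires nominal p < ``site_p`` in
    every tested stratum.
    """
    if genes is None:
        genes = list(expr.index)
    if len(genes) == 0:
        raise ValueError("empty gene set")
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {', '.join(missing[:5])}")
    samples = [s for s in expr.columns if s in activity.index]
    act = activity.loc[samples].astype(float)
    site = pd.Series(sites).loc[samples]

    counts = site.value_counts()
    sites_tested = sorted(counts.index[counts >= min_n])
    sites_skipped = sorted(counts.index[counts < min_n])
    if len(sites_tested) < 2:
        raise ValueError(
            f"need >=2 biopsy-site strata with >= {min_n} samples; "
            f"got {sites_tested}"
        )

    rows = []
    for g in genes:
        ex = expr.loc[g, samples].astype(float)
        r, p, rem = pearson_with_outlier_policy(ex, act, policy=outlier_policy)
        row = {"gene": g, "r": r, "p": p, "outliers_removed": rem}
        for s in sites_tested:
            mask = site == s
            rs, ps, _ = pearson_with_outlier_policy(
                ex[mask.values], act[mask.values], policy=outlier_policy
            )
            row[f"r_{s}"] = rs
            row[f"p_{s}"] = ps
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene")
    table["q"] = bh_fdr(table["p"].to_numpy())
    # BH within each site as a secondary readout; the consistency flag itself
    # uses the nominal per-site p.
    for s in sites_tested:
        table[f"q_{s}"] = bh_fdr(table[f"p_{s}"].to_numpy())
    table["passes_overall"] = table["q"] < fdr
    site_ok = np.logical_and.reduce(
        [table[f"p_{s}"] < site_p for s in sites_tested]
    )
    table["passes_consistent"] = table["passes_overall"] & site_ok
    return AssociationResult(table=table, sites_tested=sites_tested,
                             sites_skipped=sites_skipped)


def ldtil_density(counts, areas_mm2) -> float:
    """Pooled lymphocyte density: total T cells over total tumor area (mm^2).

    A pooled ratio — not the mean of per-image ratios — so subdividing images
    leaves the result unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    areas = np.asarray(areas_mm2, dtype=float)
    if np.any(counts < 0) or np.any(areas < 0):
        raise ValueError("counts and areas must be nonnegative")
    total_area = areas.sum()
    if total_area <= 0:
        raise ValueError("total tumor area is zero")
    return float(counts.sum() / total_area)


def contingency_odds_ratio(a: float, b: float, c: float, d: float,
                           correction: bool = True):
    """Crude odds ratio for a 2x2 table [[a, b], [c, d]] with a Woolf
    log-scale 95% CI.

    With ``correction`` (Haldane-Anscombe), 0.5 is added to every cell when
    any cell is zero; without it a zero cell yields an infinite or zero OR
    and an undefined CI.
    """
    cells = np.array([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("cell counts must be nonnegative")
    if correction and np.any(cells == 0):
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    if b_ * c_ == 0:
        return float("inf"), (float("nan"), float("nan"))
    orr = (a_ * d_) / (b_ * c_)
    if np.any(cells == 0):
        return float(orr), (float("nan"), float("nan"))
    se = np.sqrt((1 / cells).sum())
    z = stats.norm.ppf(0.975)
    lo = np.exp(np.log(orr) - z * se)
    hi = np.exp(np.log(orr) + z * se)
    return float(orr), (float(lo), float(hi))
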