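"""Tumor-only somatic variant filtering, mutation load, and MMR-gene status.

Candidate variants are screened in three stages: (1) a quality filter that
removes a record when any low-quality condition holds (haplotype score > 200,
mapping quality < 40, coverage depth < 60, alternate allele < 5% of reads,
multiallelic calls, indels, known poorly sequenced sites); (2) a germline
filter (cohort allele frequency > 5%, presence in >= 2 population databases,
or > 99.9% of reads supporting the alternate allele); and (3) a COSMIC rescue
that re-admits germline-filtered point mutations reported somatic at least 10
times.  Surviving records define the mutation load (optionally per megabase
of panel territory).  Boundary semantics follow the stated inequalities
exactly and are pinned by tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MAF_COLUMNS",
    "MMR_GENES",
    "FilterReport",
    "quality_filter",
    "germline_filter",
    "cosmic_rescue",
    "apply_filters",
    "mutation_load",
    "dichotomize_load",
    "classify_mmr_status",
    "QUALITY_THRESHOLDS",
]

MMR_GENES = ("MSH2", "MSH6", "MLH1", "PMS2")

MAF_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "variant_type", "depth",
    "alt_reads", "mapq", "haplotype_score", "cohort_af", "db_hits",
    "cosmic_count", "multiallelic", "poorly_sequenced_site", "gene",
]

QUALITY_THRESHOLDS = {
    "haplotype_score_max": 200.0,   # removed if strictly greater
    "mapq_min": 40.0,               # removed if strictly less
    "depth_min": 60.0,              # removed if strictly less
    "alt_fraction_min": 0.05,       # removed if strictly less
}

GERMLINE_THRESHOLDS = {
    "cohort_af": 0.05,     # germline if strictly greater
    "db_hits": 2,          # germline if >= 2
    "alt_fraction": 0.999, # germline if strictly greater
}

COSMIC_RESCUE_MIN = 10  # rescued if reported somatic at least this often

_QUALITY_FIELDS = ["depth", "alt_reads", "mapq", "haplotype_score"]


def _alt_fraction(records: pd.DataFrame) -> pd.Series:
    with np.errstate(invalid="ignore", divide="ignore"):
        return records["alt_reads"] / records["depth"]


def quality_filter(records: pd.DataFrame, exclude_indels: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove low-quality records; a record fails if ANY condition holds.

    Missing quality annotations fail closed (record removed, reason
    ``missing-field``).  Returns ``(kept, removed)`` where ``removed`` carries
    a ``reason`` column of semicolon-joined codes.
    """
    r = records
    alt_frac = _alt_fraction(r)
    missing = r[_QUALITY_FIELDS].isna().any(axis=1)
    conditions = {
        "haplotype-score": r["haplotype_score"] > QUALITY_THRESHOLDS["haplotype_score_max"],
        "mapping-quality": r["mapq"] < QUALITY_THRESHOLDS["mapq_min"],
        "depth": r["depth"] < QUALITY_THRESHOLDS["depth_min"],
        "alt-fraction": alt_frac < QUALITY_THRESHOLDS["alt_fraction_min"],
        "multiallelic": r["multiallelic"].fillna(False).astype(bool),
        "poorly-sequenced-site": r["poorly_sequenced_site"].fillna(False).astype(bool),
        "missing-field": missing,
    }
    if exclude_indels:
        conditions["indel"] = r["variant_type"].eq("indel")
    fail = pd.DataFrame({k: v.fillna(False) for k, v in conditions.items()})
    any_fail = fail.any(axis=1)
    reasons = fail.apply(lambda row: ";".join(fail.columns[row.values]), axis=1)
    removed = r[any_fail].copy()
    removed["reason"] = reasons[any_fail]
    return r[~any_fail].copy(), removed


def germline_filter(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into putative somatic and germline.

    Germline iff cohort allele frequency > 0.05, or present in >= 2 population
    databases, or alternate-allele read fraction > 0.999 (all strict as
    stated).  Missing annotations fail open: absent evidence is not germline.
    """
    r = records
    alt_frac = _alt_fraction(r)
    germ = (
        (r["cohort_af"] > GERMLINE_THRESHOLDS["cohort_af"]).fillna(False)
        | (r["db_hits"] >= GERMLINE_THRESHOLDS["db_hits"]).fillna(False)
        | (alt_frac > GERMLINE_THRESHOLDS["alt_fraction"]).fillna(False)
    )
    return r[~germ].copy(), r[germ].copy()


def cosmic_rescue(germline_records: pd.DataFrame) -> pd.DataFrame:
    """Re-admit germline-filtered point mutations recurrently reported somatic.

    Only SNVs with a COSMIC somatic occurrence count >= 10 are rescued;
    indels are never rescued.
    """
    r = germline_records
    rescued = r["variant_type"].eq("SNV") & (r["cosmic_count"] >= COSMIC_RESCUE_MIN).fillna(False)
    return r[rescued].copy()


@dataclass
class FilterReport:
    """Stage counts and per-record dispositions for one filtering run.

    Dispositions are exhaustive and exclusive: ``somatic``,
    ``removed-quality``, ``germline``, ``rescued-cosmic`` (or
    ``indel-somatic``/``indel-germline`` on the separate indel path).
    Balance: input = final + removed_quality + (germline - rescued).
    """

    n_input: int
    n_removed_quality: int
    n_removed_germline: int
    n_rescued_cosmic: int
    n_final: int
    dispositions: pd.Series

    def balances(self) -> bool:
        n_indel_path = int(self.dispositions.str.startswith("indel").sum())
        return self.n_input == (
            self.n_final + self.n_removed_quality
            + self.n_removed_germline - self.n_rescued_cosmic
            + n_indel_path
        )


def apply_filters(records: pd.DataFrame, indels: str = "exclude") -> tuple[pd.DataFrame, FilterReport]:
    """Full filter cascade: quality → germline → COSMIC rescue.

    ``indels='exclude'`` (default) drops indels at the quality stage, so the
    final table is the SNV mutation-count substrate.  ``indels='separate'``
    routes indels through the same quality (minus the indel criterion) and
    germline rules on a side path; they are labeled ``indel-somatic`` /
    ``indel-germline`` and excluded from the SNV-final table.

    Returns the final (load-countable) records and a :class:`FilterReport`.
    The outcome for each record depends only on its own fields, never on
    table order.
    """
    if indels not in ("exclude", "separate"):
        raise ValueError("indels must be 'exclude' or 'separate'")
    disp = pd.Series("somatic", index=records.index, dtype=object)

    snv_input = records
    if indels == "separate":
        is_indel = records["variant_type"].eq("indel")
        indel_records = records[is_indel]
        snv_input = records[~is_indel]
        ikept, _irem = quality_filter(indel_records, exclude_indels=False)
        disp.loc[indel_records.index.difference(ikept.index)] = "removed-quality"
        isom, igerm = germline_filter(ikept)
        disp.loc[isom.index] = "indel-somatic"
        disp.loc[igerm.index] = "indel-germline"

    kept, removed = quality_filter(snv_input, exclude_indels=True)
    disp.loc[removed.index] = "removed-quality"
    somatic, germline = germline_filter(kept)
    disp.loc[germline.index] = "germline"
    rescued = cosmic_rescue(germline)
    disp.loc[rescued.index] = "rescued-cosmic"
    final = pd.concat([somatic, rescued]).sort_index()

    report = FilterReport(
        n_input=len(records),
        n_removed_quality=int((disp == "removed-quality").sum()),
        n_removed_germline=int((disp == "germline").sum()) + int((disp == "rescued-cosmic").sum()),
        n_rescued_cosmic=len(rescued),
        n_final=len(final),
        dispositions=disp,
    )
    return final, report


def mutation_load(final_records: pd.DataFrame, panel_size_mb: float = 0.6) -> pd.DataFrame:
    """Per-sample surviving mutation count and count per megabase."""
    if panel_size_mb <= 0:
        raise ValueError("panel_size_mb must be positive")
    counts = final_records.groupby("sample_id").size().rename("count").to_frame()
    counts["per_mb"] = counts["count"] / panel_size_mb
    return counts.reset_index()


def dichotomize_load(count: float, threshold: float = 5.5) -> str:
    """'high' when the mutation count meets or exceeds the cutoff."""
    return "high" if count >= threshold else "low"


def classify_mmr_status(gene: str, n_nonsynonymous: int = 0, loh: bool = False,
                        homozygous_deletion: bool = False, germline: bool = False) -> str:
    """Event status of one canonical MMR gene in one sample.

    biallelic-LOF iff homozygous deletion, or >=1 nonsynonymous mutation with
    LOH, or >=2 nonsynonymous mutations.  Precedence:
    biallelic-LOF > germline > single-allele-nonsynonymous > none.
    """
    if gene not in MMR_GENES:
        raise ValueError(f"unknown MMR gene {gene!r}; expected one of {MMR_GENES}")
    if homozygous_deletion or (n_nonsynonymous >= 1 and loh) or n_nonsynonymous >= 2:
        return "biallelic-LOF"
    if germline:
        return "germline"
    if n_nonsynonymous == 1:
        return "single-allele-nonsynonymous"
    return "none"
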