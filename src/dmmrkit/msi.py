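"""MSI scoring from per-locus allele repeat-length histograms.

A sample's MSI score is the fraction of evaluated microsatellite loci called
unstable relative to a baseline built from MMR-intact specimens: per locus the
number of supported allele lengths (peaks above a fraction of the modal read
count) is compared against the baseline mean + multiplier x SD for that locus.
Also provides enriched-locus selection, harmonization of exome-derived scores
to the targeted-panel scale, and the five-marker PCR (Promega-style)
MSI-high/MSI-low/MSS classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MicrosatelliteLocus",
    "AlleleLengthHistogram",
    "count_alleles",
    "allele_count_table",
    "MsingsBaseline",
    "build_baseline",
    "call_locus_instability",
    "msings_score",
    "select_enriched_loci",
    "harmonize_exome_score",
    "promega_classify",
    "PROMEGA_MARKERS",
    "EXOME_HARMONIZATION_FACTOR",
]

#: Default multiplicative factor mapping exome-derived MSI scores onto the
#: targeted-panel score scale.
EXOME_HARMONIZATION_FACTOR = 0.209

PROMEGA_MARKERS = ("BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27")

HISTOGRAM_COLUMNS = ["sample_id", "locus_id", "repeat_length", "read_count"]


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """One microsatellite locus; start/end are 0-based half-open (BED)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    repeat_unit: str = "A"
    reference_repeat_count: int = 0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.locus_id}: end must exceed start")
        if len(self.repeat_unit) < 1:
            raise ValueError(f"{self.locus_id}: empty repeat unit")


@dataclass
class AlleleLengthHistogram:
    """Read support per repeat length at one locus in one sample."""

    sample_id: str
    locus_id: str
    counts: dict[int, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return int(sum(self.counts.values()))


def count_alleles(counts: Mapping[int, int] | AlleleLengthHistogram, peak_fraction: float = 0.05) -> int:
    """Number of repeat lengths supported by >= peak_fraction of the modal count.

    The threshold is ``peak_fraction * max(count)``; comparison is inclusive.
    """
    if isinstance(counts, AlleleLengthHistogram):
        counts = counts.counts
    values = np.asarray([c for c in counts.values() if c > 0], dtype=float)
    if values.size == 0:
        raise ValueError("empty histogram: no supported alleles")
    threshold = peak_fraction * values.max()
    return int(np.sum(values >= threshold))


def allele_count_table(
    hist: pd.DataFrame, peak_fraction: float = 0.05
) -> pd.DataFrame:
    """Per sample x locus: number of supported alleles and total reads.

    ``hist`` is the tidy histogram table (sample_id, locus_id, repeat_length,
    read_count).  Vectorized equivalent of :func:`count_alleles` per group.
    """
    g = hist.groupby(["sample_id", "locus_id"], sort=True)["read_count"]
    peak = g.transform("max")
    supported = hist["read_count"] >= peak_fraction * peak
    supported &= hist["read_count"] > 0
    out = (
        hist.assign(_supported=supported)
        .groupby(["sample_id", "locus_id"], sort=True)
        .agg(n_alleles=("_supported", "sum"), total_reads=("read_count", "sum"))
        .reset_index()
    )
    out["n_alleles"] = out["n_alleles"].astype(int)
    return out


class MsingsBaseline(BaseEstimator):
    """Baseline reference of allele-count dispersion at MMR-intact loci
    (sklearn-style estimator).

    ``fit`` consumes histograms from MMR-intact specimens only and records the
    per-locus mean and SD of the supported-allele count; scoring then flags a
    locus unstable when its allele count strictly exceeds
    ``mean + sd_multiplier * sd``.

    Parameters
    ----------
    peak_fraction : fraction of the modal read count an allele needs to count
        as supported (default 0.05).
    sd_multiplier : baseline exceedance multiplier (default 2.0).
    min_reads : minimum total reads for a locus to be evaluated (default 30).
    min_evaluated : minimum evaluated loci per scored sample (default 20).
    min_baseline : minimum covered baseline samples per locus (default 2).
    ddof : 0 for population SD (default; baselines are reference populations),
        1 for sample SD.

    Attributes
    ----------
    baseline_ : DataFrame indexed by locus_id with mean_allele_count,
        sd_allele_count, n_baseline_samples.
    dropped_loci_ : loci excluded for insufficient baseline coverage.
    """

    def __init__(self, peak_fraction=0.05, sd_multiplier=2.0, min_reads=30,
                 min_evaluated=20, min_baseline=2, ddof=0):
        self.peak_fraction = peak_fraction
        self.sd_multiplier = sd_multiplier
        self.min_reads = min_reads
        self.min_evaluated = min_evaluated
        self.min_baseline = min_baseline
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        """X: tidy histogram table from MMR-intact samples."""
        if len(X) == 0 or X["sample_id"].nunique() == 0:
            raise ValueError("no baseline samples provided")
        counts = allele_count_table(X, self.peak_fraction)
        counts = counts[counts["total_reads"] >= self.min_reads]
        stats = counts.groupby("locus_id")["n_alleles"].agg(
            mean_allele_count="mean",
            sd_allele_count=lambda v: float(np.std(v, ddof=self.ddof)),
            n_baseline_samples="count",
        )
        keep = stats["n_baseline_samples"] >= self.min_baseline
        self.dropped_loci_ = sorted(stats.index[~keep])
        self.baseline_ = stats[keep]
        return self

    def call_loci(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per sample x locus call table with columns n_alleles, total_reads,
        evaluated (coverage and baseline membership) and unstable."""
        check_is_fitted(self, "baseline_")
        counts = allele_count_table(X, self.peak_fraction)
        counts = counts.merge(
            self.baseline_.reset_index(), on="locus_id", how="left"
        )
        in_baseline = counts["mean_allele_count"].notna()
        covered = counts["total_reads"] >= self.min_reads
        counts["evaluated"] = in_baseline & covered
        threshold = counts["mean_allele_count"] + self.sd_multiplier * counts["sd_allele_count"]
        counts["unstable"] = counts["evaluated"] & (counts["n_alleles"] > threshold)
        return counts[
            ["sample_id", "locus_id", "n_alleles", "total_reads", "evaluated", "unstable"]
        ]

    def score_samples(self, X: pd.DataFrame, source: str = "panel",
                      exome_factor: float = EXOME_HARMONIZATION_FACTOR) -> pd.DataFrame:
        """Per-sample MSI score = unstable / evaluated loci.

        ``source='exome'`` additionally reports the harmonized (scaled) score;
        for panel scores harmonized equals the raw score.
        """
        calls = self.call_loci(X)
        per_sample = calls.groupby("sample_id").agg(
            n_unstable=("unstable", "sum"), n_evaluated=("evaluated", "sum")
        )
        too_few = per_sample.index[per_sample["n_evaluated"] < self.min_evaluated]
        if len(too_few):
            raise ValueError(
                f"samples with fewer than {self.min_evaluated} evaluated loci: "
                f"{', '.join(map(str, too_few[:5]))}"
            )
        per_sample["score"] = per_sample["n_unstable"] / per_sample["n_evaluated"]
        per_sample["source"] = source
        factor = exome_factor if source == "exome" else 1.0
        per_sample["harmonized_score"] = per_sample["score"].map(
            lambda s: harmonize_exome_score(s, factor)
        )
        return per_sample.reset_index()


def build_baseline(hist: pd.DataFrame, peak_fraction: float = 0.05,
                   min_reads: int = 30, min_baseline: int = 2, ddof: int = 0) -> pd.DataFrame:
    """Per-locus mean/SD of allele counts across MMR-intact samples.

    Thin wrapper over :class:`MsingsBaseline.fit`; returns the baseline table.
    """
    est = MsingsBaseline(peak_fraction=peak_fraction, min_reads=min_reads,
                         min_baseline=min_baseline, ddof=ddof).fit(hist)
    return est.baseline_


def call_locus_instability(hist: AlleleLengthHistogram | Mapping[int, int],
                           baseline_row, sd_multiplier: float = 2.0,
                           peak_fraction: float = 0.05):
    """Instability flag for one locus: allele count strictly above
    mean + sd_multiplier x sd.  Returns None (not evaluated) when the locus
    is absent from the baseline (``baseline_row`` is None)."""
    if baseline_row is None:
        return None
    n = count_alleles(hist, peak_fraction)
    return bool(n > baseline_row["mean_allele_count"]
                + sd_multiplier * baseline_row["sd_allele_count"])


def msings_score(hist: pd.DataFrame, baseline: pd.DataFrame | MsingsBaseline,
                 sd_multiplier: float = 2.0, peak_fraction: float = 0.05,
                 min_reads: int = 30, min_evaluated: int = 20,
                 source: str = "panel",
                 exome_factor: float = EXOME_HARMONIZATION_FACTOR) -> pd.DataFrame:
    """Score each sample in a tidy histogram table against a baseline."""
    if isinstance(baseline, MsingsBaseline):
        est = baseline
    else:
        est = MsingsBaseline(peak_fraction=peak_fraction, sd_multiplier=sd_multiplier,
                             min_reads=min_reads, min_evaluated=min_evaluated)
        est.baseline_ = baseline
        est.dropped_loci_ = []
    return est.score_samples(hist, source=source, exome_factor=exome_factor)


def select_enriched_loci(hist: pd.DataFrame, labels: Mapping[str, str] | pd.Series,
                         peak_fraction: float = 0.05, sd_multiplier: float = 2.0,
                         min_reads: int = 30, min_fraction: float = 0.9) -> list[str]:
    """Select informative loci from tumor + normal histogram sets.

    ``labels`` maps sample_id to 'normal' or 'dmmr_tumor' (other labels are
    ignored).  A locus is retained iff it is (a) callable (coverage-passing)
    in at least ``min_fraction`` of normals, (b) unstable in at least one
    known-dMMR tumor, and (c) stable in every normal.  Returned sorted by
    locus_id for determinism.
    """
    labels = pd.Series(labels)
    normals = labels.index[labels == "normal"]
    tumors = labels.index[labels == "dmmr_tumor"]
    if len(tumors) == 0:
        raise ValueError("no dMMR tumors provided; enrichment needs >=1 unstable tumor")
    est = MsingsBaseline(peak_fraction=peak_fraction, sd_multiplier=sd_multiplier,
                         min_reads=min_reads).fit(hist[hist["sample_id"].isin(normals)])
    calls = est.call_loci(hist)
    normal_calls = calls[calls["sample_id"].isin(normals)]
    tumor_calls = calls[calls["sample_id"].isin(tumors)]
    by_locus_n = normal_calls.groupby("locus_id")
    callable_frac = by_locus_n["evaluated"].mean()
    any_normal_unstable = by_locus_n["unstable"].any()
    any_tumor_unstable = tumor_calls.groupby("locus_id")["unstable"].any()
    keep = [
        locus
        for locus in callable_frac.index
        if callable_frac[locus] >= min_fraction
        and not any_normal_unstable[locus]
        and bool(any_tumor_unstable.get(locus, False))
    ]
    return sorted(keep)


def harmonize_exome_score(raw_score: float, factor: float = EXOME_HARMONIZATION_FACTOR) -> float:
    """Scale an exome-derived MSI score onto the targeted-panel scale."""
    if raw_score < 0:
        raise ValueError("MSI score cannot be negative")
    return float(raw_score * factor)


def promega_classify(flags: Mapping[str, bool]) -> tuple[str, str]:
    """Five-mononucleotide-marker PCR MSI classifier.

    Requires instability flags for exactly BAT-25, BAT-26, NR-21, NR-24 and
    MONO-27.  Two or more unstable markers → MSI-high; exactly one → MSI-low;
    none → MSS.  The dichotomized call groups MSI-low with MSS ('negative');
    only MSI-high is 'positive'.
    """
    missing = [m for m in PROMEGA_MARKERS if m not in flags]
    if missing:
        raise ValueError(f"missing Promega markers: {', '.join(missing)}")
    unknown = sorted(set(flags) - set(PROMEGA_MARKERS))
    if unknown:
        raise ValueError(f"unknown markers (expected only the 5 mononucleotide "
                         f"markers): {', '.join(unknown)}")
    n_unstable = sum(bool(flags[m]) for m in PROMEGA_MARKERS)
    if n_unstable >= 2:
        category = "MSI-high"
    elif n_unstable == 1:
        category = "MSI-low"
    else:
        category = "MSS"
    return category, ("positive" if category == "MSI-high" else "negative")
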