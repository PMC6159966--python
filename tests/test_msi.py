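"""MSI scoring: allele counting, baseline comparison, enrichment, Promega."""

import numpy as np
import pandas as pd
import pytest

from dmmrkit.msi import (
    MsingsBaseline,
    build_baseline,
    call_locus_instability,
    count_alleles,
    harmonize_exome_score,
    msings_score,
    promega_classify,
    select_enriched_loci,
)
from dmmrkit.simulate import SimConfig, simulate_locus_histograms


def tidy(entries):
    """[(sample, locus, {length: count}), ...] -> tidy histogram frame."""
    rows = [(s, l, length, c)
            for s, l, hist in entries for length, c in sorted(hist.items())]
    return pd.DataFrame(rows, columns=["sample_id", "locus_id",
                                       "repeat_length", "read_count"])


class TestCountAlleles:
    @pytest.mark.parametrize("counts,frac,expected", [
        ({15: 100, 14: 6, 16: 3}, 0.05, 2),   # threshold 5 reads: 100 and 6
        ({15: 100}, 0.05, 1),
        ({15: 100, 14: 100}, 0.05, 2),
        ({15: 100, 14: 5}, 0.05, 2),          # inclusive at the threshold
    ])
    def test_peak_counting(self, counts, frac, expected):
        assert count_alleles(counts, frac) == expected

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_alleles({})


class TestBaseline:
    def test_identical_histograms_give_zero_sd(self):
        hist = tidy([(f"N{i}", "L1", {15: 80, 14: 10}) for i in range(4)])
        base = build_baseline(hist, min_reads=30)
        assert base.loc["L1", "sd_allele_count"] == 0.0
        assert base.loc["L1", "mean_allele_count"] == 2.0

    def test_population_sd_closed_form(self):
        # allele counts {1,1,2,2}: mean 1.5, population sd 0.5
        hist = tidy([
            ("N1", "L1", {15: 100}), ("N2", "L1", {15: 100}),
            ("N3", "L1", {15: 100, 14: 50}), ("N4", "L1", {15: 100, 14: 50}),
        ])
        base = build_baseline(hist)
        assert base.loc["L1", "mean_allele_count"] == pytest.approx(1.5)
        assert base.loc["L1", "sd_allele_count"] == pytest.approx(0.5)

    def test_undercovered_locus_dropped_and_logged(self):
        hist = tidy([("N1", "L1", {15: 100}), ("N2", "L1", {15: 100}),
                     ("N1", "L2", {10: 100})])
        est = MsingsBaseline().fit(hist)
        assert "L2" in est.dropped_loci_
        assert "L2" not in est.baseline_.index

    def test_no_baseline_samples_rejected(self):
        with pytest.raises(ValueError, match="no baseline"):
            MsingsBaseline().fit(tidy([]))


class TestLocusCall:
    def test_threshold_arithmetic(self):
        row = {"mean_allele_count": 1.2, "sd_allele_count": 0.4}
        assert call_locus_instability({15: 100, 14: 100, 13: 100}, row, 2.0) is True   # 3 > 2.0
        assert call_locus_instability({15: 100, 14: 100}, row, 2.0) is False           # 2 <= 2.0
        zero = {"mean_allele_count": 1.0, "sd_allele_count": 0.0}
        assert call_locus_instability({15: 100}, zero, 2.0) is False  # strict inequality
        assert call_locus_instability({15: 100, 14: 100}, zero, 2.0) is True

    def test_locus_missing_from_baseline_is_not_evaluated(self):
        assert call_locus_instability({15: 100}, None) is None


class TestScore:
    def _baseline_est(self, n_loci=10, **kw):
        hist = tidy([(f"N{i}", f"L{j}", {15: 100})
                     for i in range(3) for j in range(n_loci)])
        return MsingsBaseline(min_evaluated=1, **kw).fit(hist), hist

    def test_score_is_unstable_over_evaluated(self):
        est, _ = self._baseline_est(n_loci=10)
        # tumor: 3 loci with an extra allele, 7 clean
        entries = [("T1", f"L{j}", {15: 100, 10: 40} if j < 3 else {15: 100})
                   for j in range(10)]
        res = est.score_samples(tidy(entries))
        assert res.loc[0, "n_unstable"] == 3
        assert res.loc[0, "n_evaluated"] == 10
        assert res.loc[0, "score"] == pytest.approx(0.3)

    def test_all_stable_scores_zero(self):
        est, hist = self._baseline_est()
        res = est.score_samples(tidy([("T1", f"L{j}", {15: 100}) for j in range(10)]))
        assert res.loc[0, "score"] == 0.0

    def test_adding_stable_locus_never_increases_score(self):
        est, _ = self._baseline_est(n_loci=10)
        base_entries = [("T1", f"L{j}", {15: 100, 10: 40}) for j in range(3)]
        s_small = est.score_samples(tidy(base_entries)).loc[0, "score"]
        s_more = est.score_samples(
            tidy(base_entries + [("T1", "L5", {15: 100})])).loc[0, "score"]
        s_unstable = est.score_samples(
            tidy(base_entries + [("T1", "L5", {15: 100, 9: 40})])).loc[0, "score"]
        assert s_more <= s_small
        assert s_unstable >= s_more

    def test_self_scoring_baseline_is_quiet(self):
        """Scoring the baseline samples against their own baseline yields
        (approximately) no unstable calls at multiplier 2."""
        rng = np.random.default_rng(0)
        entries = []
        for i in range(8):
            for j in range(15):
                extra = {14: int(rng.integers(3, 8))} if rng.random() < 0.5 else {}
                entries.append((f"N{i}", f"L{j}", {15: 100, **extra}))
        hist = tidy(entries)
        est = MsingsBaseline(min_evaluated=1).fit(hist)
        res = est.score_samples(hist)
        assert res["score"].mean() <= 0.05

    def test_zero_evaluated_loci_names_sample(self):
        est, _ = self._baseline_est()
        with pytest.raises(ValueError, match="T9"):
            est.score_samples(tidy([("T9", "UNKNOWN", {15: 100})]))

    def test_matches_brute_force_scorer_on_small_instances(self):
        """Exact equivalence with a literal per-locus re-derivation."""
        rng = np.random.default_rng(42)
        loci = [f"L{j}" for j in range(20)]
        normals, tumors = [f"N{i}" for i in range(5)], [f"T{i}" for i in range(4)]
        entries = []
        for s in normals + tumors:
            for l in loci:
                hist = {15: int(rng.integers(50, 150))}
                for off in (1, 2, 3, 8):
                    if rng.random() < 0.4:
                        hist[15 - off] = int(rng.integers(1, 60))
                entries.append((s, l, hist))
        frame = tidy(entries)
        est = MsingsBaseline(min_evaluated=1).fit(
            frame[frame["sample_id"].isin(normals)])
        res = est.score_samples(frame[frame["sample_id"].isin(tumors)])

        # brute force: recompute every locus call by the literal formula
        by_key = {(s, l): h for s, l, h in entries}
        for s in tumors:
            unstable = evaluated = 0
            for l in loci:
                h = by_key[(s, l)]
                if sum(h.values()) < 30 or l not in est.baseline_.index:
                    continue
                evaluated += 1
                peak = max(h.values())
                n = sum(1 for c in h.values() if c >= 0.05 * peak)
                row = est.baseline_.loc[l]
                if n > row["mean_allele_count"] + 2.0 * row["sd_allele_count"]:
                    unstable += 1
            got = res.set_index("sample_id").loc[s]
            assert got["n_evaluated"] == evaluated
            assert got["n_unstable"] == unstable

    def test_simulated_dmmr_cohort_separates_from_pmmr(self):
        cfg = SimConfig(n_samples=20, frac_dmmr=0.5, n_loci=100,
                        p_unstable_locus=0.2, seed=21)
        hist, truth = simulate_locus_histograms(cfg)
        normals = truth.dmmr.index[~truth.dmmr]
        est = MsingsBaseline().fit(hist[hist["sample_id"].isin(normals)])
        res = est.score_samples(hist).set_index("sample_id")
        from scipy.stats import mannwhitneyu
        d = res.loc[truth.dmmr.index[truth.dmmr], "score"]
        p = res.loc[normals, "score"]
        assert mannwhitneyu(d, p, alternative="greater").pvalue < 0.01


class TestEnrichment:
    def test_definition_and_synthetic_panel(self):
        """Loci unstable in a dMMR tumor and stable/callable in normals are
        selected; injected-instability loci are recovered exactly."""
        rng = np.random.default_rng(1)
        loci = [f"L{j:03d}" for j in range(30)]
        informative = set(loci[:8])
        entries = []
        for i in range(6):
            for l in loci:
                entries.append((f"N{i}", l, {15: 100, 14: int(rng.integers(3, 8))}))
        for i in range(2):
            for l in loci:
                h = {15: 100, 14: 5}
                if l in informative:
                    h[10] = 40  # novel allele far from the mode
                entries.append((f"T{i}", l, h))
        labels = {f"N{i}": "normal" for i in range(6)}
        labels.update({f"T{i}": "dmmr_tumor" for i in range(2)})
        selected = select_enriched_loci(tidy(entries), labels)
        assert selected == sorted(informative)

    def test_locus_unstable_in_a_normal_is_dropped(self):
        entries = [("N0", "L1", {15: 100}), ("N1", "L1", {15: 100, 10: 40}),
                   ("T0", "L1", {15: 100, 9: 50})]
        labels = {"N0": "normal", "N1": "normal", "T0": "dmmr_tumor"}
        assert select_enriched_loci(tidy(entries), labels) == []

    def test_requires_a_dmmr_tumor(self):
        with pytest.raises(ValueError, match="dMMR"):
            select_enriched_loci(tidy([("N0", "L1", {15: 100})]), {"N0": "normal"})


class TestHarmonization:
    @pytest.mark.parametrize("raw,factor,expected", [
        (1.0, 0.209, 0.209),
        (0.0, 0.209, 0.0),
        (0.5, 0.209, 0.1045),
    ])
    def test_scaling(self, raw, factor, expected):
        assert harmonize_exome_score(raw, factor) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            harmonize_exome_score(-0.1)


class TestPromega:
    def test_two_or_more_unstable_is_msi_high(self):
        flags = dict.fromkeys(["BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27"], False)
        flags.update({"BAT-25": True, "BAT-26": True})
        assert promega_classify(flags) == ("MSI-high", "positive")

    def test_single_locus_is_msi_low_negative(self):
        flags = dict.fromkeys(["BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27"], False)
        flags["NR-21"] = True
        assert promega_classify(flags) == ("MSI-low", "negative")

    def test_no_instability_is_mss(self):
        flags = dict.fromkeys(["BAT-25", "BAT-26", "NR-21", "NR-24", "MONO-27"], False)
        assert promega_classify(flags) == ("MSS", "negative")

    def test_missing_marker_listed(self):
        with pytest.raises(ValueError, match="MONO-27"):
            promega_classify({"BAT-25": True, "BAT-26": False, "NR-21": False,
                              "NR-24": False})


def test_msings_score_wrapper_accepts_plain_baseline_table():
    hist = tidy([(f"N{i}", f"L{j}", {15: 100}) for i in range(3) for j in range(5)])
    base = build_baseline(hist)
    res = msings_score(hist, base, min_evaluated=1)
    assert (res["score"] == 0).all()
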