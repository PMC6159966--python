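"""Context classification, KL-NMF extraction, matching and exposures."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dmmrkit.signatures import (
    CHANNELS,
    SignatureNMF,
    build_context_matrix,
    classify_context,
    cosine_similarity,
    exposure_proportions,
    fit_signatures,
    kl_divergence,
    match_signatures,
    mmr_dominant,
    nmf_brunet,
    rank_diagnostics,
)
from dmmrkit.simulate import SimConfig, simulate_mutation_catalogs


class TestClassifyContext:
    def test_pyrimidine_reference_kept_as_is(self, tiny_reference):
        # positions 2..4 spell ACA; C>T at position 3
        assert classify_context("chr1", 3, "C", "T", tiny_reference) == "A[C>T]A"

    def test_purine_reference_reverse_complemented(self, tiny_reference):
        # positions 4..6 spell AGT; G>A at position 5 -> revcomp ACT, C>T
        assert classify_context("chr1", 5, "G", "A", tiny_reference) == "A[C>T]T"

    def test_ref_mismatch_names_position(self, tiny_reference):
        with pytest.raises(ValueError, match="chr1:3"):
            classify_context("chr1", 3, "G", "A", tiny_reference)

    def test_indel_rejected(self, tiny_reference):
        with pytest.raises(ValueError, match="SNV"):
            classify_context("chr1", 3, "CA", "C", tiny_reference)

    def test_all_snv_flank_combinations_give_96_channels(self):
        """Every (flank, substitution) combination on either strand maps into
        exactly the 96 pyrimidine-strand channels."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seen = set()
        for five, ref, three in itertools.product("ACGT", repeat=3):
            for alt in "ACGT":
                if alt == ref:
                    continue
                ref_seq = {"c": f"{five}{ref}{three}"}
                seen.add(classify_context("c", 2, ref, alt, ref_seq))
        assert seen == set(CHANNELS)
        assert len(seen) == 96


class TestContextMatrix:
    def test_empty_table_gives_zero_matrix(self, tiny_reference):
        V = build_context_matrix(
            pd.DataFrame(columns=["sample_id", "chrom", "pos", "ref", "alt"]),
            tiny_reference,
        )
        assert V.shape == (0, 96)

    def test_row_sums_equal_snv_counts(self, small_cohort):
        V = build_context_matrix(small_cohort.records, small_cohort.reference)
        counts = small_cohort.records.groupby("sample_id").size()
        assert (V.sum(axis=1).sort_index() == counts.sort_index()).all()

    def test_pure_signature_catalog_matches_its_profile(self, reference_signatures):
        """With a single active signature the empirical context frequencies
        converge to that signature's profile (law of large numbers)."""
        sig = reference_signatures[["Aging1-like"]]
        cfg = SimConfig(n_samples=1, n_signatures=1, exposure_concentration=(1.0,),
                        mutations_per_sample=12000, count_model="poisson",
                        frac_dmmr=0.0, genome_length=300_000, seed=5)
        records, reference, _ = simulate_mutation_catalogs(cfg, signatures=sig)
        V = build_context_matrix(records, reference)
        profile = V.iloc[0].to_numpy(dtype=float)
        assert cosine_similarity(profile, sig.to_numpy().ravel()) >= 0.99


class TestNmfBrunet:
    def test_exact_rank_one_structure_is_fit_to_machine_precision(self):
        w = np.array([1.0, 2.0, 3.0, 0.5])
        h = np.array([4.0, 1.0, 2.0])
        V = np.outer(w, h)
        _, _, div = nmf_brunet(V, 1, seed=0, max_iter=5000, tol=1e-14)
        assert div < 1e-6

    def test_divergence_monotone_nonincreasing_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for trial in range(20):
            V = rng.poisson(5.0, size=(12, 9)).astype(float)
            *_, hist = nmf_brunet(V, 3, seed=trial, max_iter=60, tol=0.0,
                                  return_divergences=True)
            diffs = np.diff(hist)
            assert np.all(diffs <= 1e-8 * max(hist[0], 1.0))

    def test_same_seed_reproduces_factorization(self):
        V = np.random.default_rng(1).poisson(4.0, size=(10, 8)).astype(float)
        W1, H1, d1 = nmf_brunet(V, 2, seed=7)
        W2, H2, d2 = nmf_brunet(V, 2, seed=7)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)
        assert d1 == d2

    def test_divergence_matches_literal_formula(self):
        """The reported residual equals an independently coded elementwise
        evaluation of the generalized KL objective."""
        rng = np.random.default_rng(2)
        V = rng.poisson(6.0, size=(8, 6)).astype(float)
        W, H, div = nmf_brunet(V, 2, seed=3)
        WH = np.maximum(W @ H, 1e-9)
        literal = 0.0
        for i in range(V.shape[0]):
            for j in range(V.shape[1]):
                v, wh = V[i, j], WH[i, j]
                literal += (v * np.log(v / wh) - v + wh) if v > 0 else wh
        assert abs(div - literal) < 1e-8 * max(1.0, literal)

    def test_rank_and_nonfinite_input_rejected(self):
        V = np.ones((4, 4))
        with pytest.raises(ValueError, match="rank"):
            nmf_brunet(V, 4)
        V2 = V.copy(); V2[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            nmf_brunet(V2, 2)


class TestFitSignatures:
    def test_single_run_equals_direct_call(self):
        V = np.random.default_rng(4).poisson(5.0, size=(6, 96)).astype(float)
        model = fit_signatures(pd.DataFrame(V, columns=list(CHANNELS)),
                               rank=2, n_runs=1, seed=9)
        W, H, div = nmf_brunet(V.T, 2, seed=9)
        assert model.residual == div
        np.testing.assert_allclose(model.W.to_numpy(), W)

    def test_selected_residual_is_the_minimum_over_runs(self):
        V = np.random.default_rng(5).poisson(5.0, size=(8, 96)).astype(float)
        model = fit_signatures(pd.DataFrame(V, columns=list(CHANNELS)),
                               rank=2, n_runs=6, seed=20)
        divs = [nmf_brunet(V.T, 2, seed=20 + r)[2] for r in range(6)]
        assert model.residual == min(divs)
        assert model.best_seed == 20 + int(np.argmin(divs))

    def test_recovers_known_signatures_from_synthetic_catalog(
            self, reference_signatures):
        """Recovery at 100 samples x ~500 mutations with 10 restarts: every
        generating signature recovered with cosine >= 0.9, and exposure
        proportions with RMSE <= 0.10 after optimal matching."""
        cfg = SimConfig(n_samples=100, mutations_per_sample=500,
                        genome_length=300_000, seed=8)
        records, reference, truth = simulate_mutation_catalogs(cfg)
        V = build_context_matrix(records, reference)
        model = fit_signatures(V, rank=4, n_runs=10, seed=1,
                               reference=reference_signatures)
        cosines = {ref: c for _, ref, c, _ in model.assignments}
        assert set(cosines) == set(reference_signatures.columns)
        assert all(c >= 0.9 for c in cosines.values())
        mapping = {sig: ref for sig, ref, _, _ in model.assignments}
        P = model.proportions.rename(columns=mapping)[truth.exposures.columns]
        rmse = np.sqrt(((P - truth.exposures) ** 2).to_numpy().mean())
        assert rmse <= 0.10

    def test_exposures_sum_to_sample_counts_within_reconstruction_error(
            self, small_cohort):
        V = build_context_matrix(small_cohort.records, small_cohort.reference)
        model = fit_signatures(V, rank=3, n_runs=3, seed=0)
        totals = model.H.sum(axis=1).to_numpy()
        counts = V.sum(axis=1).to_numpy(dtype=float)
        assert np.allclose(totals, counts, rtol=0.05)
        np.testing.assert_allclose(model.W.sum(axis=0), 1.0, atol=1e-9)


class TestRankDiagnostics:
    def test_perfect_consensus_gives_cophenetic_one(self):
        # strongly rank-2 block data: every run clusters samples identically
        rng = np.random.default_rng(6)
        block = np.zeros((20, 96))
        block[:10, :10] = rng.poisson(60, size=(10, 10))
        block[10:, 50:60] = rng.poisson(60, size=(10, 10))
        V = pd.DataFrame(block + rng.poisson(1.0, size=(20, 96)),
                         columns=list(CHANNELS))
        diag = rank_diagnostics(V, ranks=[2], runs_per_rank=4, seed=0,
                                max_iter=300)
        assert diag.table.loc[2, "cophenetic"] == pytest.approx(1.0, abs=1e-6)

    def test_two_block_data_prefers_rank_two_and_rss_nonincreasing(self):
        rng = np.random.default_rng(7)
        block = np.zeros((16, 96))
        block[:8, :12] = rng.poisson(40, size=(8, 12))
        block[8:, 40:52] = rng.poisson(40, size=(8, 12))
        V = pd.DataFrame(block + rng.poisson(1.0, size=(16, 96)),
                         columns=list(CHANNELS))
        diag = rank_diagnostics(V, ranks=[2, 3, 5], runs_per_rank=5, seed=1,
                                max_iter=300)
        t = diag.table
        assert t.loc[2, "cophenetic"] >= t.loc[5, "cophenetic"]
        assert t.loc[2, "rss"] >= t.loc[3, "rss"] >= t.loc[5, "rss"]

    def test_fewer_than_two_runs_rejected(self):
        V = pd.DataFrame(np.ones((6, 96)), columns=list(CHANNELS))
        with pytest.raises(ValueError, match="2 runs"):
            rank_diagnostics(V, ranks=[2], runs_per_rank=1)


class TestMatching:
    def test_identity_and_permutation_recovered(self, reference_signatures):
        ref = reference_signatures
        out = match_signatures(ref, ref)
        assert all(name == match and c == pytest.approx(1.0)
                   for name, match, c, _ in out)
        perm = ref[["MMR6-like", "Aging1-like", "MMR26-like", "HRD3-like"]]
        out = match_signatures(perm, ref)
        assert all(name == match for name, match, _, _ in out)

    def test_assignment_matches_brute_force_on_two_by_two(self):
        # cross-cosines approximately {(.9,.3),(.4,.8)} -> diagonal pairing
        a = np.array([[1, 0.25], [0.6, 1.6]])
        b = np.array([[1, 0.8], [0.28, 1.9]])
        W = pd.DataFrame(a, columns=["d1", "d2"])
        R = pd.DataFrame(b, columns=["A", "B"])
        best_total, best_perm = -np.inf, None
        for perm in itertools.permutations(range(2)):
            total = sum(cosine_similarity(a[:, i], b[:, perm[i]]) for i in range(2))
            if total > best_total:
                best_total, best_perm = total, perm
        out = match_signatures(W, R)
        assert [m for _, m, _, _ in out] == [R.columns[j] for j in best_perm]
        assert sum(c for _, _, c, _ in out) == pytest.approx(best_total)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            match_signatures(pd.DataFrame(np.ones((10, 2))),
                             pd.DataFrame(np.ones((96, 2))))

    @pytest.mark.parametrize("a,b,expected", [
        ((1, 1, 0), (1, 1, 0), 1.0),
        ((1, 0, 0), (0, 1, 0), 0.0),
        ((1, 1, 0), (1, 0, 0), 1 / np.sqrt(2)),
    ])
    def test_cosine_closed_forms(self, a, b, expected):
        assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_cosine_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity((0, 0), (1, 0))


class TestExposures:
    def test_proportions_and_dominance(self):
        H = pd.DataFrame([[30, 10, 10, 0], [1, 1, 1, 1], [0, 0, 0, 0]],
                         columns=list("abcd"), index=["x", "y", "z"])
        P = exposure_proportions(H)
        assert P.loc["x", "a"] == pytest.approx(0.6)
        assert P.loc["z"].isna().all()
        flags = mmr_dominant(P, ["a"])
        assert flags["x"] == True  # 0.6 > 0.5
        assert flags["y"] == False  # 0.25
        assert flags["z"] is pd.NA

    def test_exactly_half_is_not_dominant(self):
        P = exposure_proportions(pd.DataFrame([[5, 5]], columns=["m", "o"]))
        assert mmr_dominant(P, ["m"]).iloc[0] == False

    def test_transform_reuses_fitted_signatures(self, small_cohort):
        V = build_context_matrix(small_cohort.records, small_cohort.reference)
        est = SignatureNMF(n_components=3, n_runs=2, random_state=0).fit(V.to_numpy())
        E = est.transform(V.to_numpy())
        assert E.shape == (V.shape[0], 3)
        assert np.all(E >= 0)
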