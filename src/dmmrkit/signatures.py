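"""Mutational-signature extraction from 96-channel trinucleotide context catalogs.

Single-base substitutions are classified on the pyrimidine strand into 96
channels (6 substitution types x 16 flanking-base combinations).  Signatures
are extracted by non-negative matrix factorization minimizing the generalized
Kullback-Leibler divergence with multiplicative (Brunet-style) updates, using
many random restarts and keeping the run with the lowest residual.  Discovered
signatures are matched one-to-one to reference signatures by cosine
similarity, and per-sample exposures are normalized to activity proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CHANNELS",
    "SUBSTITUTIONS",
    "classify_context",
    "build_context_matrix",
    "kl_divergence",
    "nmf_brunet",
    "SignatureNMF",
    "fit_signatures",
    "rank_diagnostics",
    "match_signatures",
    "cosine_similarity",
    "exposure_proportions",
    "mmr_dominant",
    "SignatureModel",
    "RankDiagnostics",
]

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Fixed channel order: substitution-major, then 5' base, then 3' base,
#: each alphabetical.  Label format: ``5'[REF>ALT]3'`` e.g. ``A[C>T]G``.
CHANNELS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
_CHANNEL_INDEX = {label: i for i, label in enumerate(CHANNELS)}


def _fetch(reference, chrom: str, start0: int, end0: int) -> str:
    """Fetch reference bases [start0, end0) (0-based) from a pyfaidx Fasta
    or a plain ``{chrom: sequence}`` mapping."""
    seq = reference[chrom][start0:end0]
    if not isinstance(seq, str):  # pyfaidx Sequence
        seq = str(seq)
    return seq.upper()


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_context(chrom: str, pos: int, ref: str, alt: str, reference) -> str:
    """Classify a single-nucleotide variant into one of the 96 channels.

    ``pos`` is 1-based.  Purine-reference mutations are mapped to the
    pyrimidine strand by reverse-complementing the trinucleotide.

    Raises ``ValueError`` on indels or a REF/FASTA mismatch.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref not in _BASES or alt not in _BASES:
        raise ValueError(f"not an SNV: {ref}>{alt} at {chrom}:{pos}")
    if ref == alt:
        raise ValueError(f"REF equals ALT at {chrom}:{pos}")
    tri = _fetch(reference, chrom, pos - 2, pos + 1)
    if len(tri) != 3:
        raise ValueError(f"position {chrom}:{pos} too close to a contig edge")
    if tri[1] != ref:
        raise ValueError(
            f"REF mismatch at {chrom}:{pos}: table says {ref}, FASTA has {tri[1]}"
        )
    if ref in ("A", "G"):
        tri = revcomp(tri)
        ref = _COMPLEMENT[ref]
        alt = _COMPLEMENT[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def build_context_matrix(mutations: pd.DataFrame, reference) -> pd.DataFrame:
    """Count SNVs per sample into the 96 channels.

    ``mutations`` needs columns sample_id, chrom, pos, ref, alt (and
    optionally variant_type; rows not typed SNV are skipped).  Returns a
    samples x 96 integer DataFrame in the fixed :data:`CHANNELS` order;
    row sums equal per-sample SNV counts.
    """
    samples = pd.unique(mutations["sample_id"]) if len(mutations) else np.array([])
    V = pd.DataFrame(
        np.zeros((len(samples), 96), dtype=int), index=samples, columns=list(CHANNELS)
    )
    n_skipped = 0
    for row in mutations.itertuples(index=False):
        vt = getattr(row, "variant_type", "SNV")
        if vt != "SNV" or len(str(row.ref)) != 1 or len(str(row.alt)) != 1:
            n_skipped += 1
            continue
        label = classify_context(row.chrom, int(row.pos), row.ref, row.alt, reference)
        V.at[row.sample_id, label] += 1
    V.attrs["n_skipped_non_snv"] = n_skipped
    return V


# ---------------------------------------------------------------------------
# NMF (generalized KL, multiplicative updates)
# ---------------------------------------------------------------------------


def kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence D(V || WH).

    Terms with V == 0 contribute WH (the limit of v*log(v/wh) - v + wh).
    """
    V = np.asarray(V, dtype=float)
    WH = np.asarray(WH, dtype=float)
    mask = V > 0
    d = np.sum(WH) - np.sum(V[mask])
    d += np.sum(V[mask] * np.log(V[mask] / WH[mask]))
    return float(d)


def _kl_update_h(V, W, H, eps):
    WH = W @ H
    np.maximum(WH, eps, out=WH)
    H *= (W.T @ (V / WH)) / np.maximum(W.sum(axis=0)[:, None], eps)
    return H


def _kl_update_w(V, W, H, eps):
    WH = W @ H
    np.maximum(WH, eps, out=WH)
    W *= ((V / WH) @ H.T) / np.maximum(H.sum(axis=1)[None, :], eps)
    return W


def nmf_brunet(
    V: np.ndarray,
    rank: int,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-9,
    eps: float = 1e-9,
    return_divergences: bool = False,
):
    """Factorize a nonnegative ``channels x samples`` matrix V ~ W @ H by
    multiplicative KL updates.

    Returns ``(W, H, divergence)`` with W column-normalized to sum 1 and the
    compensating scale folded into H.  The divergence sequence is
    non-increasing; iteration stops when the relative change drops below
    ``tol`` or after ``max_iter`` sweeps.  Deterministic for a fixed seed.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be a 2-d matrix")
    if not np.all(np.isfinite(V)) or np.any(V < 0):
        raise ValueError("V must be finite and nonnegative")
    m, n = V.shape
    if rank >= min(m, n):
        raise ValueError(f"rank {rank} must be < min(V.shape) = {min(m, n)}")
    rng = np.random.default_rng(seed)
    scale = max(V.mean(), eps)
    W = rng.uniform(0.1, 1.0, size=(m, rank)) * np.sqrt(scale)
    H = rng.uniform(0.1, 1.0, size=(rank, n)) * np.sqrt(scale)

    prev = kl_divergence(V, W @ H)
    history = [prev]
    for _ in range(max_iter):
        H = _kl_update_h(V, W, H, eps)
        W = _kl_update_w(V, W, H, eps)
        cur = kl_divergence(V, np.maximum(W @ H, eps))
        history.append(cur)
        if prev - cur < tol * max(abs(prev), 1.0):
            prev = cur
            break
        prev = cur

    colsum = np.maximum(W.sum(axis=0), eps)
    W = W / colsum
    H = H * colsum[:, None]
    if return_divergences:
        return W, H, prev, history
    return W, H, prev


@dataclass
class SignatureModel:
    """Best-of-restarts NMF factorization of a mutation catalog."""

    W: pd.DataFrame  # 96 x K, columns sum to 1
    H: pd.DataFrame  # samples x K, counts scale
    proportions: pd.DataFrame  # samples x K, rows sum to 1 (NaN if row of H is 0)
    residual: float
    rank: int
    n_runs: int
    best_seed: int
    assignments: list = field(default_factory=list)  # (sig name, ref name, cosine)


class SignatureNMF(BaseEstimator):
    """Multi-restart KL-NMF signature extractor (sklearn estimator).

    Parameters
    ----------
    n_components : number of signatures K.
    n_runs : independent random restarts; the factorization with the lowest
        KL residual is kept (ties broken toward the lowest restart seed).
    random_state : master seed; restart r uses seed ``random_state + r``.
    max_iter, tol : per-run update budget and relative-change stopping rule.

    Attributes (after ``fit``)
    --------------------------
    components_ : (K, 96) array, rows sum to 1 (signature profiles).
    exposures_ : (n_samples, K) array on counts scale.
    reconstruction_err_ : generalized KL divergence of the best run.
    best_seed_ : seed of the winning restart.
    """

    def __init__(self, n_components=4, n_runs=20, random_state=0, max_iter=10000, tol=1e-9):
        self.n_components = n_components
        self.n_runs = n_runs
        self.random_state = random_state
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        V = np.asarray(X, dtype=float).T  # channels x samples
        best = None
        for r in range(self.n_runs):
            seed = self.random_state + r
            W, H, div = nmf_brunet(
                V, self.n_components, seed=seed, max_iter=self.max_iter, tol=self.tol
            )
            if best is None or div < best[2]:
                best = (W, H, div, seed)
        W, H, div, seed = best
        self.components_ = W.T
        self.exposures_ = H.T
        self.reconstruction_err_ = div
        self.best_seed_ = seed
        self.n_features_in_ = V.shape[0]
        return self

    def transform(self, X):
        """Exposures for new samples with signatures held fixed (H-only updates)."""
        check_is_fitted(self, "components_")
        V = np.asarray(X, dtype=float).T
        W = self.components_.T
        rng = np.random.default_rng(self.random_state)
        H = rng.uniform(0.1, 1.0, size=(self.n_components, V.shape[1])) * max(
            V.mean(), 1e-9
        )
        prev = kl_divergence(V, np.maximum(W @ H, 1e-9))
        for _ in range(self.max_iter):
            H = _kl_update_h(V, W, H, 1e-9)
            cur = kl_divergence(V, np.maximum(W @ H, 1e-9))
            if prev - cur < self.tol * max(abs(prev), 1.0):
                break
            prev = cur
        return H.T

    def fit_transform(self, X, y=None):
        self.fit(X)
        return self.exposures_


def fit_signatures(
    V: pd.DataFrame,
    rank: int = 4,
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-9,
    reference: pd.DataFrame | None = None,
    report_threshold: float = 0.8,
) -> SignatureModel:
    """Extract ``rank`` signatures from a samples x 96 catalog.

    Thin wrapper over :class:`SignatureNMF`; if ``reference`` (96 x R, columns
    named) is given, discovered signatures are matched to it by cosine
    similarity and the assignments recorded on the model.
    """
    est = SignatureNMF(
        n_components=rank, n_runs=n_runs, random_state=seed, max_iter=max_iter, tol=tol
    ).fit(np.asarray(V, dtype=float))
    sig_names = [f"S{k + 1}" for k in range(rank)]
    channels = list(V.columns) if isinstance(V, pd.DataFrame) else list(CHANNELS)
    index = V.index if isinstance(V, pd.DataFrame) else pd.RangeIndex(est.exposures_.shape[0])
    W = pd.DataFrame(est.components_.T, index=channels, columns=sig_names)
    H = pd.DataFrame(est.exposures_, index=index, columns=sig_names)
    model = SignatureModel(
        W=W,
        H=H,
        proportions=exposure_proportions(H),
        residual=est.reconstruction_err_,
        rank=rank,
        n_runs=n_runs,
        best_seed=est.best_seed_,
    )
    if reference is not None:
        model.assignments = match_signatures(W, reference, report_threshold=report_threshold)
    return model


@dataclass
class RankDiagnostics:
    """Per-rank consensus/residual diagnostics table for manual rank choice."""

    table: pd.DataFrame  # index rank; cophenetic, residual, rss
    runs_per_rank: int


def rank_diagnostics(
    V: pd.DataFrame, ranks=range(2, 9), runs_per_rank: int = 50, seed: int = 0,
    max_iter: int = 2000, tol: float = 1e-7,
) -> RankDiagnostics:
    """Cophenetic coefficient, best-run residual, and best-run RSS per rank.

    The consensus matrix at each rank is the mean over runs of the indicator
    that two samples share the same argmax-exposure signature; the cophenetic
    coefficient correlates 1 - consensus with the cophenetic distances of its
    average-linkage hierarchical clustering.
    """
    if runs_per_rank < 2:
        raise ValueError("consensus needs at least 2 runs per rank")
    Va = np.asarray(V, dtype=float).T  # channels x samples
    n = Va.shape[1]
    rows = []
    for j, rank in enumerate(ranks):
        consensus = np.zeros((n, n))
        best = None
        for r in range(runs_per_rank):
            run_seed = seed + j * runs_per_rank + r
            W, H, div = nmf_brunet(Va, rank, seed=run_seed, max_iter=max_iter, tol=tol)
            labels = H.argmax(axis=0)
            consensus += (labels[:, None] == labels[None, :]).astype(float)
            if best is None or div < best[2]:
                best = (W, H, div)
        consensus /= runs_per_rank
        dissim = 1.0 - consensus
        np.fill_diagonal(dissim, 0.0)
        condensed = squareform(dissim, checks=False)
        if condensed.std() == 0:
            coph = 1.0  # all runs agree perfectly (or trivially)
        else:
            Z = linkage(condensed, method="average")
            coph, _ = cophenet(Z, condensed)
            coph = float(coph)
        W, H, div = best
        rss = float(np.sum((Va - W @ H) ** 2))
        rows.append({"rank": rank, "cophenetic": coph, "residual": div, "rss": rss})
    table = pd.DataFrame(rows).set_index("rank")
    return RankDiagnostics(table=table, runs_per_rank=runs_per_rank)


# ---------------------------------------------------------------------------
# Matching and exposures
# ---------------------------------------------------------------------------


def cosine_similarity(a, b) -> float:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(a @ b / (na * nb))


def match_signatures(
    W: pd.DataFrame, reference: pd.DataFrame, report_threshold: float = 0.8
) -> list[tuple[str, str, float, bool]]:
    """One-to-one assignment of discovered to reference signatures
    maximizing total cosine similarity.

    Both inputs are channels x signatures with identical channel counts.
    Returns ``(discovered, reference, cosine, matched)`` tuples, one per
    discovered signature (surplus signatures when K differs are paired with
    ``None``); ``matched`` is False below ``report_threshold``.
    """
    Wv = np.asarray(W, dtype=float)
    Rv = np.asarray(reference, dtype=float)
    if Wv.shape[0] != Rv.shape[0]:
        raise ValueError(
            f"channel count mismatch: {Wv.shape[0]} vs {Rv.shape[0]}"
        )
    wnames = list(W.columns) if isinstance(W, pd.DataFrame) else [
        f"S{k + 1}" for k in range(Wv.shape[1])
    ]
    rnames = list(reference.columns) if isinstance(reference, pd.DataFrame) else [
        f"R{k + 1}" for k in range(Rv.shape[1])
    ]
    cos = np.array(
        [[cosine_similarity(Wv[:, i], Rv[:, j]) for j in range(Rv.shape[1])]
         for i in range(Wv.shape[1])]
    )
    ri, ci = linear_sum_assignment(-cos)
    out: list[tuple[str, str, float, bool]] = []
    paired = dict(zip(ri.tolist(), ci.tolist()))
    for i, name in enumerate(wnames):
        if i in paired:
            j = paired[i]
            c = float(cos[i, j])
            out.append((name, rnames[j], c, c >= report_threshold))
        else:
            out.append((name, None, float("nan"), False))
    return out


def exposure_proportions(H: pd.DataFrame) -> pd.DataFrame:
    """Row-normalize exposures to activity proportions; all-zero rows → NaN."""
    Hv = np.asarray(H, dtype=float)
    if np.any(Hv < 0):
        raise ValueError("exposures must be nonnegative")
    totals = Hv.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(totals[:, None] > 0, Hv / totals[:, None], np.nan)
    if isinstance(H, pd.DataFrame):
        return pd.DataFrame(P, index=H.index, columns=H.columns)
    return pd.DataFrame(P)


def mmr_dominant(proportions: pd.DataFrame, dmmr_signatures) -> pd.Series:
    """Flag samples whose summed dMMR-signature activity exceeds 0.5 strictly.

    Samples with undefined proportions (no mutations) get pandas NA.
    """
    cols = list(dmmr_signatures)
    total = proportions[cols].sum(axis=1, min_count=len(cols))
    out = pd.Series(pd.NA, index=proportions.index, dtype="boolean")
    defined = total.notna()
    out[defined] = total[defined] > 0.5
    return out


def enumerate_channels() -> list[str]:
    """All 96 channel labels, by enumerating pyrimidine substitutions x flanks."""
    labels = []
    for ref, alts in (("C", "AGT"), ("T", "ACG")):
        for alt in alts:
            for five in _BASES:
                for three in _BASES:
                    labels.append(f"{five}[{ref}>{alt}]{three}")
    return sorted(set(labels), key=lambda s: _CHANNEL_INDEX[s])
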