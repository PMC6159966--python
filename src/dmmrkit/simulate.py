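"""Synthetic mCRPC cohort generator.

Emulates, with known ground truth, the four data layers the pipeline
consumes: (a) per-locus allele repeat-length read histograms with PCR-stutter
noise, where mismatch-repair-deficient (dMMR) samples gain novel alleles at
unstable loci; (b) somatic mutation catalogs drawn from mixtures of four
reference mutational signatures and realized as concrete SNVs on an emitted
synthetic chromosome; (c) variant tables with germline and low-quality
artifact spike-ins; (d) TPM expression matrices in which a latent immune
infiltrate factor correlates with dMMR signature activity; plus exponential
survival with a configurable dMMR hazard ratio.

Every generator is deterministic under a fixed seed; a master seed fans out
to per-stage seeds by stable hashing of stage names.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .immune import checkpoint_panel
from .msi import MicrosatelliteLocus
from .refsigs import REFERENCE_NAMES, make_reference_signatures
from .signatures import CHANNELS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SyntheticCohort",
    "stage_seed",
    "simulate_locus_histograms",
    "simulate_mutation_catalogs",
    "simulate_variant_annotations",
    "simulate_expression",
    "simulate_clinical",
    "simulate_cohort",
]

#: Indices (into the reference signature order) of the MMR-type signatures.
DMMR_SIGNATURE_NAMES = ("MMR6-like", "MMR26-like")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, from a master seed and a
    stage name (CRC-32 of the combined string; platform-independent)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale cohort with the dMMR structure the
    pipeline is designed to resolve: 30% dMMR prevalence, one fifth of loci
    unstable per dMMR sample, four mutational signatures with dMMR samples
    biased toward the MMR-type ones, and an infiltrate factor correlated
    0.24 with dMMR activity.
    """

    n_samples: int = 40
    n_loci: int = 200
    frac_dmmr: float = 0.3
    p_unstable_locus: float = 0.2
    stutter_decay: float = 0.3
    read_depth: float = 100.0
    n_signatures: int = 4
    mutations_per_sample: float = 500.0
    exposure_concentration: tuple = (2.0, 1.5, 0.25, 0.25)
    n_genes: int = 200
    infiltrate_effect: float = 0.24
    seed: int = 0
    # secondary knobs
    dmmr_exposure_boost: float = 16.0
    count_model: str = "negbin"  # or "poisson"
    count_dispersion: float = 5.0  # negative-binomial size parameter
    novel_allele_fraction: float = 0.3  # novel-allele support vs modal count
    max_stutter_offset: int = 5
    germline_rate: float = 0.15
    artifact_rate: float = 0.10
    cosmic_rescue_fraction: float = 0.2
    panel_loading: float = 0.4
    expression_scale: float = 1.0  # SD of log-TPM around the latent structure
    hazard_ratio: float = 4.0
    baseline_median_years: float = 7.0
    censoring_mean_years: float = 25.0
    genome_length: int = 1_000_000
    chrom_name: str = "chrS"

    def __post_init__(self):
        for name in ("frac_dmmr", "p_unstable_locus", "germline_rate",
                     "artifact_rate", "cosmic_rescue_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.stutter_decay < 1:
            raise ValueError("stutter_decay must lie in [0, 1)")
        for name in ("n_samples", "n_loci", "n_signatures", "n_genes",
                     "genome_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if len(self.exposure_concentration) != self.n_signatures:
            raise ValueError(
                f"exposure_concentration has {len(self.exposure_concentration)} "
                f"entries for n_signatures={self.n_signatures}"
            )

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:04d}" for i in range(self.n_samples)]


@dataclass
class GroundTruth:
    """Latent state of a simulated cohort; downstream recovery tests read
    labels only from here, never from file naming."""

    dmmr: pd.Series | None = None                 # sample -> bool
    loci: list = field(default_factory=list)      # MicrosatelliteLocus
    locus_instability: pd.DataFrame | None = None # samples x loci bool
    signatures: pd.DataFrame | None = None        # 96 x K, columns sum to 1
    exposures: pd.DataFrame | None = None         # samples x K proportions
    mutation_counts: pd.Series | None = None      # sample -> count
    variant_class: pd.Series | None = None        # record -> somatic/germline/artifact
    infiltrate: pd.Series | None = None           # sample -> latent factor
    panel_genes: list = field(default_factory=list)
    panel_loadings: pd.Series | None = None

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        for name in self.__dataclass_fields__:
            v = getattr(other, name)
            if v is not None and not (isinstance(v, list) and not v):
                setattr(self, name, v)
        return self


def _draw_dmmr_labels(cfg: SimConfig, rng) -> pd.Series:
    n_dmmr = int(round(cfg.frac_dmmr * cfg.n_samples))
    flags = np.zeros(cfg.n_samples, dtype=bool)
    flags[rng.permutation(cfg.n_samples)[:n_dmmr]] = True
    return pd.Series(flags, index=cfg.sample_ids(), name="dmmr")


# ---------------------------------------------------------------------------
# Locus histograms
# ---------------------------------------------------------------------------


def simulate_locus_histograms(cfg: SimConfig, rng=None,
                              dmmr: pd.Series | None = None):
    """Stutter-noise allele-length histograms for every sample x locus.

    Each histogram is modal at the locus's reference repeat count, with
    stutter alleles at +/-k repeat units carrying read counts that decay
    geometrically by ``stutter_decay``.  In dMMR samples each locus
    independently becomes unstable with probability ``p_unstable_locus``,
    gaining a novel allele >=2 repeat units from the mode supported by at
    least 10% of the modal read count.

    Returns ``(hist, truth)``: a tidy histogram table (sample_id, locus_id,
    repeat_length, read_count) and a :class:`GroundTruth` with dMMR labels,
    locus definitions, and the per-sample-per-locus instability flags.
    """
    if rng is None:
        rng = np.random.default_rng(stage_seed(cfg.seed, "histograms"))
    if dmmr is None:
        dmmr = _draw_dmmr_labels(cfg, rng)

    loci = []
    for i in range(cfg.n_loci):
        repeat = int(rng.integers(10, 26))
        start = 1000 + i * 200
        loci.append(MicrosatelliteLocus(
            locus_id=f"MS{i + 1:05d}", chrom=cfg.chrom_name,
            start=start, end=start + repeat, repeat_unit="A",
            reference_repeat_count=repeat,
        ))

    offsets = np.arange(-cfg.max_stutter_offset, cfg.max_stutter_offset + 1)
    weights = cfg.stutter_decay ** np.abs(offsets).astype(float)
    weights /= weights.sum()

    rows = []
    instab = np.zeros((cfg.n_samples, cfg.n_loci), dtype=bool)
    for si, sample in enumerate(cfg.sample_ids()):
        for li, locus in enumerate(loci):
            depth = int(rng.poisson(cfg.read_depth))
            if depth == 0:
                continue
            counts = rng.multinomial(depth, weights)
            hist = {}
            for off, c in zip(offsets, counts):
                if c > 0:
                    hist[locus.reference_repeat_count + int(off)] = int(c)
            modal = hist.get(locus.reference_repeat_count, 0)
            if dmmr[sample] and modal > 0 and rng.random() < cfg.p_unstable_locus:
                delta = int(rng.integers(2, 7))
                sign = 1 if rng.random() < 0.5 else -1
                if locus.reference_repeat_count + sign * delta < 1:
                    sign = 1
                novel_len = locus.reference_repeat_count + sign * delta
                support = max(
                    int(round(cfg.novel_allele_fraction * modal)),
                    int(np.ceil(0.1 * modal)), 1,
                )
                hist[novel_len] = hist.get(novel_len, 0) + support
                instab[si, li] = True
            for length in sorted(hist):
                rows.append((sample, locus.locus_id, length, hist[length]))

    hist_df = pd.DataFrame(rows, columns=["sample_id", "locus_id",
                                          "repeat_length", "read_count"])
    truth = GroundTruth(
        dmmr=dmmr,
        loci=loci,
        locus_instability=pd.DataFrame(
            instab, index=cfg.sample_ids(), columns=[l.locus_id for l in loci]
        ),
    )
    return hist_df, truth


# ---------------------------------------------------------------------------
# Mutation catalogs on a synthetic chromosome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G on 0..3 codes
_PYRIMIDINE = np.array([False, True, False, True])  # C, T


def _make_reference_sequence(cfg: SimConfig, rng) -> str:
    codes = rng.integers(0, 4, size=cfg.genome_length)
    return _BASES[codes].tobytes().decode()


def _context_groups(seq_codes: np.ndarray):
    """Map every interior position to its 32-way pyrimidine ref-context group
    (ref base C/T x 5' x 3', purines folded by reverse complement).

    Group id = is_T * 16 + five * 4 + three.  Returns (group ids, 0-based
    interior positions).
    """
    center = seq_codes[1:-1]
    left = seq_codes[:-2]
    right = seq_codes[2:]
    pyr = _PYRIMIDINE[center]
    ref_pyr = np.where(pyr, center, _COMP_IDX[center])
    five = np.where(pyr, left, _COMP_IDX[right])
    three = np.where(pyr, right, _COMP_IDX[left])
    is_t = (ref_pyr == 3).astype(int)
    group = is_t * 16 + five * 4 + three
    pos0 = np.arange(1, len(seq_codes) - 1)
    return group, pos0


def _channel_decomposition():
    """For each of the 96 channels: its 32-way context group and the
    pyrimidine-strand alt base code."""
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    groups, alts = [], []
    for label in CHANNELS:
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        is_t = int(ref == "T")
        groups.append(is_t * 16 + base_code[five] * 4 + base_code[three])
        alts.append(base_code[alt])
    return np.array(groups), np.array(alts)


_CHANNEL_GROUP, _CHANNEL_ALT = _channel_decomposition()


def draw_exposures(cfg: SimConfig, dmmr: pd.Series, rng,
                   signature_names=REFERENCE_NAMES) -> pd.DataFrame:
    """Dirichlet exposure proportions per sample; dMMR samples use a
    concentration vector with the MMR-type entries multiplied by
    ``dmmr_exposure_boost``."""
    alpha = np.asarray(cfg.exposure_concentration, dtype=float)
    boost = alpha.copy()
    for i, name in enumerate(signature_names[: cfg.n_signatures]):
        if name in DMMR_SIGNATURE_NAMES:
            boost[i] *= cfg.dmmr_exposure_boost
    rows = [rng.dirichlet(boost if dmmr[s] else alpha) for s in dmmr.index]
    return pd.DataFrame(rows, index=dmmr.index,
                        columns=list(signature_names[: cfg.n_signatures]))


def simulate_mutation_catalogs(cfg: SimConfig, signatures: pd.DataFrame | None = None,
                               rng=None, dmmr: pd.Series | None = None):
    """Mutation catalogs drawn from a mixture of reference signatures.

    Per sample: exposure proportions are drawn from a Dirichlet (MMR-type
    concentration boosted for dMMR samples), a mutation count from a negative
    binomial (or Poisson) around ``mutations_per_sample``, each mutation a
    96-channel category from the signature mixture, and a concrete SNV placed
    at a genome position whose flanking bases realize that context in the
    emitted reference (purine-strand positions via reverse complement).
    Positions are unique within a sample.

    Returns ``(records, reference, truth)`` where ``records`` is a MAF-like
    table with clean QC annotations, ``reference`` maps the synthetic
    chromosome name to its sequence, and ``truth`` carries the signatures,
    exposures and counts.
    """
    if rng is None:
        rng = np.random.default_rng(stage_seed(cfg.seed, "mutations"))
    if signatures is None:
        signatures = make_reference_signatures().iloc[:, : cfg.n_signatures]
    S = np.asarray(signatures, dtype=float)
    if S.shape[0] != 96:
        raise ValueError("signatures must have 96 channel rows")
    if not np.allclose(S.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("signature columns must sum to 1 within 1e-9")
    if S.shape[1] != len(cfg.exposure_concentration):
        raise ValueError(
            f"{S.shape[1]} signatures but {len(cfg.exposure_concentration)} "
            "concentration parameters"
        )
    if dmmr is None:
        dmmr = _draw_dmmr_labels(cfg, rng)

    seq = _make_reference_sequence(cfg, rng)
    seq_codes = np.frombuffer(seq.encode(), dtype="S1")
    seq_codes = np.searchsorted(_BASES, seq_codes)
    group_ids, pos0 = _context_groups(seq_codes)
    pool_by_group = {g: pos0[group_ids == g] for g in range(32)}

    exposures = draw_exposures(cfg, dmmr, rng,
                               signature_names=list(signatures.columns))
    mean = cfg.mutations_per_sample
    rows = []
    counts = {}
    for sample in dmmr.index:
        if cfg.count_model == "poisson":
            n_mut = int(rng.poisson(mean))
        else:
            size = cfg.count_dispersion
            n_mut = int(rng.negative_binomial(size, size / (size + mean)))
        counts[sample] = n_mut
        mixture = S @ exposures.loc[sample].to_numpy()
        channel_counts = rng.multinomial(n_mut, mixture)
        # Draw positions jointly per context group so positions are unique
        # within the sample (two channels can share a group).
        for g in range(32):
            chans = np.where(_CHANNEL_GROUP == g)[0]
            k = int(channel_counts[chans].sum())
            if k == 0:
                continue
            pool = pool_by_group[g]
            chosen = rng.choice(pool, size=k, replace=k > len(pool))
            labels = np.repeat(chans, channel_counts[chans])
            for p0, ch in zip(chosen, labels):
                ref_code = seq_codes[p0]
                alt_pyr = _CHANNEL_ALT[ch]
                alt_code = alt_pyr if _PYRIMIDINE[ref_code] else _COMP_IDX[alt_pyr]
                depth = int(rng.integers(100, 301))
                af = rng.uniform(0.2, 0.6)
                rows.append((
                    sample, cfg.chrom_name, int(p0) + 1,
                    seq[p0], _BASES[alt_code].decode(), "SNV",
                    depth, int(round(af * depth)),
                    60.0, float(np.round(rng.uniform(1, 50), 3)),
                    float(np.round(rng.uniform(0, 0.02), 5)), 0, 0,
                    False, False, "",
                ))

    from .variants import MAF_COLUMNS

    records = pd.DataFrame(rows, columns=MAF_COLUMNS)
    records = records.sort_values(["sample_id", "pos"], kind="stable").reset_index(drop=True)
    truth = GroundTruth(
        dmmr=dmmr,
        signatures=pd.DataFrame(S, index=list(CHANNELS), columns=signatures.columns),
        exposures=exposures,
        mutation_counts=pd.Series(counts, name="n_mutations"),
    )
    return records, {cfg.chrom_name: seq}, truth


# ---------------------------------------------------------------------------
# Variant spike-ins
# ---------------------------------------------------------------------------


def simulate_variant_annotations(records: pd.DataFrame, cfg: SimConfig, rng=None):
    """Spike germline variants and low-quality artifacts into a clean catalog.

    Germline spike-ins get one of: cohort allele frequency in [0.08, 0.5],
    presence in 2-3 population databases, or an alternate-read fraction of
    1.0 — each clear of its filter boundary by a margin; a
    ``cosmic_rescue_fraction`` of them additionally carries a COSMIC somatic
    count >= 10.  Artifacts get mapping quality <= 35, depth <= 50, or an
    alternate fraction <= 0.03.  Returns ``(annotated, truth)`` with
    ``truth.variant_class`` in {somatic, germline, artifact} per record.
    """
    if len(records) == 0:
        raise ValueError("no records to annotate")
    if rng is None:
        rng = np.random.default_rng(stage_seed(cfg.seed, "annotations"))
    r = records.copy()
    n = len(r)
    u = rng.random(n)
    is_germ = u < cfg.germline_rate
    is_art = (~is_germ) & (u < cfg.germline_rate + cfg.artifact_rate)
    labels = pd.Series("somatic", index=r.index, dtype=object)
    labels[is_germ] = "germline"
    labels[is_art] = "artifact"

    for i in r.index[is_germ]:
        mech = rng.integers(0, 3)
        if mech == 0:
            r.at[i, "cohort_af"] = float(np.round(rng.uniform(0.08, 0.5), 5))
        elif mech == 1:
            r.at[i, "db_hits"] = int(rng.integers(2, 4))
        else:
            r.at[i, "alt_reads"] = int(r.at[i, "depth"])
        if rng.random() < cfg.cosmic_rescue_fraction:
            r.at[i, "cosmic_count"] = int(rng.integers(10, 100))

    for i in r.index[is_art]:
        mech = rng.integers(0, 3)
        if mech == 0:
            r.at[i, "mapq"] = float(np.round(rng.uniform(10, 35), 2))
        elif mech == 1:
            depth = int(rng.integers(10, 51))
            r.at[i, "depth"] = depth
            r.at[i, "alt_reads"] = max(1, int(round(0.4 * depth)))
        else:
            r.at[i, "alt_reads"] = max(0, int(np.floor(0.03 * r.at[i, "depth"])))

    return r, GroundTruth(variant_class=labels)


# ---------------------------------------------------------------------------
# Expression and clinical layers
# ---------------------------------------------------------------------------


def simulate_expression(cfg: SimConfig, dmmr_activity: pd.Series, rng=None):
    """TPM expression matrix with an infiltrate factor tied to dMMR activity.

    The latent infiltrate factor is
    ``infiltrate_effect * z(activity) + sqrt(1 - effect^2) * noise`` (unit
    variance, correlation ``infiltrate_effect`` with activity by
    construction).  The bundled 32-gene checkpoint panel loads positively on
    the factor with gene-specific loadings around ``panel_loading``
    (log-scale correlation = loading); the remaining genes are independent
    log-normal noise.  Values are strictly positive TPMs.

    Returns ``(expr, truth)``: genes x samples DataFrame and ground truth
    with the factor, panel genes, and loadings.
    """
    act = np.asarray(dmmr_activity, dtype=float)
    if np.any((act < 0) | (act > 1)):
        raise ValueError("activities must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(stage_seed(cfg.seed, "expression"))
    samples = list(dmmr_activity.index)
    n = len(samples)
    sd = act.std()
    z = (act - act.mean()) / sd if sd > 0 else np.zeros(n)
    e = cfg.infiltrate_effect
    factor = e * z + np.sqrt(max(1 - e**2, 0.0)) * rng.standard_normal(n)

    panel = checkpoint_panel()
    background = [f"G{i + 1:05d}" for i in range(max(cfg.n_genes - len(panel), 0))]
    genes = panel + background
    loadings = np.clip(
        rng.uniform(cfg.panel_loading - 0.05, cfg.panel_loading + 0.05, len(panel)),
        0.0, 0.99,
    )
    X = np.empty((len(genes), n))
    base = rng.uniform(1.0, 4.0, size=len(genes))  # per-gene mean log-TPM
    for gi, gene in enumerate(genes):
        if gi < len(panel):
            lam = loadings[gi]
            logx = lam * factor + np.sqrt(1 - lam**2) * rng.standard_normal(n)
        else:
            logx = rng.standard_normal(n)
        X[gi] = np.exp(base[gi] + cfg.expression_scale * logx)
    expr = pd.DataFrame(np.round(X, 4), index=genes, columns=samples)
    truth = GroundTruth(
        infiltrate=pd.Series(factor, index=samples, name="infiltrate"),
        panel_genes=panel,
        panel_loadings=pd.Series(loadings, index=panel, name="loading"),
    )
    return expr, truth


def simulate_clinical(cfg: SimConfig, dmmr: pd.Series, rng=None) -> pd.DataFrame:
    """Cohort table with biopsy sites and exponentially distributed survival.

    pMMR survival is exponential with median ``baseline_median_years``; dMMR
    hazard is multiplied by ``hazard_ratio``.  Censoring is an independent
    exponential clock with mean ``censoring_mean_years``.
    """
    if rng is None:
        rng = np.random.default_rng(stage_seed(cfg.seed, "clinical"))
    if not set(pd.unique(dmmr)) <= {True, False}:
        raise ValueError("dmmr labels must be binary")
    lam_p = np.log(2) / cfg.baseline_median_years
    rows = []
    for sample in dmmr.index:
        lam = lam_p * (cfg.hazard_ratio if dmmr[sample] else 1.0)
        t = rng.exponential(1.0 / lam)
        c = rng.exponential(cfg.censoring_mean_years)
        site = rng.choice(["bone", "lymph_node", "other"], p=[0.35, 0.45, 0.20])
        rows.append((sample, sample.replace("S", "P", 1), bool(dmmr[sample]), site,
                     float(np.round(min(t, c), 4)), bool(t <= c)))
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "dmmr",
                                       "site", "time_years", "event"])


@dataclass
class SyntheticCohort:
    """Everything one simulated cohort produces, plus its ground truth."""

    config: SimConfig
    histograms: pd.DataFrame
    records: pd.DataFrame
    reference: dict
    expression: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Run every generator stage under per-stage seeds fanned out from
    ``cfg.seed``; all stages share one set of dMMR labels."""
    label_rng = np.random.default_rng(stage_seed(cfg.seed, "labels"))
    dmmr = _draw_dmmr_labels(cfg, label_rng)
    truth = GroundTruth(dmmr=dmmr)

    hist, t1 = simulate_locus_histograms(
        cfg, np.random.default_rng(stage_seed(cfg.seed, "histograms")), dmmr=dmmr)
    truth.merge(t1)
    records, reference, t2 = simulate_mutation_catalogs(
        cfg, rng=np.random.default_rng(stage_seed(cfg.seed, "mutations")), dmmr=dmmr)
    truth.merge(t2)
    records, t3 = simulate_variant_annotations(
        records, cfg, np.random.default_rng(stage_seed(cfg.seed, "annotations")))
    truth.merge(t3)
    dmmr_activity = t2.exposures[list(DMMR_SIGNATURE_NAMES)].sum(axis=1)
    expr, t4 = simulate_expression(
        cfg, dmmr_activity, np.random.default_rng(stage_seed(cfg.seed, "expression")))
    truth.merge(t4)
    clinical = simulate_clinical(
        cfg, dmmr, np.random.default_rng(stage_seed(cfg.seed, "clinical")))
    return SyntheticCohort(config=cfg, histograms=hist, records=records,
                           reference=reference, expression=expr,
                           clinical=clinical, truth=truth)
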