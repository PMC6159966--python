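"""Built-in synthetic reference signatures and a loader for user references.

The four bundled signatures are synthetic 96-channel profiles with the
qualitative shapes of well-known processes — an aging-like spiky C>T-at-CpG
profile, a flat HRD-like profile, and two mismatch-repair-like C>T / T>C-rich
profiles with distinct flanking-base preferences.  They are constructed
programmatically (no external catalog is bundled) and are mutually well
separated (pairwise cosine <= 0.6) so that signature-recovery simulations are
well posed.  Real reference catalogs can be supplied as a TSV via
:func:`load_reference_signatures`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .signatures import CHANNELS

__all__ = [
    "REFERENCE_NAMES",
    "make_reference_signatures",
    "load_reference_signatures",
    "write_reference_signatures",
]

REFERENCE_NAMES = ("Aging1-like", "HRD3-like", "MMR6-like", "MMR26-like")


def _profile(main: dict[str, float], background: float) -> np.ndarray:
    """Dense profile: named channel masses plus a uniform background, sum 1."""
    p = np.full(96, background / 96.0)
    for label, mass in main.items():
        p[CHANNELS.index(label)] += mass
    return p / p.sum()


def make_reference_signatures() -> pd.DataFrame:
    """The four bundled signatures as a channels x 4 DataFrame (columns sum to 1)."""
    bases = "ACGT"
    aging = _profile({f"{b}[C>T]G": 0.20 for b in bases}, background=0.20)
    flat = np.full(96, 1 / 96.0)
    mmr6_main = {f"G[C>T]{b}": 0.15 for b in bases}
    for five in bases:
        for three in bases:
            if five != "G":
                mmr6_main[f"{five}[C>T]{three}"] = 0.20 / 12
    mmr6 = _profile(mmr6_main, background=0.20)
    mmr26_main = {f"A[T>C]{b}": 0.15 for b in bases}
    for five in bases:
        for three in bases:
            if five != "A":
                mmr26_main[f"{five}[T>C]{three}"] = 0.20 / 12
    mmr26 = _profile(mmr26_main, background=0.20)
    return pd.DataFrame(
        np.column_stack([aging, flat, mmr6, mmr26]),
        index=list(CHANNELS),
        columns=list(REFERENCE_NAMES),
    )


def load_reference_signatures(path) -> pd.DataFrame:
    """Read a reference-signature TSV (one row per signature: name + 96
    channel columns) into a channels x K DataFrame in canonical channel order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CHANNELS) - set(df.columns)
    if missing:
        raise ValueError(f"reference TSV missing {len(missing)} channels, e.g. {sorted(missing)[:3]}")
    mat = df[list(CHANNELS)].T
    mat.columns = list(df.index)
    return mat.astype(float)


def write_reference_signatures(sigs: pd.DataFrame, path) -> None:
    """Inverse of :func:`load_reference_signatures` (signatures as rows)."""
    sigs.T.to_csv(path, sep="\t", index_label="signature")
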