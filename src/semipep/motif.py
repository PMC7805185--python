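"""Cleavage-site motif analysis: P6-P6' position frequency matrices,
probability-logo data, and the per-sample feature table fed to the
statistics layer.

Counting is identification-based: each distinct (peptide, side) site
counts once per sample in which it was observed, regardless of
intensity (intensity weighting is available as an option).  ``_`` pads
introduced by protein termini are excluded from both numerator and
denominator at the affected position, so each position's frequencies
sum to 1 over the residues actually observed there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, PAD
from .tryptic import POSITIONS, CleavageSite


@dataclass
class PositionFrequencyMatrix:
    """20 amino acids x 12 positions, counts and relative frequencies."""

    counts: pd.DataFrame       # int counts, index AMINO_ACIDS, columns POSITIONS
    frequencies: pd.DataFrame  # counts / per-position totals; NaN if no obs
    n_sites: int


@dataclass
class LogoSpec:
    """Per position: (symbol, height) stacks, height = relative frequency,
    ordered ascending so the tallest symbol sits on top of the stack."""

    stacks: dict[str, list[tuple[str, float]]]


def dedupe_sites(sites: list[CleavageSite]) -> list[CleavageSite]:
    """One site per distinct (peptide, side)."""
    seen: set[tuple[str, str]] = set()
    out = []
    for s in sites:
        key = (s.peptide, s.side)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def position_frequencies(sites: list[CleavageSite],
                         sample: str | None = None,
                         weights: dict[tuple[str, str], float] | None = None
                         ) -> PositionFrequencyMatrix:
    """Tally residues per Schechter-Berger position over the sites
    observed in ``sample`` (all sites when ``sample`` is None).

    ``weights`` optionally maps (peptide, side) to a weight (e.g. LFQ
    intensity) for intensity-weighted counting.
    """
    if sample is not None:
        sites = [s for s in sites if sample in s.sample_ids]
    sites = dedupe_sites(sites)
    counts = np.zeros((len(AMINO_ACIDS), len(POSITIONS)))
    ai = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    for s in sites:
        w = weights.get((s.peptide, s.side), 0.0) if weights else 1.0
        for j, ch in enumerate(s.window):
            if ch == PAD:
                continue
            counts[ai[ch], j] += w
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / np.where(totals > 0, totals, 1.0),
                         np.nan)
    idx = pd.Index(list(AMINO_ACIDS), name="aa")
    cols = pd.Index(POSITIONS, name="position")
    return PositionFrequencyMatrix(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        frequencies=pd.DataFrame(freqs, index=idx, columns=cols),
        n_sites=len(sites),
    )


def logo_matrix(pfm: PositionFrequencyMatrix) -> LogoSpec:
    """Probability-logo stacks: symbol heights equal relative frequencies."""
    stacks: dict[str, list[tuple[str, float]]] = {}
    for pos in POSITIONS:
        col = pfm.frequencies[pos].dropna()
        col = col[col > 0].sort_values()
        stacks[pos] = [(aa, float(f)) for aa, f in col.items()]
    return LogoSpec(stacks)


def plot_logo(spec: LogoSpec, ax=None):
    """Render a simple frequency-scaled letter-stack logo with matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 2.5))
    for x, pos in enumerate(POSITIONS):
        y = 0.0
        for aa, h in spec.stacks.get(pos, []):
            ax.text(x, y + h / 2, aa, ha="center", va="center",
                    fontsize=4 + 16 * h, family="monospace")
            y += h
    ax.set_xticks(range(len(POSITIONS)), POSITIONS)
    ax.set_xlim(-0.6, len(POSITIONS) - 0.4)
    ax.set_ylim(0, 1.02)
    ax.set_ylabel("relative frequency")
    ax.axvline(5.5, color="0.6", ls="--", lw=0.8)  # scissile bond P1 | P1'
    return ax


def feature_name(aa: str, position: str) -> str:
    return f"{aa}@{position}"


def motif_feature_table(pfms: dict[str, PositionFrequencyMatrix]) -> pd.DataFrame:
    """Samples x 240 table of per-position amino-acid frequencies.

    Columns are named ``<aa>@<position>``; cells are NaN where a sample
    had zero observations at that position.
    """
    cols = [feature_name(aa, pos) for pos in POSITIONS for aa in AMINO_ACIDS]
    rows = {}
    for sample, pfm in pfms.items():
        flat = {feature_name(aa, pos): pfm.frequencies.at[aa, pos]
                for pos in POSITIONS for aa in AMINO_ACIDS}
        rows[sample] = flat
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "sample"
    return df
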