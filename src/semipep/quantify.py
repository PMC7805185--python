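"""Relative abundance and the NRASP proteolysis index.

NRASP (normalized relative abundance of semi-tryptic peptides) is the
ratio of a group's semi-tryptic relative abundance to its fully tryptic
relative abundance.  If proteolysis acts proportionally on a group, its
semi- and fully tryptic signals move together and NRASP stays at 1;
NRASP above (below) 1 indicates relatively more (less) proteolysis of
that group than of the community average.

Relative abundance of a group in a sample is the summed LFQ intensity
of the group's peptides of one stratum (semi or full) divided by the
summed intensity of *all* peptides of that stratum in the sample
(normalization is global per stratum; peptides here are the microbial
partition unless the caller passes a different one).  Missing
intensities contribute zero to sums; a zero denominator leaves the
whole column undefined.  NRASP is missing whenever the fully tryptic
denominator is zero or unquantified -- never imputed at this stage.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import PeptideRecord
from .tryptic import TrypticStatus

logger = logging.getLogger(__name__)

_STRATA = {
    "semi": (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C),
    "full": (TrypticStatus.FULL,),
}


def relative_abundance(records: list[PeptideRecord],
                       statuses: dict[str, TrypticStatus],
                       membership: dict[str, set[str]],
                       stratum: str,
                       sample_ids: list[str],
                       exclude: set[tuple[str, str]] = frozenset(),
                       groups: list[str] | None = None) -> pd.DataFrame:
    """Groups x samples relative-abundance matrix for one stratum.

    ``exclude`` holds (peptide, sample) pairs to drop (in-source
    flagged).  ``groups`` fixes the row axis; by default it is the
    sorted union of group labels seen in ``membership``.
    """
    if stratum not in _STRATA:
        raise ValueError(f"stratum must be 'semi' or 'full', got {stratum!r}")
    wanted = _STRATA[stratum]
    if groups is None:
        groups = sorted({g for gs in membership.values() for g in gs})
    gi = {g: k for k, g in enumerate(groups)}
    si = {s: k for k, s in enumerate(sample_ids)}
    num = np.zeros((len(groups), len(sample_ids)))
    den = np.zeros(len(sample_ids))
    counts = np.zeros((len(groups), len(sample_ids)), dtype=int)
    for r in records:
        if statuses.get(r.sequence) not in wanted:
            continue
        for s, v in r.intensities.items():
            if s not in si or (r.sequence, s) in exclude:
                continue
            j = si[s]
            den[j] += v
            for g in membership.get(r.sequence, ()):
                if g in gi:
                    num[gi[g], j] += v
                    counts[gi[g], j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    empty = [s for s, j in si.items() if den[j] == 0]
    if empty:
        logger.warning("relative_abundance(%s): no quantified peptides in "
                       "sample(s) %s; columns undefined", stratum, empty)
    df = pd.DataFrame(rel, index=pd.Index(groups, name="group"),
                      columns=pd.Index(sample_ids, name="sample"))
    df.attrs["peptide_counts"] = pd.DataFrame(counts, index=df.index,
                                              columns=df.columns)
    df.attrs["stratum"] = stratum
    return df


def compute_nrasp(semi: pd.DataFrame, full: pd.DataFrame) -> pd.DataFrame:
    """NRASP(g, s) = semi(g, s) / full(g, s).

    Cells where the fully tryptic denominator is zero/missing, or the
    semi numerator is missing, are NaN (never infinity or imputed).
    """
    if not semi.index.equals(full.index) or not semi.columns.equals(full.columns):
        raise ContractError("semi and full abundance matrices must share axes")
    denom = full.where(full > 0)
    nrasp = semi / denom
    nrasp.attrs["semi_counts"] = semi.attrs.get("peptide_counts")
    nrasp.attrs["full_counts"] = full.attrs.get("peptide_counts")
    return nrasp


def presence_filter(table: pd.DataFrame, min_fraction: float = 0.75) -> pd.DataFrame:
    """Keep rows with non-missing values in >= ceil(min_fraction * n) samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    threshold = math.ceil(min_fraction * table.shape[1])
    keep = table.notna().sum(axis=1) >= threshold
    return table.loc[keep]
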