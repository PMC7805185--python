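"""Tryptic status assignment, cleavage-site extraction, and in-source
fragment discrimination.

A peptide terminus is *tryptic* when it was generated by trypsin (the
preceding residue is K or R for the N-terminus, the last residue is K or
R for the C-terminus) or coincides with a protein terminus.  Peptides
with exactly one non-tryptic terminus are semi-tryptic and act as
proxies for endogenous proteolysis; the scissile bond is described with
the Schechter-Berger window P6..P1 | P1'..P6'.

Semi-tryptic species can also arise from in-source fragmentation in the
ion source.  Such artifacts co-elute with their fully tryptic parent,
carry a lower charge state (the parent's charge is split between
fragments), and deviate strongly from the retention time predicted from
their own composition.  ``flag_in_source_fragments`` applies all of
these criteria jointly and conservatively.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ClassificationError, ContractError
from .io import AMINO_ACIDS, PAD, TERMINUS, ConsensusTable, PeptideRecord

logger = logging.getLogger(__name__)

TRYPTIC_RESIDUES = "KR"

#: Schechter-Berger position labels, N- to C-terminal across the scissile bond
POSITIONS = ("P6", "P5", "P4", "P3", "P2", "P1",
             "P1'", "P2'", "P3'", "P4'", "P5'", "P6'")


class TrypticStatus(enum.Enum):
    FULL = "FULL"
    SEMI_N = "SEMI_N"
    SEMI_C = "SEMI_C"
    NON = "NON"


@dataclass
class CleavageSite:
    """A non-tryptic peptide terminus with its P6-P6' residue window.

    The cleaved bond sits between window positions 6 and 7 (P1 | P1');
    ``_`` pads mark positions beyond protein termini.
    """

    peptide: str
    side: str  # "N" or "C"
    window: str
    sample_ids: tuple[str, ...] = ()
    accession: str = ""

    def __post_init__(self):
        if len(self.window) != 12:
            raise ValueError(f"window must be 12 chars, got {self.window!r}")
        if self.side not in ("N", "C"):
            raise ValueError("side must be 'N' or 'C'")


@dataclass
class RTModel:
    """Additive retention-time model calibrated on fully tryptic peptides.

    RT ~ intercept + sum(residue_count * coef) + c * ln(length).  Only a
    relative deviation criterion is needed downstream, so a per-sample
    calibrated additive model replaces external predictors such as
    SSRCalc.
    """

    coefficients: dict[str, float]
    intercept: float
    length_coef: float
    r_squared: float
    residual_std: float
    n: int
    reliable: bool

    def predict(self, sequence: str) -> float:
        rt = self.intercept + self.length_coef * math.log(len(sequence))
        for aa in sequence:
            rt += self.coefficients.get(aa, 0.0)
        return rt

    def standardized_residual(self, sequence: str, observed_rt: float) -> float:
        if self.residual_std <= 0:
            return 0.0
        return (observed_rt - self.predict(sequence)) / self.residual_std


@dataclass
class InSourceFlag:
    peptide: str
    sample: str
    is_in_source: bool
    evidence: dict = field(default_factory=dict)


def _is_residue(ch: str) -> bool:
    return len(ch) == 1 and ch in AMINO_ACIDS


def classify_peptide(record: PeptideRecord,
                     nterm_positions: tuple[int, ...] = (1, 2)) -> TrypticStatus:
    """Assign FULL / SEMI_N / SEMI_C / NON tryptic status.

    The N-terminus is tryptic iff the preceding residue is K/R or the
    peptide starts at a protein N-terminal position (1, or 2 for
    initiator-Met removal; configurable).  The C-terminus is tryptic iff
    the last residue is K/R or the peptide ends at the protein
    C-terminus (following residue is the terminus sentinel).
    """
    pre = record.preceding_residue
    post = record.following_residue
    for ch in (pre, post):
        if not (_is_residue(ch) or ch in (TERMINUS, PAD)):
            raise ClassificationError(f"unknown flanking residue {ch!r} "
                                      f"for {record.sequence}")
    last = record.sequence[-1]
    if last not in AMINO_ACIDS:
        raise ClassificationError(f"unknown residue {last!r} in {record.sequence}")
    n_tryptic = (pre in TRYPTIC_RESIDUES or pre in (TERMINUS, PAD)
                 or record.start_pos in nterm_positions)
    c_tryptic = last in TRYPTIC_RESIDUES or post in (TERMINUS, PAD)
    if n_tryptic and c_tryptic:
        return TrypticStatus.FULL
    if c_tryptic:
        return TrypticStatus.SEMI_N
    if n_tryptic:
        return TrypticStatus.SEMI_C
    return TrypticStatus.NON


def classify_all(consensus: ConsensusTable,
                 nterm_positions: tuple[int, ...] = (1, 2)) -> dict[str, TrypticStatus]:
    return {r.sequence: classify_peptide(r, nterm_positions)
            for r in consensus.records}


def extract_cleavage_sites(record: PeptideRecord,
                           status: TrypticStatus) -> list[CleavageSite]:
    """Build the P6-P6' window(s) for a semi-tryptic peptide.

    For SEMI_N the non-tryptic bond precedes the peptide: P6-P1 are the
    last six characters of the N-term cleavage window and P1'-P6' the
    first six residues of the peptide (continued into the C-term window
    if the peptide is shorter than six).  SEMI_C is the mirror image.
    """
    if status not in (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C):
        raise ContractError(f"cleavage sites only defined for semi-tryptic "
                            f"peptides, got {status}")
    acc = record.protein_accessions[0] if record.protein_accessions else ""
    samples = tuple(sorted(record.intensities))
    if status is TrypticStatus.SEMI_N:
        left = record.nterm_window[-6:].rjust(6, PAD)
        right = (record.sequence + record.cterm_window)[:6].ljust(6, PAD)
        side = "N"
    else:
        left = (record.nterm_window + record.sequence)[-6:].rjust(6, PAD)
        right = record.cterm_window[:6].ljust(6, PAD)
        side = "C"
    return [CleavageSite(record.sequence, side, left + right, samples, acc)]


def fit_rt_model(records: list[PeptideRecord], sample: str,
                 min_n: int = 50) -> RTModel:
    """Least-squares fit of RT ~ intercept + residue counts + c*ln(length).

    Only records quantified in ``sample`` enter the fit.  Below ``min_n``
    peptides (or a rank-deficient design) the model is flagged
    unreliable and the downstream RT-residual criterion is disabled.
    """
    fit_recs = [r for r in records if sample in r.intensities]
    n = len(fit_recs)
    if n == 0:
        return RTModel({aa: 0.0 for aa in AMINO_ACIDS}, 0.0, 0.0, 0.0, 0.0, 0, False)
    X = np.zeros((n, len(AMINO_ACIDS) + 1))
    y = np.array([r.retention_time for r in fit_recs])
    idx = {aa: j for j, aa in enumerate(AMINO_ACIDS)}
    for i, r in enumerate(fit_recs):
        for aa in r.sequence:
            X[i, idx[aa]] += 1.0
        X[i, -1] = math.log(len(r.sequence))
    # centered fit: the intercept absorbs the means, and a constant RT
    # yields exactly zero coefficients (minimum-norm solution)
    xm, ym = X.mean(axis=0), float(y.mean())
    beta, _, rank, _ = np.linalg.lstsq(X - xm, y - ym, rcond=None)
    intercept = ym - float(xm @ beta)
    resid = y - (X @ beta + intercept)
    ss_res = float(resid @ resid)
    ss_tot = float(((y - ym) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    dof = max(n - X.shape[1] - 1, 1)
    reliable = n >= min_n and rank == X.shape[1]
    return RTModel(
        coefficients={aa: float(beta[idx[aa]]) for aa in AMINO_ACIDS},
        intercept=intercept,
        length_coef=float(beta[-1]),
        r_squared=r2,
        residual_std=math.sqrt(ss_res / dof),
        n=n,
        reliable=reliable,
    )


def _parent_candidates(frag: PeptideRecord, status: TrypticStatus,
                       fulls_by_acc: dict[str, list[PeptideRecord]]):
    """FULL peptides at the same protein locus that share the fragment's
    tryptic terminus and extend past its non-tryptic terminus."""
    seen = set()
    for acc in frag.protein_accessions:
        for parent in fulls_by_acc.get(acc, ()):
            if parent.sequence in seen or len(parent.sequence) <= len(frag.sequence):
                continue
            if status is TrypticStatus.SEMI_N:
                ok = parent.sequence.endswith(frag.sequence)
            else:  # SEMI_C: shares the tryptic N-terminus
                ok = parent.sequence.startswith(frag.sequence)
            if ok:
                seen.add(parent.sequence)
                yield parent


def flag_in_source_fragments(consensus: ConsensusTable,
                             statuses: dict[str, TrypticStatus],
                             rt_models: dict[str, RTModel] | None,
                             rt_tol_min: float = 1.0,
                             resid_z: float = 3.0) -> list[InSourceFlag]:
    """Flag semi-tryptic peptides that behave like in-source fragments.

    A peptide is flagged in a sample iff, for some fully tryptic parent
    candidate detected in the same sample: (i) the parent is a
    superstring at the same locus sharing the tryptic terminus, (ii)
    |RT_fragment - RT_parent| <= ``rt_tol_min``, (iii) the fragment's
    charge is lower than the parent's, and (iv) the fragment's
    standardized RT-model residual exceeds ``resid_z`` while the
    parent's does not.  Criterion (iv) is skipped (with a warning) when
    no reliable RT model exists for the sample.
    """
    fulls_by_acc: dict[str, list[PeptideRecord]] = {}
    for r in consensus.records:
        if statuses.get(r.sequence) is TrypticStatus.FULL:
            for acc in r.protein_accessions:
                fulls_by_acc.setdefault(acc, []).append(r)
    warned: set[str] = set()
    flags: list[InSourceFlag] = []
    for r in consensus.records:
        status = statuses.get(r.sequence)
        if status not in (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C):
            continue
        for sample in sorted(r.intensities):
            model = rt_models.get(sample) if rt_models else None
            use_resid = model is not None and model.reliable
            if not use_resid and sample not in warned:
                logger.warning("no reliable RT model for sample %s; "
                               "RT-residual criterion skipped", sample)
                warned.add(sample)
            hit = None
            for parent in _parent_candidates(r, status, fulls_by_acc):
                if sample not in parent.intensities:
                    continue
                drt = abs(r.retention_time - parent.retention_time)
                if drt > rt_tol_min or r.charge >= parent.charge:
                    continue
                if use_resid:
                    z_frag = abs(model.standardized_residual(r.sequence,
                                                             r.retention_time))
                    z_par = abs(model.standardized_residual(parent.sequence,
                                                            parent.retention_time))
                    if z_frag <= resid_z or z_par > resid_z:
                        continue
                else:
                    z_frag = z_par = float("nan")
                hit = {"parent_found": True, "parent": parent.sequence,
                       "rt_delta_to_parent": drt,
                       "charge_drop": parent.charge - r.charge,
                       "rt_prediction_residual": z_frag}
                break
            if hit is not None:
                flags.append(InSourceFlag(r.sequence, sample, True, hit))
    return flags


def in_source_exclusions(flags: list[InSourceFlag]) -> set[tuple[str, str]]:
    """(peptide, sample) pairs to exclude from proteolysis analyses."""
    return {(f.peptide, f.sample) for f in flags if f.is_in_source}
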