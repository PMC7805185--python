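"""Peptide identification tables, protein FASTA databases and sample metadata.

The central record type mirrors one row of a MaxQuant ``peptides.txt``:
the identified sequence, its flanking context in the leading protein
(preceding/following residue plus fixed-width N-/C-terminal cleavage
windows), the proteins it maps to, and per-sample label-free (LFQ)
intensities.  Two table dialects are supported:

``maxquant``
    MaxQuant column names (``Sequence``, ``Amino acid before``,
    ``N-term cleavage window`` ..., ``LFQ intensity <sample>``).
``generic``
    lower-case equivalents (``sequence``, ``aa_before``, ...,
    ``intensity_<sample>``); this is also the dialect the writer emits,
    so write -> read round-trips are lossless.

Conventions (documented, MaxQuant-compatible):

* positions are 1-based inclusive in the leading (first listed) protein;
* a blank or zero LFQ cell means *not quantified* and is stored as a
  missing intensity, never as a measured zero;
* cleavage windows have a fixed configured width ``w`` (default 15) and
  are padded with ``_`` beyond protein termini;
* ``-`` as preceding/following residue marks a protein terminus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AnnotationError, ConsistencyError, FormatError

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
TERMINUS = "-"

SOURCE_CLASSES = ("microbial", "human", "food", "contaminant")

#: per-dialect mapping of logical field -> column name
_DIALECTS = {
    "maxquant": {
        "sequence": "Sequence",
        "aa_before": "Amino acid before",
        "aa_after": "Amino acid after",
        "nterm_window": "N-term cleavage window",
        "cterm_window": "C-term cleavage window",
        "proteins": "Proteins",
        "start": "Start position",
        "end": "End position",
        "charge": "Charges",
        "rt": "Retention time",
        "pep": "PEP",
    },
    "generic": {
        "sequence": "sequence",
        "aa_before": "aa_before",
        "aa_after": "aa_after",
        "nterm_window": "nterm_window",
        "cterm_window": "cterm_window",
        "proteins": "proteins",
        "start": "start",
        "end": "end",
        "charge": "charge",
        "rt": "retention_time",
        "pep": "pep",
    },
}
_INTENSITY_PREFIX = {"maxquant": "LFQ intensity ", "generic": "intensity_"}


@dataclass
class PeptideRecord:
    """One identified peptide in one dataset."""

    sequence: str
    preceding_residue: str = TERMINUS
    following_residue: str = TERMINUS
    nterm_window: str = ""
    cterm_window: str = ""
    protein_accessions: list[str] = field(default_factory=list)
    start_pos: int = 1
    end_pos: int = 1
    charge: int = 2
    retention_time: float = 0.0
    pep: float = 0.0
    intensities: dict[str, float] = field(default_factory=dict)
    source_engine: str = ""

    def validate(self) -> None:
        if len(self.sequence) < 5:
            raise ValueError(f"sequence shorter than 5 residues: {self.sequence!r}")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-amino-acid character(s) {sorted(bad)} in {self.sequence!r}")
        if self.start_pos > self.end_pos:
            raise ValueError("start_pos > end_pos")
        if not 0.0 <= self.pep <= 1.0:
            raise ValueError(f"PEP outside [0,1]: {self.pep}")


@dataclass
class EngineResult:
    """All records reported by one search engine for one dataset."""

    engine_id: str
    records: list[PeptideRecord]

    def sequences(self) -> set[str]:
        return {r.sequence for r in self.records}


@dataclass
class ConsensusTable:
    """Peptides identified by every required engine.

    Record payloads (intensities, RT, charge, windows) come from the
    designated quantitation engine; ``provenance`` maps each sequence to
    the set of engines that identified it.
    """

    records: list[PeptideRecord]
    provenance: dict[str, set[str]]


@dataclass
class ProteinEntry:
    description: str
    sequence: str
    source_class: str = "microbial"


@dataclass
class ProteinDatabase:
    entries: dict[str, ProteinEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def read_fasta(cls, path, class_of=None) -> "ProteinDatabase":
        """Read a FASTA file (multi-line wrapped accepted).

        The source class of each accession is taken from a ``class=...``
        token in the description if present, else from ``class_of(acc)``,
        else ``microbial``.
        """
        entries: dict[str, ProteinEntry] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            desc = rec.description[len(rec.id):].strip()
            sc = None
            for token in desc.split():
                if token.startswith("class="):
                    sc = token[len("class="):]
            if sc is None:
                sc = class_of(rec.id) if class_of is not None else "microbial"
            if sc not in SOURCE_CLASSES:
                raise FormatError(f"unknown source class {sc!r} for {rec.id}")
            entries[rec.id] = ProteinEntry(desc, str(rec.seq).upper(), sc)
        return cls(entries)

    def write_fasta(self, path) -> None:
        recs = []
        for acc, e in self.entries.items():
            desc = e.description
            if "class=" not in desc:
                desc = (desc + " " if desc else "") + f"class={e.source_class}"
            recs.append(SeqRecord(Seq(e.sequence), id=acc, description=desc))
        SeqIO.write(recs, str(path), "fasta")


@dataclass
class SampleMetadata:
    """Per-sample group/site/subject labels; sample_ids must be unique."""

    table: pd.DataFrame  # columns: sample_id, group, site, subject_id

    def __post_init__(self):
        if self.table["sample_id"].duplicated().any():
            raise FormatError("duplicate sample_id in metadata")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def group_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["group"].iloc[0]

    def groups(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["group"]))

    @classmethod
    def read_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers


def _fit_window(window: str, window_len: int, side: str) -> str:
    """Truncate/pad a cleavage window to ``window_len``.

    The residues adjacent to the peptide terminus are preserved: for the
    N-term window these are the *last* characters, for the C-term window
    the *first*.
    """
    window = window.strip()
    if side == "n":
        return window[-window_len:].rjust(window_len, PAD)
    return window[:window_len].ljust(window_len, PAD)


def read_peptide_table(path, dialect: str = "generic", window_len: int = 15,
                       engine_id: str | None = None) -> EngineResult:
    """Read a peptide identification table into an :class:`EngineResult`.

    Raises :class:`FormatError` naming the first missing mandatory column;
    rows whose sequence contains a non-amino-acid character raise a
    row-level :class:`FormatError` carrying the row index.
    """
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}")
    cols = _DIALECTS[dialect]
    prefix = _INTENSITY_PREFIX[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical, name in cols.items():
        if name not in df.columns:
            raise FormatError(f"missing mandatory column {name!r} ({dialect} dialect)")
    sample_cols = [c for c in df.columns if c.startswith(prefix)]
    samples = [c[len(prefix):] for c in sample_cols]

    records: list[PeptideRecord] = []
    seen: dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        seq = row[cols["sequence"]].strip().upper()
        if not seq or set(seq) - set(AMINO_ACIDS):
            raise FormatError(f"row {i}: non-amino-acid character in sequence {seq!r}")
        if len(seq) < 5:
            raise FormatError(f"row {i}: sequence shorter than 5 residues")
        intens: dict[str, float] = {}
        for sid, c in zip(samples, sample_cols):
            cell = row[c].strip()
            if cell in ("", "0", "0.0", "NaN", "nan"):
                continue  # blank/zero = not quantified
            v = float(cell)
            if v > 0:
                intens[sid] = v
        charge_str = row[cols["charge"]].split(";")[0].strip()
        rec = PeptideRecord(
            sequence=seq,
            preceding_residue=(row[cols["aa_before"]].strip() or TERMINUS),
            following_residue=(row[cols["aa_after"]].strip() or TERMINUS),
            nterm_window=_fit_window(row[cols["nterm_window"]], window_len, "n"),
            cterm_window=_fit_window(row[cols["cterm_window"]], window_len, "c"),
            protein_accessions=[a for a in row[cols["proteins"]].split(";") if a],
            start_pos=int(float(row[cols["start"]])),
            end_pos=int(float(row[cols["end"]])),
            charge=int(charge_str) if charge_str else 2,
            retention_time=float(row[cols["rt"]]) if row[cols["rt"]].strip() else 0.0,
            pep=float(row[cols["pep"]]),
            intensities=intens,
            source_engine=engine_id or "",
        )
        rec.validate()
        if seq in seen:
            # keep the more confident record; merge intensities
            prev = records[seen[seq]]
            if rec.pep < prev.pep:
                rec.intensities = {**prev.intensities, **rec.intensities}
                records[seen[seq]] = rec
            else:
                prev.intensities.update({k: v for k, v in rec.intensities.items()
                                         if k not in prev.intensities})
            logger.warning("duplicate sequence %s at row %d merged", seq, i)
            continue
        seen[seq] = len(records)
        records.append(rec)
    return EngineResult(engine_id or str(path), records)


def write_peptide_table(result: EngineResult | ConsensusTable, path,
                        dialect: str = "generic") -> None:
    """Write records as a TSV in the given dialect (generic round-trips)."""
    cols = _DIALECTS[dialect]
    prefix = _INTENSITY_PREFIX[dialect]
    records = result.records
    samples = sorted({s for r in records for s in r.intensities})
    rows = []
    for r in records:
        row = {
            cols["sequence"]: r.sequence,
            cols["aa_before"]: r.preceding_residue,
            cols["aa_after"]: r.following_residue,
            cols["nterm_window"]: r.nterm_window,
            cols["cterm_window"]: r.cterm_window,
            cols["proteins"]: ";".join(r.protein_accessions),
            cols["start"]: r.start_pos,
            cols["end"]: r.end_pos,
            cols["charge"]: r.charge,
            cols["rt"]: repr(float(r.retention_time)),
            cols["pep"]: repr(float(r.pep)),
        }
        for s in samples:
            row[prefix + s] = repr(r.intensities[s]) if s in r.intensities else ""
        rows.append(row)
    header = list(cols.values()) + [prefix + s for s in samples]
    pd.DataFrame(rows, columns=header).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# filters and cross-engine consensus


def filter_pep(result: EngineResult, threshold: float = 0.05) -> EngineResult:
    """Keep records with posterior error probability strictly below ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    kept = [r for r in result.records if r.pep < threshold]
    logger.info("filter_pep(%s): removed %d of %d records at PEP < %g",
                result.engine_id, len(result.records) - len(kept),
                len(result.records), threshold)
    return EngineResult(result.engine_id, kept)


def _match_key(match_on: str):
    if match_on == "sequence_IL_equated":
        return lambda s: s.replace("I", "L")
    if match_on == "sequence":
        return lambda s: s
    raise ValueError(f"unknown match_on {match_on!r}")


def intersect_engines(results: list[EngineResult], quant_engine: str,
                      match_on: str = "sequence") -> ConsensusTable:
    """Keep only peptides identified by *every* engine.

    Payloads are taken from ``quant_engine``; the consensus contains
    exactly the sequences whose matching key occurs in all engines.
    """
    if not results:
        raise ValueError("need at least one EngineResult")
    key = _match_key(match_on)
    keysets = [{key(r.sequence) for r in res.records} for res in results]
    consensus_keys = set.intersection(*keysets)
    try:
        quant = next(res for res in results if res.engine_id == quant_engine)
    except StopIteration:
        raise ValueError(f"quantitation engine {quant_engine!r} not among results")
    records = [r for r in quant.records if key(r.sequence) in consensus_keys]
    covered = {key(r.sequence) for r in records}
    if covered != consensus_keys:
        missing = sorted(consensus_keys - covered)[:3]
        raise ConsistencyError(
            f"quantitation engine lacks records for consensus keys {missing}")
    provenance: dict[str, set[str]] = {}
    for r in records:
        k = key(r.sequence)
        provenance[r.sequence] = {res.engine_id for res, ks in zip(results, keysets)
                                  if k in ks}
    return ConsensusTable(records, provenance)


def dereplicate_fasta(db: ProteinDatabase) -> tuple[ProteinDatabase, dict[str, str]]:
    """Collapse 100 %-identical sequences.

    Keeps the lexicographically first accession among duplicates; returns
    the reduced database and a dropped -> kept accession mapping.
    """
    by_seq: dict[str, list[str]] = {}
    for acc in sorted(db.entries):
        by_seq.setdefault(db.entries[acc].sequence, []).append(acc)
    kept: dict[str, ProteinEntry] = {}
    dropped: dict[str, str] = {}
    for accs in by_seq.values():
        keep = accs[0]
        kept[keep] = db.entries[keep]
        for a in accs[1:]:
            dropped[a] = keep
    return ProteinDatabase(kept), dropped


def classify_source(record: PeptideRecord, db: ProteinDatabase) -> str:
    """Classify a peptide by the source classes of all its accessions.

    ``microbial_unique`` means *every* accession is microbial (not shared
    by human or food sequences); mixed classes yield ``shared``; any
    contaminant accession marks the peptide ``contaminant``.
    """
    classes = set()
    for acc in record.protein_accessions:
        if acc not in db.entries:
            raise AnnotationError(f"unknown accession {acc!r}")
        classes.add(db.entries[acc].source_class)
    if "contaminant" in classes:
        return "contaminant"
    if classes == {"microbial"}:
        return "microbial_unique"
    if classes == {"human"}:
        return "human"
    if classes == {"food"}:
        return "food"
    return "shared"
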