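"""Peptide-centric taxonomic and functional annotation.

Semi-tryptic peptides are converted to their *closest fully tryptic*
form (extending through the cleavage windows to the nearest K/R or
protein terminus) before taxonomy lookup, because peptide-to-taxon
indices are built from in-silico tryptic digests.  Taxonomy is assigned
with the lowest-common-ancestor (LCA) algorithm over a user-supplied
peptide -> taxa mapping and an NCBI-style taxonomy tree, with I and L
equated by default (they are isobaric and indistinguishable by MS).
Functional annotation attaches GO biological-process terms and EC
numbers truncated to sub-class (two fields, e.g. ``1.15``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import AnnotationError
from .io import PAD, PeptideRecord
from .tryptic import TrypticStatus

CANONICAL_RANKS = ("superkingdom", "phylum", "class", "order",
                   "family", "genus", "species")

_EC_RE = re.compile(r"^\d+(\.\d+){0,3}$")


@dataclass
class TaxonomyTree:
    """Rooted taxonomy: taxid -> (parent, rank, name)."""

    nodes: dict[int, tuple[int, str, str]]
    root: int

    def __post_init__(self):
        for taxid, (parent, rank, _name) in self.nodes.items():
            if taxid != self.root and parent not in self.nodes:
                raise AnnotationError(f"parent {parent} of taxid {taxid} missing")
        # cycle check via path walking
        for taxid in self.nodes:
            self.path(taxid)

    def path(self, taxid: int) -> list[int]:
        """Root-to-node ancestor path (inclusive)."""
        if taxid not in self.nodes:
            raise AnnotationError(f"taxid {taxid} not in tree")
        out = [taxid]
        seen = {taxid}
        while taxid != self.root:
            taxid = self.nodes[taxid][0]
            if taxid in seen:
                raise AnnotationError(f"cycle in taxonomy at taxid {taxid}")
            seen.add(taxid)
            out.append(taxid)
        return out[::-1]

    def lca(self, taxids) -> int:
        taxids = list(taxids)
        if not taxids:
            raise ValueError("empty taxid set")
        paths = [self.path(t) for t in taxids]
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def name(self, taxid: int) -> str:
        return self.nodes[taxid][2]

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid][1]

    def lineage(self, taxid: int) -> dict[str, str]:
        """Names at the 7 canonical ranks along the ancestor path (gaps allowed)."""
        out: dict[str, str] = {}
        for t in self.path(taxid):
            rank = self.rank(t)
            if rank in CANONICAL_RANKS:
                out[rank] = self.name(t)
        return out

    @classmethod
    def read_tsv(cls, path) -> "TaxonomyTree":
        """Read a nodes table (columns: taxid, parent_taxid, rank, name)."""
        df = pd.read_csv(path, sep="\t", dtype={"taxid": int, "parent_taxid": int})
        nodes = {int(r.taxid): (int(r.parent_taxid), str(r.rank), str(r.name))
                 for r in df.itertuples(index=False)}
        roots = [t for t, (p, _, _) in nodes.items() if p == t]
        if len(roots) != 1:
            raise AnnotationError(f"expected exactly one root, found {roots}")
        return cls(nodes, roots[0])

    def write_tsv(self, path) -> None:
        rows = [{"taxid": t, "parent_taxid": p, "rank": r, "name": n}
                for t, (p, r, n) in sorted(self.nodes.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class AnnotatedPeptide:
    sequence: str
    status: TrypticStatus
    closest_fully_tryptic: str
    resolved: bool
    lca_taxid: int | None = None
    lineage: dict[str, str] = field(default_factory=dict)
    go_terms: set[str] = field(default_factory=set)
    ec_subclasses: set[str] = field(default_factory=set)


def equate_il(seq: str) -> str:
    return seq.replace("I", "L")


def read_peptide_taxon_map(path, equate: bool = True) -> dict[str, set[int]]:
    """Read a peptide -> taxid mapping TSV (columns: peptide, taxids as
    comma- or semicolon-separated list), keyed I/L-equated if ``equate``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, set[int]] = {}
    for r in df.itertuples(index=False):
        key = equate_il(r.peptide) if equate else r.peptide
        taxa = {int(t) for t in re.split(r"[,;]", r.taxids) if t}
        out.setdefault(key, set()).update(taxa)
    return out


def read_function_map(path) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Read a key -> GO/EC map TSV (columns: key, go_terms, ec_numbers).

    Keys may be peptides or protein accessions.  EC numbers are
    validated and truncated to sub-class on use, not here.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    go: dict[str, set[str]] = {}
    ec: dict[str, set[str]] = {}
    for r in df.itertuples(index=False):
        if r.go_terms:
            go.setdefault(r.key, set()).update(t for t in r.go_terms.split(";") if t)
        if r.ec_numbers:
            ec.setdefault(r.key, set()).update(t for t in r.ec_numbers.split(";") if t)
    return go, ec


def ec_subclass(ec: str) -> str:
    """Truncate an EC number to its sub-class, e.g. 1.15.1.1 -> 1.15."""
    if not _EC_RE.match(ec):
        raise AnnotationError(f"malformed EC number {ec!r}")
    return ".".join(ec.split(".")[:2])


# ---------------------------------------------------------------------------
# closest fully tryptic conversion


def _extend_n(sequence: str, nterm_window: str) -> tuple[str, bool]:
    """Prepend residues from the N-term window up to (excluding) the
    nearest K/R; a pad is a protein terminus and is a valid boundary."""
    prefix: list[str] = []
    for ch in reversed(nterm_window):
        if ch in "KR":
            return "".join(reversed(prefix)) + sequence, True
        if ch == PAD:
            return "".join(reversed(prefix)) + sequence, True
        prefix.append(ch)
    return sequence, False  # no boundary within the window: unresolved


def _extend_c(sequence: str, cterm_window: str) -> tuple[str, bool]:
    """Append residues from the C-term window up to and including the
    nearest K/R (or stop at a protein-terminus pad)."""
    suffix: list[str] = []
    for ch in cterm_window:
        if ch == PAD:
            return sequence + "".join(suffix), True
        suffix.append(ch)
        if ch in "KR":
            return sequence + "".join(suffix), True
    return sequence, False


def closest_fully_tryptic(record: PeptideRecord,
                          status: TrypticStatus) -> tuple[str, bool]:
    """Convert a peptide to its closest fully tryptic form.

    Returns ``(sequence, resolved)``; when no K/R lies within the
    relevant window and the window does not reach a protein terminus the
    original sequence is returned with ``resolved=False``.
    """
    if status is TrypticStatus.FULL:
        return record.sequence, True
    seq, resolved = record.sequence, True
    if status in (TrypticStatus.SEMI_N, TrypticStatus.NON):
        seq, ok = _extend_n(seq, record.nterm_window)
        resolved = resolved and ok
    if status in (TrypticStatus.SEMI_C, TrypticStatus.NON):
        seq, ok = _extend_c(seq, record.cterm_window)
        resolved = resolved and ok
    return seq, resolved


def lca_assign(peptide: str, pep2taxa: dict[str, set[int]], tree: TaxonomyTree,
               equate: bool = True) -> tuple[int | None, dict[str, str]]:
    """LCA taxonomy for one (closest fully tryptic) peptide.

    Returns ``(None, {})`` when the peptide is absent from the map.
    """
    if not peptide:
        raise ValueError("empty peptide")
    key = equate_il(peptide) if equate else peptide
    taxa = pep2taxa.get(key)
    if not taxa:
        return None, {}
    lca = tree.lca(taxa)
    return lca, tree.lineage(lca)


def split_tryptic_units(peptide: str, min_len: int = 5) -> list[str]:
    """Split a peptide with internal K/R into constituent tryptic units
    (opt-in missed-cleavage handling: the LCA is taken over the
    intersection of per-unit taxon sets)."""
    units, start = [], 0
    for i, ch in enumerate(peptide):
        if ch in "KR":
            units.append(peptide[start:i + 1])
            start = i + 1
    if start < len(peptide):
        units.append(peptide[start:])
    return [u for u in units if len(u) >= min_len] or [peptide]


def annotate_peptides(records: list[PeptideRecord],
                      statuses: dict[str, TrypticStatus],
                      pep2taxa: dict[str, set[int]],
                      tree: TaxonomyTree,
                      go_map: dict[str, set[str]] | None = None,
                      ec_map: dict[str, set[str]] | None = None,
                      equate: bool = True,
                      split_missed: bool = False) -> list[AnnotatedPeptide]:
    """Full annotation pass: conversion, LCA, GO-BP and EC sub-classes.

    Functional maps may key on peptide sequence or on the leading
    protein accession; peptide keys take precedence.
    """
    out = []
    for r in records:
        status = statuses[r.sequence]
        tryptic, resolved = closest_fully_tryptic(r, status)
        taxid, lineage = (None, {})
        if resolved:
            if split_missed:
                units = split_tryptic_units(tryptic)
                sets = []
                for u in units:
                    key = equate_il(u) if equate else u
                    if key in pep2taxa:
                        sets.append(pep2taxa[key])
                common = set.intersection(*sets) if sets else set()
                if common:
                    taxid = tree.lca(common)
                    lineage = tree.lineage(taxid)
            else:
                taxid, lineage = lca_assign(tryptic, pep2taxa, tree, equate)
        go: set[str] = set()
        ec: set[str] = set()
        lead = r.protein_accessions[0] if r.protein_accessions else None
        for m, acc_set in ((go_map, go), (ec_map, ec)):
            if not m:
                continue
            if r.sequence in m:
                acc_set.update(m[r.sequence])
            elif lead and lead in m:
                acc_set.update(m[lead])
        out.append(AnnotatedPeptide(
            sequence=r.sequence, status=status, closest_fully_tryptic=tryptic,
            resolved=resolved, lca_taxid=taxid, lineage=lineage,
            go_terms=go, ec_subclasses={ec_subclass(e) for e in ec}))
    return out


def assign_groups(annotated: list[AnnotatedPeptide],
                  ranks: tuple[str, ...] = CANONICAL_RANKS,
                  include_go: bool = True,
                  include_ec: bool = True) -> dict[str, set[str]]:
    """Peptide -> group membership (sample-independent).

    Each peptide belongs to every taxon along its LCA lineage (lineage
    closure), every GO biological-process term, and every EC sub-class
    it is annotated with.  Taxon groups are named ``taxon:<name>``, GO
    groups ``go:<term>`` and EC groups ``ec:<subclass>``; an unannotated
    peptide is a member of no group but still counts in totals.
    """
    membership: dict[str, set[str]] = {}
    for a in annotated:
        groups = set()
        for rank in ranks:
            if rank in a.lineage:
                groups.add(f"taxon:{a.lineage[rank]}")
        if include_go:
            groups.update(f"go:{t}" for t in a.go_terms)
        if include_ec:
            groups.update(f"ec:{e}" for e in a.ec_subclasses)
        membership[a.sequence] = groups
    return membership
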