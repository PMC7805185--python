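"""Ground-truthed synthetic metaproteome generator.

Emulates the data the mining pipeline consumes: a protein FASTA with
microbial / human / food / contaminant partitions, a toy gut taxonomy,
peptide -> taxa and protein -> function mapping tables, three search
engines' peptide identification tables with per-sample log-normal LFQ
intensities, and a ground-truth table recording every emitted peptide's
true tryptic status, cleavage window, parent, and in-source flag.

The generative model, stage by stage:

* random proteins with a realistic residue composition, assigned to
  species of a small fixed gut taxonomy and to GO-BP / EC labels;
* in-silico tryptic digestion (cleavage after K/R, no proline rule, up
  to 3 missed cleavages, length 7-30) with a detection subsample;
* endogenous proteolysis injected as Poisson-distributed cleavage
  events inside detected tryptic peptides, with a configurable
  position-specific P1 residue preference, yielding semi-tryptic
  peptides whose intensity tracks their parent peptide (times a yield
  factor, a per-group/taxon proteolysis-rate multiplier, and noise);
* in-source fragments generated from fully tryptic parents: truncated,
  charge reduced by one, retention time within +-0.2 min of the parent;
* per-engine independent detection dropout and per-engine PEP draws,
  with shared underlying intensities (all engines see the same LC-MS
  signal);
* retention times from an additive residue-coefficient model plus
  noise, so a calibrated RT model can recover them.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .io import (AMINO_ACIDS, PAD, EngineResult, PeptideRecord, ProteinDatabase,
                 ProteinEntry, SampleMetadata)
from .annotate import TaxonomyTree, equate_il
from .tryptic import TrypticStatus

# approximate UniProt residue frequencies
DEFAULT_RESIDUE_FREQS = {
    "A": 0.082, "C": 0.014, "D": 0.054, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.022, "I": 0.059, "K": 0.058, "L": 0.096,
    "M": 0.024, "N": 0.040, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.054, "V": 0.069, "W": 0.011, "Y": 0.029,
}

# additive retention coefficients (min) used to generate true RTs
TRUE_RT_COEF = {
    "A": 2.0, "C": 2.6, "D": 2.8, "E": 1.5, "F": 13.2, "G": -0.2,
    "H": -2.1, "I": 11.8, "K": -3.7, "L": 14.0, "M": 7.1, "N": -0.6,
    "P": 5.1, "Q": 0.0, "R": -2.6, "S": -0.6, "T": 0.8, "V": 5.0,
    "W": 13.9, "Y": 5.9,
}
RT_INTERCEPT = 10.0
RT_COEF_SCALE = 0.25
RT_LENGTH_COEF = 2.0

GO_POOL = (
    "translation", "protein folding", "protein refolding", "protein transport",
    "carbohydrate transport", "glycolytic process",
    "polysaccharide catabolic process", "fatty acid metabolic process",
    "bacterial-type flagellum-dependent cell motility",
    "response to oxidative stress", "cell division", "transmembrane transport",
)
EC_POOL = ("1.15.1.1", "3.4.21.107", "2.7.1.1", "1.1.1.27",
           "5.3.1.9", "4.1.2.13", "6.3.1.2", "2.3.1.9")


@dataclass
class SimConfig:
    """All tunables of the generator; the seed is mandatory."""

    seed: int
    n_proteins: int = 200
    n_human: int = 10
    n_food: int = 4
    n_contaminant: int = 2
    protein_length_range: tuple[int, int] = (150, 400)
    residue_freqs: dict[str, float] | None = None
    groups: tuple[str, ...] = ("Ctrl", "CD", "UC")
    n_samples_per_group: int = 10
    # digestion
    max_missed_cleavages: int = 3
    min_len: int = 7
    max_len: int = 30
    detection_prob: float = 0.35
    # proteolysis
    proteolysis_rate: float = 8.0  # mean endogenous cleavage events / protein
    p1_weights: dict[str, float] | None = None
    group_multipliers: dict[str, dict[str, float]] = field(default_factory=dict)
    semi_yield: float = 0.25       # diverted fraction of protein tryptic signal
    semi_sigma: float = 0.25       # per-product log2 noise on the yield
    # intensities (log2 scale): protein abundances are log-normal and
    # peptides inherit them through a smaller response factor
    intensity_mu: float = 20.0
    intensity_sigma: float = 2.0   # protein-level spread
    peptide_sigma: float = 0.5     # per-peptide response spread
    sample_sigma: float = 0.3
    sample_dropout: float = 0.02
    # engines: besides the uniform dropout, detection is intensity
    # dependent (logistic in log2 intensity, see _detect_prob) so that
    # abundant peptides are reliably identified, as in real LC-MS data
    engines: tuple[str, ...] = ("maxquant", "peaks", "pfind")
    quant_engine: str = "maxquant"
    intensity_detection: bool = True  # logistic detection in log2 intensity
    engine_dropout: float = 0.0       # extra uniform per-engine dropout
    pep_high_fraction: float = 0.05
    # in-source fragments
    in_source_rate: float = 0.05
    in_source_rt_jitter: float = 0.2
    # retention time
    rt_noise: float = 0.3
    window_len: int = 15

    def __post_init__(self):
        for p in (self.detection_prob, self.engine_dropout, self.sample_dropout,
                  self.in_source_rate, self.pep_high_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("protein_length_range", "groups", "engines"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class SimPeptide:
    sequence: str
    accession: str
    start0: int                 # 0-based slice start in the protein
    end0: int                   # 0-based slice end (exclusive)
    status: TrypticStatus
    parent_seq: str | None = None
    is_in_source: bool = False
    window: str | None = None   # true P6-P6' window for injected cleavages
    p1: str | None = None
    base_log2: float = 0.0      # log2 abundance base (fully tryptic only)


@dataclass
class SimBundle:
    cfg: SimConfig
    db: ProteinDatabase
    tree: TaxonomyTree
    acc2taxid: dict[str, int]
    pep2taxa: dict[str, set[int]]
    go_map: dict[str, set[str]]
    ec_map: dict[str, set[str]]
    engines: dict[str, EngineResult]
    metadata: SampleMetadata
    truth: pd.DataFrame
    pool: list[SimPeptide]


# ---------------------------------------------------------------------------
# taxonomy


def build_toy_taxonomy() -> tuple[TaxonomyTree, list[int]]:
    """Small fixed gut taxonomy: 2 phyla, 4 genera, 8 species.

    Returns the tree and the list of species taxids.
    """
    rows: list[tuple[int, int, str, str]] = [(1, 1, "no rank", "root"),
                                             (2, 1, "superkingdom", "Bacteria")]
    nxt = [3]

    def add(parent, rank, name):
        t = nxt[0]
        nxt[0] += 1
        rows.append((t, parent, rank, name))
        return t

    species: list[int] = []
    plan = {
        "Firmicutes": {
            "Clostridia": {"Clostridiales": {
                "Ruminococcaceae": {"Faecalibacterium":
                                    ["Faecalibacterium prausnitzii",
                                     "Faecalibacterium duncaniae"]},
                "Lachnospiraceae": {"Roseburia":
                                    ["Roseburia intestinalis",
                                     "Roseburia hominis"]},
            }}},
        "Bacteroidetes": {
            "Bacteroidia": {"Bacteroidales": {
                "Bacteroidaceae": {"Bacteroides":
                                   ["Bacteroides fragilis",
                                    "Bacteroides vulgatus"]},
                "Prevotellaceae": {"Prevotella":
                                   ["Prevotella copri",
                                    "Prevotella stercorea"]},
            }}},
    }
    for phy, classes in plan.items():
        p = add(2, "phylum", phy)
        for cls_name, orders in classes.items():
            c = add(p, "class", cls_name)
            for ordn, fams in orders.items():
                o = add(c, "order", ordn)
                for fam, genera in fams.items():
                    f = add(o, "family", fam)
                    for gen, spp in genera.items():
                        g = add(f, "genus", gen)
                        for sp in spp:
                            species.append(add(g, "species", sp))
    nodes = {t: (p, r, n) for t, p, r, n in rows}
    return TaxonomyTree(nodes, root=1), species


# ---------------------------------------------------------------------------
# proteome


def _random_protein(rng: np.random.Generator, length: int,
                    freqs: dict[str, float]) -> str:
    aas = list(freqs)
    p = np.array([freqs[a] for a in aas], dtype=float)
    p = p / p.sum()
    return "".join(rng.choice(aas, size=length, p=p))


def simulate_proteome(cfg: SimConfig, rng: np.random.Generator | None = None
                      ) -> tuple[ProteinDatabase, TaxonomyTree, dict[str, int],
                                 dict[str, set[str]], dict[str, set[str]]]:
    """Random protein database + taxonomy + function maps (deterministic
    under the config seed when no generator is passed)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    freqs = cfg.residue_freqs or DEFAULT_RESIDUE_FREQS
    tree, species = build_toy_taxonomy()
    lo, hi = cfg.protein_length_range
    entries: dict[str, ProteinEntry] = {}
    acc2taxid: dict[str, int] = {}
    go_map: dict[str, set[str]] = {}
    ec_map: dict[str, set[str]] = {}
    for i in range(cfg.n_proteins):
        acc = f"MB_{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        sp = int(species[int(rng.integers(len(species)))])
        entries[acc] = ProteinEntry(f"synthetic microbial protein "
                                    f"OS={tree.name(sp)}",
                                    _random_protein(rng, length, freqs),
                                    "microbial")
        acc2taxid[acc] = sp
        n_go = 1 + int(rng.random() < 0.5)
        go_map[acc] = {GO_POOL[int(k)] for k in
                       rng.choice(len(GO_POOL), size=n_go, replace=False)}
        if rng.random() < 0.4:
            ec_map[acc] = {EC_POOL[int(rng.integers(len(EC_POOL)))]}
    for prefix, n, sc in (("HS", cfg.n_human, "human"),
                          ("FD", cfg.n_food, "food"),
                          ("CT", cfg.n_contaminant, "contaminant")):
        for i in range(n):
            acc = f"{prefix}_{i:04d}"
            length = int(rng.integers(lo, hi + 1))
            entries[acc] = ProteinEntry(f"synthetic {sc} protein",
                                        _random_protein(rng, length, freqs), sc)
    return ProteinDatabase(entries), tree, acc2taxid, go_map, ec_map


# ---------------------------------------------------------------------------
# digestion and proteolysis injection


def tryptic_peptides(seq: str, max_missed: int = 3, min_len: int = 7,
                     max_len: int = 30) -> list[tuple[int, int, int]]:
    """Enumerate fully tryptic peptides as (start0, end0, missed) slices:
    cleavage after K/R (no proline restriction), up to ``max_missed``
    missed cleavages, length filtered."""
    bounds = [0] + [i + 1 for i in range(len(seq) - 1) if seq[i] in "KR"]
    bounds.append(len(seq))
    out = []
    for i in range(len(bounds) - 1):
        for missed in range(max_missed + 1):
            j = i + 1 + missed
            if j >= len(bounds):
                break
            a, b = bounds[i], bounds[j]
            if min_len <= b - a <= max_len:
                out.append((a, b, missed))
    return out


def _true_window(seq: str, i: int) -> str:
    """True P6-P6' window around the bond preceding position i (0-based)."""
    left = seq[max(0, i - 6):i].rjust(6, PAD)
    right = seq[i:i + 6].ljust(6, PAD)
    return left + right


def _semi_candidates(seq: str, a: int, b: int, direction: str,
                     min_len: int, max_len: int) -> list[int]:
    """Bond positions i producing a semi-tryptic truncation of peptide
    [a, b); the P1 residue seq[i-1] must not be K/R (that would recreate
    a tryptic boundary)."""
    out = []
    if direction == "C":  # keep [a, i): tryptic N-terminus retained
        for i in range(a + min_len, min(a + max_len, b - 1) + 1):
            if i < b and seq[i - 1] not in "KR":
                out.append(i)
    else:  # keep [i, b): tryptic C-terminus retained; avoid the protein
        # N-terminal positions (1-based start 1 or 2), which classify as
        # tryptic under the initiator-Met exception
        for i in range(max(b - max_len, a + 1, 2), b - min_len + 1):
            if seq[i - 1] not in "KR":
                out.append(i)
    return out


def digest_and_cleave(db: ProteinDatabase, cfg: SimConfig,
                      rng: np.random.Generator) -> list[SimPeptide]:
    """Detected tryptic peptide pool plus injected proteolysis products.

    Peptide abundance bases are drawn here so that proteolysis events
    can target parents in proportion to abundance: abundant proteins
    shed proportionally more semi-tryptic products, which keeps group
    NRASP at 1 under a uniform proteolysis rate.
    """
    p1w = cfg.p1_weights or {}
    pool: dict[str, SimPeptide] = {}
    for acc in sorted(db.entries):
        seq = db.entries[acc].sequence
        protein_base = float(rng.normal(cfg.intensity_mu, cfg.intensity_sigma))
        fulls = []
        for a, b, _missed in tryptic_peptides(seq, cfg.max_missed_cleavages,
                                              cfg.min_len, cfg.max_len):
            if rng.random() >= cfg.detection_prob:
                continue
            pep = seq[a:b]
            if pep not in pool:
                sp = SimPeptide(pep, acc, a, b, TrypticStatus.FULL,
                                base_log2=protein_base
                                + float(rng.normal(0.0, cfg.peptide_sigma)))
                pool[pep] = sp
                fulls.append(sp)
        if not fulls or cfg.proteolysis_rate <= 0:
            continue
        n_events = rng.poisson(cfg.proteolysis_rate)
        if not n_events:
            continue
        # proteolysis diverts a fixed fraction (semi_yield) of the protein's
        # tryptic signal into its semi products, split evenly across the
        # realized products; event positions fall on abundant parents
        # proportionally
        bases = np.array([sp.base_log2 for sp in fulls])
        shift = bases.max()
        masses = 2.0 ** (bases - shift)
        parent_p = masses / masses.sum()
        protein_mass_log2 = shift + math.log2(masses.sum())
        parent_idx = [int(k) for k in
                      rng.choice(len(fulls), size=n_events, p=parent_p)]
        products: list[SimPeptide] = []
        for ev in range(n_events):
            fp = fulls[parent_idx[ev]]
            direction = "C" if rng.random() < 0.5 else "N"
            cands = _semi_candidates(seq, fp.start0, fp.end0, direction,
                                     cfg.min_len, cfg.max_len)
            if not cands:
                direction = "N" if direction == "C" else "C"
                cands = _semi_candidates(seq, fp.start0, fp.end0, direction,
                                         cfg.min_len, cfg.max_len)
            if not cands:
                continue
            w = np.array([p1w.get(seq[i - 1], 1.0) for i in cands], dtype=float)
            i = cands[int(rng.choice(len(cands), p=w / w.sum()))]
            if direction == "C":
                a2, b2, status = fp.start0, i, TrypticStatus.SEMI_C
            else:
                a2, b2, status = i, fp.end0, TrypticStatus.SEMI_N
            pep = seq[a2:b2]
            if pep in pool or any(pep == q.sequence for q in products):
                continue
            products.append(SimPeptide(pep, acc, a2, b2, status,
                                       parent_seq=fp.sequence,
                                       window=_true_window(seq, i),
                                       p1=seq[i - 1]))
        if products:
            semi_base = (protein_mass_log2 + math.log2(cfg.semi_yield)
                         - math.log2(len(products)))
            for sp in products:
                sp.base_log2 = semi_base
                pool[sp.sequence] = sp
    return list(pool.values())


def _inject_in_source(pool: list[SimPeptide], db: ProteinDatabase,
                      cfg: SimConfig, rng: np.random.Generator) -> list[SimPeptide]:
    """Truncated co-eluting fragments of fully tryptic parents."""
    existing = {p.sequence for p in pool}
    frags: list[SimPeptide] = []
    for sp in pool:
        if sp.status is not TrypticStatus.FULL or len(sp.sequence) < 14:
            continue
        if rng.random() >= cfg.in_source_rate:
            continue
        seq = db.entries[sp.accession].sequence
        length = sp.end0 - sp.start0
        k_min = max(6, int(0.4 * length))
        k_max = length - cfg.min_len
        if k_min > k_max:
            continue
        side = "C" if rng.random() < 0.5 else "N"
        for _ in range(4):  # a few attempts to find a valid truncation
            k = int(rng.integers(k_min, k_max + 1))
            if side == "C":
                a2, b2, status = sp.start0, sp.end0 - k, TrypticStatus.SEMI_C
                terminal_ok = seq[b2 - 1] not in "KR"
            else:
                a2, b2, status = sp.start0 + k, sp.end0, TrypticStatus.SEMI_N
                terminal_ok = seq[a2 - 1] not in "KR"
            pep = seq[a2:b2]
            if terminal_ok and pep not in existing:
                existing.add(pep)
                frags.append(SimPeptide(pep, sp.accession, a2, b2, status,
                                        parent_seq=sp.sequence,
                                        is_in_source=True))
                break
    return frags


# ---------------------------------------------------------------------------
# emission


def _detect_prob(log2_intensity, cfg: SimConfig):
    """Detection probability, logistic in log2 intensity with midpoint
    1.5 protein-level sigmas below the mean (width 0.7 log2 units):
    abundant peptides are (almost) always identified, faint ones drop
    out."""
    midpoint = cfg.intensity_mu - 1.5 * cfg.intensity_sigma
    return 1.0 / (1.0 + 2.0 ** (-(np.asarray(log2_intensity) - midpoint) / 0.7))


def true_rt(seq: str) -> float:
    return (RT_INTERCEPT
            + RT_COEF_SCALE * sum(TRUE_RT_COEF[a] for a in seq)
            + RT_LENGTH_COEF * math.log(len(seq)))


def _record_context(sp: SimPeptide, db: ProteinDatabase, w: int):
    seq = db.entries[sp.accession].sequence
    pre = seq[sp.start0 - 1] if sp.start0 > 0 else "-"
    post = seq[sp.end0] if sp.end0 < len(seq) else "-"
    ntw = seq[max(0, sp.start0 - w):sp.start0].rjust(w, PAD)
    ctw = seq[sp.end0:sp.end0 + w].ljust(w, PAD)
    return pre, post, ntw, ctw


def emit_tables(pool: list[SimPeptide], db: ProteinDatabase,
                acc2taxid: dict[str, int], cfg: SimConfig,
                rng: np.random.Generator,
                lineages: dict[int, tuple[str, ...]] | None = None
                ) -> tuple[dict[str, EngineResult], SampleMetadata, pd.DataFrame]:
    """Per-engine identification tables, sample metadata and ground truth.

    ``lineages`` maps taxid -> lineage names; it is required for
    taxon-name-keyed proteolysis multipliers (``simulate_dataset``
    supplies it from the toy tree).
    """
    pool = pool + _inject_in_source(pool, db, cfg, rng)
    lineages = lineages or {}
    samples = [f"{g}{i + 1:02d}" for g in cfg.groups
               for i in range(cfg.n_samples_per_group)]
    sample_group = {s: g for g in cfg.groups
                    for s in samples if s.startswith(g)}
    n_pep, n_s = len(pool), len(samples)
    index = {sp.sequence: i for i, sp in enumerate(pool)}

    # shared log2 intensity matrix (bases were drawn at digestion time)
    log2 = np.zeros((n_pep, n_s))
    noise = rng.normal(0.0, cfg.sample_sigma, size=(n_pep, n_s))
    yield_noise = rng.normal(0.0, cfg.semi_sigma, size=n_pep)
    for i, sp in enumerate(pool):
        if sp.status is TrypticStatus.FULL:
            log2[i] = sp.base_log2 + noise[i]
    for i, sp in enumerate(pool):
        if sp.status is TrypticStatus.FULL:
            continue
        if sp.is_in_source:
            log2[i] = log2[index[sp.parent_seq]] + math.log2(0.1) + noise[i]
            continue
        row = sp.base_log2 + yield_noise[i] + noise[i]
        taxid = acc2taxid.get(sp.accession)
        if taxid is not None and cfg.group_multipliers:
            lineage = lineages.get(taxid, ())
            for j, s in enumerate(samples):
                mult = _multiplier(cfg.group_multipliers.get(sample_group[s], {}),
                                   lineage)
                if mult != 1.0:
                    row[j] = row[j] + math.log2(mult)
        log2[i] = row

    present = rng.random((n_pep, n_s)) >= cfg.sample_dropout
    if cfg.intensity_detection:
        p_detect = _detect_prob(log2.mean(axis=1), cfg)
    else:
        p_detect = np.ones(n_pep)

    # retention time and charge (shared across engines)
    rts = np.empty(n_pep)
    charges = np.empty(n_pep, dtype=int)
    for i, sp in enumerate(pool):
        if sp.is_in_source:
            rts[i] = (rts[index[sp.parent_seq]]
                      + rng.uniform(-cfg.in_source_rt_jitter,
                                    cfg.in_source_rt_jitter))
            charges[i] = max(1, charges[index[sp.parent_seq]] - 1)
        else:
            rts[i] = true_rt(sp.sequence) + rng.normal(0.0, cfg.rt_noise)
            charges[i] = 2 if len(sp.sequence) < 20 else 3

    # one shared intensity-driven detection draw: all engines process the
    # same LC-MS signal, so a well-measured peptide is found by all of
    # them; per-engine disagreement is a small independent residual
    shared_detect = rng.random(n_pep) < p_detect
    engines: dict[str, EngineResult] = {}
    for engine in cfg.engines:
        detected = shared_detect & (rng.random(n_pep) >= cfg.engine_dropout)
        high = rng.random(n_pep) < np.clip(
            2.0 * cfg.pep_high_fraction * (1.0 - p_detect), 0.0, 1.0)
        peps = np.where(high, rng.uniform(0.05, 0.3, n_pep),
                        rng.uniform(0.0, 0.049, n_pep))
        records = []
        for i, sp in enumerate(pool):
            if not detected[i]:
                continue
            pre, post, ntw, ctw = _record_context(sp, db, cfg.window_len)
            intens = {s: float(2.0 ** log2[i, j])
                      for j, s in enumerate(samples) if present[i, j]}
            records.append(PeptideRecord(
                sequence=sp.sequence, preceding_residue=pre,
                following_residue=post, nterm_window=ntw, cterm_window=ctw,
                protein_accessions=[sp.accession],
                start_pos=sp.start0 + 1, end_pos=sp.end0,
                charge=int(charges[i]), retention_time=float(rts[i]),
                pep=float(peps[i]), intensities=intens, source_engine=engine))
        engines[engine] = EngineResult(engine, records)

    meta = SampleMetadata(pd.DataFrame({
        "sample_id": samples,
        "group": [sample_group[s] for s in samples],
        "site": ["feces"] * n_s,
        "subject_id": samples,
    }))
    truth = pd.DataFrame([{
        "sequence": sp.sequence, "accession": sp.accession,
        "status": sp.status.value, "is_in_source": sp.is_in_source,
        "parent": sp.parent_seq or "", "window": sp.window or "",
        "p1": sp.p1 or "", "species_taxid": acc2taxid.get(sp.accession, -1),
    } for sp in pool])
    return engines, meta, truth


def _multiplier(group_mults: dict[str, float],
                lineage: tuple[str, ...]) -> float:
    """Resolve a taxon-name-keyed multiplier table against a lineage;
    names at any rank apply, and ``*`` matches every taxon."""
    mult = 1.0
    for name in lineage:
        if name in group_mults:
            mult *= group_mults[name]
    if "*" in group_mults:
        mult *= group_mults["*"]
    return mult


def taxon_lineages(tree: TaxonomyTree) -> dict[int, tuple[str, ...]]:
    return {taxid: tuple(tree.name(t) for t in tree.path(taxid))
            for taxid in tree.nodes}


def build_peptide_taxon_map(db: ProteinDatabase, acc2taxid: dict[str, int],
                            max_missed: int = 3, min_len: int = 5,
                            max_len: int = 45) -> dict[str, set[int]]:
    """I/L-equated tryptic peptide -> species taxids, from an in-silico
    digest of the microbial proteins (wide length bounds so that
    closest-fully-tryptic conversions of emitted peptides resolve)."""
    out: dict[str, set[int]] = {}
    for acc in sorted(acc2taxid):
        seq = db.entries[acc].sequence
        taxid = acc2taxid[acc]
        for a, b, _ in tryptic_peptides(seq, max_missed, min_len, max_len):
            out.setdefault(equate_il(seq[a:b]), set()).add(taxid)
    return out


def simulate_dataset(cfg: SimConfig) -> SimBundle:
    """End-to-end generation: proteome, digestion, proteolysis, emission."""
    rng = np.random.default_rng(cfg.seed)
    db, tree, acc2taxid, go_map, ec_map = simulate_proteome(cfg, rng)
    pool = digest_and_cleave(db, cfg, rng)
    engines, meta, truth = emit_tables(pool, db, acc2taxid, cfg, rng,
                                       lineages=taxon_lineages(tree))
    pep2taxa = build_peptide_taxon_map(db, acc2taxid,
                                       max_missed=cfg.max_missed_cleavages,
                                       min_len=5,
                                       max_len=cfg.max_len + cfg.window_len)
    return SimBundle(cfg, db, tree, acc2taxid, pep2taxa, go_map, ec_map,
                     engines, meta, truth, pool)


# ---------------------------------------------------------------------------
# on-disk bundle


def write_bundle(bundle: SimBundle, outdir) -> None:
    """Write the bundle as plain-text files: FASTA, taxonomy TSV, mapping
    TSVs, per-engine tables (quantitation engine in the maxquant dialect,
    the rest generic), metadata and ground truth."""
    from pathlib import Path
    from .io import write_peptide_table

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.db.write_fasta(out / "proteins.fasta")
    bundle.tree.write_tsv(out / "taxonomy.tsv")
    pd.DataFrame([{"peptide": p, "taxids": ";".join(map(str, sorted(ts)))}
                  for p, ts in sorted(bundle.pep2taxa.items())]
                 ).to_csv(out / "pep2taxa.tsv", sep="\t", index=False)
    keys = sorted(set(bundle.go_map) | set(bundle.ec_map))
    pd.DataFrame([{"key": k,
                   "go_terms": ";".join(sorted(bundle.go_map.get(k, ()))),
                   "ec_numbers": ";".join(sorted(bundle.ec_map.get(k, ())))}
                  for k in keys]).to_csv(out / "functions.tsv", sep="\t",
                                         index=False)
    bundle.metadata.write_tsv(out / "metadata.tsv")
    bundle.truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    for engine, res in bundle.engines.items():
        dialect = "maxquant" if engine == bundle.cfg.quant_engine else "generic"
        write_peptide_table(res, out / f"{engine}.tsv", dialect=dialect)
    bundle.cfg.to_yaml(out / "sim_config.yaml")
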