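"""Pipeline orchestration: ingest -> classify -> annotate -> quantify ->
motif -> stats, with a reproducible run manifest.

``run_stages`` is the in-memory core (usable directly on a synthetic
bundle); ``run_pipeline`` wraps it with file I/O driven by a YAML
config and writes all stage outputs plus a manifest (config hash, seed,
per-stage record counts, output-table hashes) so that identical config
and inputs give bit-identical results for the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import FormatError, StageError
from .io import (ConsensusTable, EngineResult, ProteinDatabase, SampleMetadata,
                 classify_source, filter_pep, intersect_engines,
                 read_peptide_table)
from .annotate import (TaxonomyTree, annotate_peptides, assign_groups,
                       read_function_map, read_peptide_taxon_map)
from .tryptic import (TrypticStatus, classify_all, extract_cleavage_sites,
                      fit_rt_model, flag_in_source_fragments,
                      in_source_exclusions)
from .quantify import compute_nrasp, presence_filter, relative_abundance
from .motif import motif_feature_table, position_frequencies
from .stats import (bray_curtis, bpca_impute, hierarchical_cluster,
                    kruskal_dunn, pco_correlate, pcoa, plsda, results_frame)

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Analysis thresholds; defaults are the study's standard settings."""

    pep_threshold: float = 0.05
    presence: float = 0.75
    alpha: float = 0.05
    report_min_abs_r: float = 0.2
    rt_tol_min: float = 1.0
    resid_z: float = 3.0
    window_len: int = 15
    equate_il: bool = True
    match_on: str = "sequence"
    quant_engine: str = "maxquant"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.pep_threshold <= 1:
            raise FormatError("pep_threshold must be in (0, 1]")
        if not 0 < self.presence <= 1:
            raise FormatError("presence must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise FormatError("alpha must be in (0, 1)")
        if self.rt_tol_min < 0 or self.resid_z < 0:
            raise FormatError("rt_tol_min and resid_z must be non-negative")
        if self.match_on not in ("sequence", "sequence_IL_equated"):
            raise FormatError(f"unknown match_on {self.match_on!r}")


@dataclass
class PipelineConfig:
    """Paths + params, loadable from a single YAML file."""

    engine_tables: dict[str, dict[str, str]]  # engine -> {path, dialect}
    fasta: str
    taxonomy: str
    pep2taxa: str
    functions: str
    metadata: str
    out_dir: str
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise FormatError("pipeline config must be a YAML mapping")
        required = ("engine_tables", "fasta", "taxonomy", "pep2taxa",
                    "functions", "metadata", "out_dir")
        missing = [k for k in required if k not in raw]
        if missing:
            raise FormatError(f"pipeline config missing keys: {missing}")
        params = PipelineParams(**raw.get("params", {}))
        params.validate()
        for engine, spec in raw["engine_tables"].items():
            if "path" not in spec:
                raise FormatError(f"engine_tables[{engine!r}] needs a 'path'")
            spec.setdefault("dialect", "generic")
        return cls(engine_tables=raw["engine_tables"], fasta=raw["fasta"],
                   taxonomy=raw["taxonomy"], pep2taxa=raw["pep2taxa"],
                   functions=raw["functions"], metadata=raw["metadata"],
                   out_dir=raw["out_dir"], params=params)

    def canonical_dict(self) -> dict:
        d = {"engine_tables": self.engine_tables, "fasta": self.fasta,
             "taxonomy": self.taxonomy, "pep2taxa": self.pep2taxa,
             "functions": self.functions, "metadata": self.metadata,
             "out_dir": self.out_dir,
             "params": dataclasses.asdict(self.params)}
        return d


@dataclass
class StageOutputs:
    consensus: ConsensusTable
    statuses: dict[str, TrypticStatus]
    source_classes: dict[str, str]
    in_source_flags: list
    sites: list
    membership: dict[str, set[str]]
    nrasp: pd.DataFrame
    nrasp_filtered: pd.DataFrame
    abundance_semi: pd.DataFrame
    abundance_full: pd.DataFrame
    motif_features: pd.DataFrame
    nrasp_tests: list
    motif_tests: list
    pcoa_semi: object
    pcoa_full: object
    correlations: list
    plsda_motif: object
    motif_cluster: dict | None
    counts: dict[str, int]


def run_stages(engines: dict[str, EngineResult], db: ProteinDatabase,
               tree: TaxonomyTree, pep2taxa: dict[str, set[int]],
               go_map: dict[str, set[str]], ec_map: dict[str, set[str]],
               metadata: SampleMetadata,
               params: PipelineParams) -> StageOutputs:
    """Run the full analysis on in-memory inputs."""
    params.validate()
    counts: dict[str, int] = {}
    samples = metadata.sample_ids
    groups = metadata.groups()

    # -- ingest ------------------------------------------------------------
    stage = "ingest"
    try:
        filtered = []
        for engine_id in sorted(engines):
            res = engines[engine_id]
            counts[f"identified_{engine_id}"] = len(res.records)
            f = filter_pep(res, params.pep_threshold)
            counts[f"pep_filtered_{engine_id}"] = len(f.records)
            filtered.append(f)
        consensus = intersect_engines(filtered, params.quant_engine,
                                      params.match_on)
        counts["consensus"] = len(consensus.records)
    except Exception as e:  # noqa: BLE001 - re-raised with stage context
        raise StageError(stage, str(e)) from e

    # -- classify ----------------------------------------------------------
    stage = "classify"
    try:
        statuses = classify_all(consensus)
        counts["semi_tryptic"] = sum(
            1 for s in statuses.values()
            if s in (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C))
        counts["fully_tryptic"] = sum(
            1 for s in statuses.values() if s is TrypticStatus.FULL)
        full_records = [r for r in consensus.records
                        if statuses[r.sequence] is TrypticStatus.FULL]
        rt_models = {s: fit_rt_model(full_records, s) for s in samples}
        flags = flag_in_source_fragments(consensus, statuses, rt_models,
                                         params.rt_tol_min, params.resid_z)
        exclusions = in_source_exclusions(flags)
        counts["in_source_flagged_pairs"] = len(exclusions)
        counts["in_source_flagged_peptides"] = len({p for p, _ in exclusions})
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- source partition + annotate ----------------------------------------
    stage = "annotate"
    try:
        source_classes = {r.sequence: classify_source(r, db)
                          for r in consensus.records}
        microbial = [r for r in consensus.records
                     if source_classes[r.sequence] == "microbial_unique"]
        counts["microbial_unique"] = len(microbial)
        annotated = annotate_peptides(microbial, statuses, pep2taxa, tree,
                                      go_map, ec_map, equate=params.equate_il)
        membership = assign_groups(annotated)
        counts["taxonomy_annotated"] = sum(
            1 for a in annotated if a.lca_taxid is not None)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- quantify ------------------------------------------------------------
    stage = "quantify"
    try:
        if not microbial:
            raise FormatError("no microbial peptides left after filtering; "
                              "nothing to quantify")
        all_groups = sorted({g for gs in membership.values() for g in gs})
        semi_ab = relative_abundance(microbial, statuses, membership, "semi",
                                     samples, exclude=exclusions,
                                     groups=all_groups)
        full_ab = relative_abundance(microbial, statuses, membership, "full",
                                     samples, exclude=exclusions,
                                     groups=all_groups)
        nrasp = compute_nrasp(semi_ab, full_ab)
        nrasp_f = presence_filter(nrasp, params.presence)
        counts["nrasp_groups"] = nrasp.shape[0]
        counts["nrasp_groups_present"] = nrasp_f.shape[0]
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- motif ---------------------------------------------------------------
    stage = "motif"
    try:
        sites = []
        for r in microbial:
            st = statuses[r.sequence]
            if st in (TrypticStatus.SEMI_N, TrypticStatus.SEMI_C):
                for site in extract_cleavage_sites(r, st):
                    kept = tuple(s for s in site.sample_ids
                                 if (site.peptide, s) not in exclusions)
                    site.sample_ids = kept
                    if kept:
                        sites.append(site)
        counts["cleavage_sites"] = len(sites)
        pfms = {s: position_frequencies(sites, s) for s in samples}
        motif_features = motif_feature_table(pfms)
        motif_features = motif_features.dropna(axis=1, how="all")
    except Exception as e:
        raise StageError(stage, str(e)) from e

    # -- statistics ----------------------------------------------------------
    stage = "stats"
    try:
        nrasp_tests = kruskal_dunn(nrasp_f, groups, params.alpha)
        motif_tab = presence_filter(motif_features.T, params.presence)
        motif_tests = kruskal_dunn(motif_tab, groups, params.alpha)

        def intensity_matrix(stratum):
            wanted = ((TrypticStatus.SEMI_N, TrypticStatus.SEMI_C)
                      if stratum == "semi" else (TrypticStatus.FULL,))
            rows = {}
            for r in microbial:
                if statuses[r.sequence] in wanted:
                    rows[r.sequence] = {
                        s: v for s, v in r.intensities.items()
                        if (r.sequence, s) not in exclusions}
            return (pd.DataFrame.from_dict(rows, orient="index")
                    .reindex(columns=samples).T)

        pcoa_semi = pcoa(bray_curtis(intensity_matrix("semi")), k=3)
        pcoa_full = pcoa(bray_curtis(intensity_matrix("full")), k=3)
        correlations = pco_correlate(pcoa_semi.scores, pcoa_full.scores,
                                     params.report_min_abs_r, params.alpha)
        completed, _ = bpca_impute(motif_tab.T, seed=params.seed)
        try:
            plsda_motif = plsda(completed, groups, n_latent=2)
        except ValueError as e:
            logger.warning("PLS-DA of motif features skipped: %s", e)
            plsda_motif = None
        sig = [t.feature for t in motif_tests
               if t.pairwise and min(p.p_adj for p in t.pairwise) < params.alpha]
        motif_cluster = None
        if len(sig) >= 1:
            gm = (completed[sig]
                  .groupby(pd.Series(groups)).mean())
            if gm.shape[0] >= 2:
                motif_cluster = hierarchical_cluster(gm)
        counts["nrasp_significant"] = sum(
            1 for t in nrasp_tests
            if t.pairwise and min(p.p_adj for p in t.pairwise) < params.alpha)
        counts["motif_significant"] = len(sig)
    except Exception as e:
        raise StageError(stage, str(e)) from e

    return StageOutputs(
        consensus=consensus, statuses=statuses, source_classes=source_classes,
        in_source_flags=flags, sites=sites, membership=membership,
        nrasp=nrasp, nrasp_filtered=nrasp_f, abundance_semi=semi_ab,
        abundance_full=full_ab, motif_features=motif_features,
        nrasp_tests=nrasp_tests, motif_tests=motif_tests,
        pcoa_semi=pcoa_semi, pcoa_full=pcoa_full, correlations=correlations,
        plsda_motif=plsda_motif, motif_cluster=motif_cluster, counts=counts)


# ---------------------------------------------------------------------------
# file-driven entry point


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Load inputs, run all stages, write outputs + manifest.

    Returns the manifest dict.  Any stage error halts with the stage
    name; outputs written so far are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    engines = {}
    for engine_id, spec in config.engine_tables.items():
        engines[engine_id] = read_peptide_table(
            spec["path"], spec.get("dialect", "generic"),
            window_len=p.window_len, engine_id=engine_id)
    db = ProteinDatabase.read_fasta(config.fasta)
    tree = TaxonomyTree.read_tsv(config.taxonomy)
    pep2taxa = read_peptide_taxon_map(config.pep2taxa, equate=p.equate_il)
    go_map, ec_map = read_function_map(config.functions)
    metadata = SampleMetadata.read_tsv(config.metadata)

    res = run_stages(engines, db, tree, pep2taxa, go_map, ec_map, metadata, p)

    # stage outputs
    written: dict[str, str] = {}

    def save(df: pd.DataFrame, name: str, **kw):
        path = out / name
        df.to_csv(path, sep="\t", **kw)
        written[name] = _sha256(path)

    status_df = pd.DataFrame(
        [{"sequence": s, "status": res.statuses[s].value,
          "source_class": res.source_classes[s]}
         for s in sorted(res.statuses)])
    save(status_df, "statuses.tsv", index=False)
    sites_df = pd.DataFrame(
        [{"peptide": s.peptide, "side": s.side, "window": s.window,
          "samples": ";".join(s.sample_ids), "accession": s.accession}
         for s in res.sites])
    save(sites_df, "cleavage_sites.tsv", index=False)
    save(res.abundance_semi, "abundance_semi.tsv")
    save(res.abundance_full, "abundance_full.tsv")
    save(res.nrasp, "nrasp.tsv")
    save(res.nrasp_filtered, "nrasp_present.tsv")
    save(res.motif_features, "motif_features.tsv")
    save(results_frame(res.nrasp_tests), "nrasp_tests.tsv", index=False)
    save(results_frame(res.motif_tests), "motif_tests.tsv", index=False)
    save(res.pcoa_semi.scores, "pcoa_semi_scores.tsv")
    save(res.pcoa_full.scores, "pcoa_full_scores.tsv")
    corr_df = pd.DataFrame([dataclasses.asdict(c) for c in res.correlations])
    save(corr_df, "pco_correlations.tsv", index=False)
    if res.plsda_motif is not None:
        save(res.plsda_motif.scores, "plsda_motif_scores.tsv")

    cfg_yaml = yaml.safe_dump(config.canonical_dict(), sort_keys=True)
    manifest = {
        "semipep_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config_hash": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": p.seed,
        "counts": res.counts,
        "tables": written,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    logger.info("pipeline complete: %s", res.counts)
    return manifest
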