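"""Shared fixtures: synthetic bundles and record builders."""

import numpy as np
import pytest

import semipep as sp


def make_record(sequence, pre="K", post="A", nwin=None, cwin=None,
                accs=("MB_0000",), start=10, end=None, charge=2, rt=30.0,
                pep=0.01, intensities=None, w=15):
    """Minimal PeptideRecord with sensible defaults for unit tests."""
    end = end if end is not None else start + len(sequence) - 1
    return sp.PeptideRecord(
        sequence=sequence, preceding_residue=pre, following_residue=post,
        nterm_window=(nwin or "A" * w)[-w:].rjust(w, "_"),
        cterm_window=(cwin or "A" * w)[:w].ljust(w, "_"),
        protein_accessions=list(accs), start_pos=start, end_pos=end,
        charge=charge, retention_time=rt, pep=pep,
        intensities=dict(intensities or {}))


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def null_bundle():
    """Default study conditions: uniform proteolysis, 3 groups x 10 samples."""
    return sp.simulate_dataset(sp.SimConfig(seed=0))


@pytest.fixture(scope="session")
def null_result(null_bundle):
    b = null_bundle
    return sp.run_stages(b.engines, b.db, b.tree, b.pep2taxa, b.go_map,
                         b.ec_map, b.metadata, sp.PipelineParams(seed=0))


@pytest.fixture(scope="session")
def small_bundle():
    """Quick bundle for I/O and pipeline plumbing tests."""
    cfg = sp.SimConfig(seed=11, n_proteins=60, n_samples_per_group=3,
                       proteolysis_rate=4.0)
    return sp.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
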