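import dataclasses

import pytest
from hypothesis import settings

import ligandkit as lk

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def msln_protein():
    return lk.load_msln_protein()


@pytest.fixture(scope="session")
def msln_peptides():
    return lk.load_msln_target_peptides()


@pytest.fixture(scope="session")
def a3_9mer_spec():
    """A*03:01-like preset restricted to 9-mers (anchor ground truth P2, P9)."""
    return dataclasses.replace(lk.presets()["A*03:01"], length_weights={9: 1.0})


@pytest.fixture(scope="session")
def a11_9mer_spec():
    return dataclasses.replace(lk.presets()["A*11:01"], length_weights={9: 1.0})


@pytest.fixture(scope="session")
def a3_ligandome_2000(a3_9mer_spec):
    pset, truth = lk.sample_ligandome(
        a3_9mer_spec, lk.SimulationConfig(n_peptides=2000, seed=11)
    )
    return pset, truth


def make_set(seqs, name="s", run_id="run1", rt=None, **kw):
    """Small helper: a PeptideSet from bare sequences (optionally with RTs)."""
    records = []
    for i, s in enumerate(seqs):
        records.append(
            lk.PeptideRecord(
                sequence=s,
                retention_time=None if rt is None else rt[i],
                run_id=run_id,
                **kw,
            )
        )
    return lk.PeptideSet(name=name, records=records)


@pytest.fixture
def make_peptide_set():
    return make_set
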