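import copy

import pytest

from nhkir.namegrammar import parse
from nhkir.registry import (AlleleRecord, GeneRecord, Registry,
                            load_default_registry)
from nhkir.synthgen import SynthSpec, generate_gene_set


@pytest.fixture(scope="session")
def fixture_registry():
    """The packaged registry transcribed from the published tables."""
    return load_default_registry()


@pytest.fixture(scope="session")
def fixture_names(fixture_registry):
    """Every designation string in the packaged registry."""
    return ([g.designation for g in fixture_registry.genes.values()]
            + [a.designation for a in fixture_registry.alleles.values()])


@pytest.fixture(scope="session")
def synth_set():
    """Three full-length synthetic genes at 0.90 pairwise identity."""
    return generate_gene_set(SynthSpec(seed=7, n_genes=3, divergence=0.90))


@pytest.fixture(scope="session")
def small_synth_set():
    """Three short (1-domain, short-tail) genes for allocation-heavy tests."""
    return generate_gene_set(SynthSpec(
        seed=11, n_genes=3, divergence=0.90,
        domain_plan=[(1, 14)] * 3))


def build_synth_registry(seqs) -> Registry:
    """A macaque-style registry whose *001 alleles are the synthetic genes."""
    reg = Registry()
    for i, (nm, seq) in enumerate(seqs.items(), start=1):
        gene = parse(f"Mamu-KIR3DL{i:02d}")
        reg.add_gene(GeneRecord(species="Mamu", symbol=gene))
        reg.add_allele(AlleleRecord(
            species="Mamu", name=parse(f"Mamu-KIR3DL{i:02d}*001"),
            cds=seq.cds, flank5=seq.flank5, flank3=seq.flank3,
            exon_spans=list(seq.exon_spans)))
    return reg


@pytest.fixture(scope="session")
def _synth_registry_master(synth_set):
    seqs, _ = synth_set
    return build_synth_registry(seqs)


@pytest.fixture
def synth_registry(_synth_registry_master):
    """Fresh copy per test so commits cannot leak between tests."""
    return copy.deepcopy(_synth_registry_master)


@pytest.fixture
def submission_meta():
    """Metadata passing the replication-evidence check."""
    return {"date": "2018-05-01",
            "evidence": [{"kind": "independent_pcr", "label": "expA"},
                         {"kind": "independent_pcr", "label": "expB"}]}
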