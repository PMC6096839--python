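"""The naming engine: locus votes, tier pipeline, checks, idempotence."""

import copy

import pytest

from nhkir.allocate import (AllocatorConfig, AmbiguousRecombinantError,
                            NewGeneProposal, assign_locus, assign_name,
                            rename_gene)
from nhkir.namegrammar import parse
from nhkir.registry import registry_to_dict
from nhkir.seqclass import make_aligner, _aligned_columns
from nhkir.synthgen import SynthSpec, chimera, generate_gene_set, mutate


def window_vote_oracle(chi_cds, parents, size=100, step=50):
    """Direct per-window nearest-neighbour count, independent of the engine:
    align once per parent, then count matching positions per window."""
    aligner = make_aligner()
    vecs = {}
    for gene, cds in parents.items():
        vec = [False] * len(chi_cds)
        for i, j in _aligned_columns(chi_cds, cds, aligner):
            if i is not None and j is not None and chi_cds[i] == cds[j]:
                vec[i] = True
        vecs[gene] = vec
    counts = {g: 0 for g in parents}
    for start in range(0, len(chi_cds) - size + 1, step):
        scores = {g: sum(v[start:start + size]) for g, v in vecs.items()}
        top = max(scores.values())
        leaders = [g for g, s in scores.items() if s == top]
        if len(leaders) == 1:
            counts[leaders[0]] += 1
    return counts


class TestAssignLocus:
    def test_identical_sequence_gets_unanimous_votes(self, synth_set,
                                                     synth_registry):
        seqs, _ = synth_set
        gene, votes, nearest = assign_locus(seqs["SYN1"], synth_registry,
                                            "Mamu")
        assert gene.designation == "Mamu-KIR3DL01"
        assert all(v == "3DL01" for _, v in votes)
        assert nearest[0] == ("Mamu-KIR3DL01*001", 1.0)

    def test_chimera_assigned_to_majority_parent(self, synth_set,
                                                 synth_registry):
        seqs, _ = synth_set
        chi = chimera(seqs["SYN1"], seqs["SYN2"], 0.7)
        gene, votes, _ = assign_locus(chi, synth_registry, "Mamu")
        assert gene.bare_symbol == "3DL01"
        # the winning gene agrees with a direct windowed count over the
        # two parents, computed independently of the engine
        oracle = window_vote_oracle(
            chi.cds, {"3DL01": seqs["SYN1"].cds, "3DL02": seqs["SYN2"].cds})
        assert max(oracle, key=oracle.get) == "3DL01"
        engine = {g: sum(1 for _, v in votes if v == g) for g in oracle}
        assert engine["3DL01"] > engine["3DL02"]

    def test_even_split_raises_ambiguity(self, synth_set, synth_registry):
        seqs, _ = synth_set
        chi = chimera(seqs["SYN1"], seqs["SYN2"], 0.5)
        with pytest.raises(AmbiguousRecombinantError) as err:
            assign_locus(chi, synth_registry, "Mamu")
        assert err.value.votes
        assert "manual review" in str(err.value)

    def test_breakpoint_sweep_always_finds_majority_parent(
            self, synth_set, synth_registry):
        seqs, _ = synth_set
        for bp in [0.55, 0.65, 0.75, 0.85, 0.95]:
            chi = chimera(seqs["SYN1"], seqs["SYN2"], bp)
            gene, _, _ = assign_locus(chi, synth_registry, "Mamu")
            assert gene.bare_symbol == "3DL01", bp
            rev = chimera(seqs["SYN2"], seqs["SYN1"], bp)
            gene, _, _ = assign_locus(rev, synth_registry, "Mamu")
            assert gene.bare_symbol == "3DL02", bp

    def test_divergent_sequence_proposes_workshop_gene(self, synth_registry):
        outsider, _ = generate_gene_set(SynthSpec(seed=99, n_genes=1,
                                                  divergence=0.9))
        locus, _, nearest = assign_locus(outsider["SYN1"], synth_registry,
                                         "Mamu")
        assert isinstance(locus, NewGeneProposal)
        assert locus.symbol.workshop
        # numbering continues the species sequence with macaque width
        assert locus.symbol.gene_id == "04"
        assert locus.best_identity == nearest[0][1] < 0.96


class TestAssignName:
    def test_registered_sequence_is_existing_allele(self, synth_set,
                                                    synth_registry,
                                                    submission_meta):
        seqs, _ = synth_set
        before = registry_to_dict(synth_registry)
        decision = assign_name(seqs["SYN1"], synth_registry, "Mamu",
                               submission_meta, commit=True)
        assert decision.status == "existing_allele"
        assert decision.designation == "Mamu-KIR3DL01*001"
        assert registry_to_dict(synth_registry) == before  # idempotent

    def test_protein_changing_variant_gets_tier1_number(
            self, synth_set, synth_registry, submission_meta):
        seqs, _ = synth_set
        novel = mutate(seqs["SYN1"], "nonsynonymous", 3, seed=21)
        decision = assign_name(novel, synth_registry, "Mamu",
                               submission_meta)
        assert decision.status == "new_tier1"
        assert decision.designation == "Mamu-KIR3DL01*002"

    def test_synonymous_variant_extends_incumbent(self, synth_set,
                                                  synth_registry,
                                                  submission_meta):
        seqs, _ = synth_set
        novel = mutate(seqs["SYN1"], "synonymous", 2, seed=22)
        decision = assign_name(novel, synth_registry, "Mamu",
                               submission_meta)
        assert decision.status == "new_tier2"
        assert decision.designation == "Mamu-KIR3DL01*001:02"
        # the incumbent keeps its short printed form; its canonical long
        # form gains the :01
        assert decision.rationale["incumbent_canonical"] == \
            "Mamu-KIR3DL01*001:01"

    def test_noncoding_variant_gets_tier3_number(self, synth_set,
                                                 synth_registry,
                                                 submission_meta):
        seqs, _ = synth_set
        novel = mutate(seqs["SYN1"], "noncoding", 2, seed=23)
        decision = assign_name(novel, synth_registry, "Mamu",
                               submission_meta)
        assert decision.status == "new_tier3"
        assert decision.designation == "Mamu-KIR3DL01*001:01:02"

    def test_null_variant_gets_n_suffix(self, synth_set, synth_registry,
                                        submission_meta):
        seqs, _ = synth_set
        novel = mutate(mutate(seqs["SYN1"], "nonsynonymous", 3, seed=24),
                       "stop", seed=24, stop_fraction=0.5)
        decision = assign_name(novel, synth_registry, "Mamu",
                               submission_meta)
        assert decision.assigned.suffix == "N"
        assert "premature_stop" in decision.suffix_triggers

    def test_late_stop_never_triggers_n(self, synth_set, synth_registry,
                                        submission_meta):
        seqs, _ = synth_set
        novel = mutate(seqs["SYN1"], "stop", seed=25, stop_fraction=0.95)
        decision = assign_name(novel, synth_registry, "Mamu",
                               submission_meta)
        assert decision.assigned.suffix != "N"

    def test_single_pcr_experiment_is_rejected(self, synth_set,
                                               synth_registry):
        seqs, _ = synth_set
        meta = {"date": "2018-05-01",
                "evidence": [{"kind": "independent_pcr", "label": "only"}]}
        decision = assign_name(seqs["SYN1"], synth_registry, "Mamu", meta)
        assert decision.status == "rejected"
        assert decision.checks["evidence"] == "fail"
        assert decision.assigned is None

    def test_two_individuals_pass_evidence(self, synth_set, synth_registry):
        seqs, _ = synth_set
        meta = {"date": "2018-05-01",
                "evidence": [{"kind": "individual", "label": "rh01"},
                             {"kind": "individual", "label": "rh02"}]}
        decision = assign_name(seqs["SYN1"], synth_registry, "Mamu", meta)
        assert decision.checks["evidence"] == "pass"

    def test_partial_sequence_rejected_where_full_length_mandatory(
            self, synth_set, synth_registry, submission_meta):
        seqs, _ = synth_set
        partial = copy.deepcopy(seqs["SYN1"])
        partial.complete = False
        decision = assign_name(partial, synth_registry, "Mamu",
                               submission_meta)
        assert decision.status == "rejected"
        assert decision.checks["full_length"] == "fail"

    def test_full_length_waived_for_other_species(self, synth_set,
                                                  synth_registry,
                                                  submission_meta):
        # move the registry under a species without the mandatory flag
        seqs, _ = synth_set
        reg = synth_registry
        for key in list(reg.genes):
            g = reg.genes.pop(key)
            g.species = "Patr"
            reg.genes[("Patr", key[1])] = g
        for key in list(reg.alleles):
            a = reg.alleles.pop(key)
            a.species = "Patr"
            reg.alleles[("Patr", key[1])] = a
        partial = copy.deepcopy(seqs["SYN1"])
        partial.complete = False
        decision = assign_name(partial, reg, "Patr", submission_meta)
        assert decision.checks["full_length"] == "waived"
        assert decision.status != "rejected"

    def test_workshop_commit_registers_gene_and_allele(self, synth_registry,
                                                       submission_meta):
        outsider, _ = generate_gene_set(SynthSpec(seed=99, n_genes=1,
                                                  divergence=0.9))
        decision = assign_name(outsider["SYN1"], synth_registry, "Mamu",
                               submission_meta, commit=True)
        assert decision.status == "new_gene_workshop"
        assert decision.designation == "Mamu-KIR3DLW04*001"
        assert ("Mamu", "3DLW04") in synth_registry.genes
        again = assign_name(outsider["SYN1"], synth_registry, "Mamu",
                            submission_meta)
        assert again.status == "existing_allele"

    def test_other_macaque_named_against_rhesus_registry(self, synth_set,
                                                         synth_registry,
                                                         submission_meta):
        seqs, _ = synth_set
        novel = mutate(seqs["SYN1"], "nonsynonymous", 3, seed=31)
        decision = assign_name(novel, synth_registry, "Mafa",
                               submission_meta)
        # nearest rhesus gene, query species' prefix on the output
        assert decision.designation.startswith("Mafa-KIR3DL01*")

    def test_determinism(self, synth_set, synth_registry, submission_meta):
        seqs, _ = synth_set
        novel = mutate(seqs["SYN1"], "nonsynonymous", 2, seed=40)
        d1 = assign_name(novel, copy.deepcopy(synth_registry), "Mamu",
                         submission_meta)
        d2 = assign_name(novel, copy.deepcopy(synth_registry), "Mamu",
                         submission_meta)
        assert d1.to_dict() == d2.to_dict()


def test_sequential_novelties_get_consecutive_numbers(small_synth_set,
                                                      submission_meta):
    from conftest import build_synth_registry
    seqs, _ = small_synth_set
    reg = build_synth_registry(seqs)
    assigned = []
    for k in range(10):
        novel = mutate(seqs["SYN1"], "nonsynonymous", 3, seed=500 + k)
        decision = assign_name(novel, reg, "Mamu", submission_meta,
                               commit=True)
        assert decision.status == "new_tier1"
        assigned.append(int(decision.assigned.field1))
    assert assigned == list(range(2, 12))


def test_rename_gene_preserves_history(synth_registry):
    new_symbol = parse("Mamu-KIR3DL30")
    rename_gene(synth_registry, "Mamu", "3DL01", new_symbol)
    assert ("Mamu", "3DL30") in synth_registry.genes
    gene = synth_registry.genes[("Mamu", "3DL30")]
    assert "Mamu-KIR3DL01" in gene.previous_designations
    allele = synth_registry.get_allele("Mamu", "Mamu-KIR3DL30*001")
    assert allele is not None
    assert "Mamu-KIR3DL01*001" in allele.previous_designations
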