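"""Seeded generator of KIR-like coding sequences with known ground truth.

Real KIR sequence data cannot be bundled, so every other module is exercised
against synthetic genes built from the same block anatomy a KIR cDNA has:
leader peptide, one to three Ig-like domain exons (D0/D1/D2, each with the
canonical pair of domain-bridging cysteines), stem, transmembrane segment
and a cytoplasmic tail of requested length, closed by a stop codon.

Determinism is part of the contract: the RNG is Python's Mersenne Twister
(``random.Random``) seeded explicitly, and the same seed always yields
byte-identical sequences.  Divergence between genes is engineered exactly,
not sampled: each gene receives substitutions at a private, disjoint set of
codons, so the pairwise difference count between two genes is the sum of
their private mutation counts and the realised identity lands on the target
to within rounding.  Codon sampling never creates a stop codon except where
one is explicitly requested.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field as dc_field

from Bio.Seq import Seq

from .seqclass import AnnotatedSequence

_BASES = "ACGT"

#: all 61 sense codons and their residues under the standard code
CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product(_BASES, repeat=3)
}
STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in CODON_TABLE if c not in STOP_CODONS))

_SYNONYMS: dict[str, tuple[str, ...]] = {
    c: tuple(sorted(c2 for c2, aa in CODON_TABLE.items()
                    if aa == CODON_TABLE[c] and c2 != c and aa != "*"))
    for c in SENSE_CODONS
}

_LEADER_CODONS = 21
_DOMAIN_CODONS = 100
_STEM_CODONS = 24
_TM_CODONS = 21
_CYS_OFFSETS = (20, 80)      # Ig-fold cysteine spacing within a domain


class SynthError(ValueError):
    pass


@dataclass
class SynthSpec:
    """Recipe for a synthetic gene set.

    ``divergence`` is the target pairwise cds identity between genes (a
    fraction); ``domain_plan`` gives per-gene (domain_count, tail_codons).
    A long inhibitory-type tail is ~84 codons, a short activating-type tail
    ~14.
    """
    seed: int
    n_genes: int = 3
    divergence: float = 0.90
    domain_plan: list[tuple[int, int]] | None = None
    flank_len: int = 60

    def plans(self) -> list[tuple[int, int]]:
        if self.domain_plan is not None:
            if len(self.domain_plan) != self.n_genes:
                raise SynthError("domain_plan length must equal n_genes")
            return list(self.domain_plan)
        return [(3, 84)] * self.n_genes

    def validate(self) -> None:
        if not 0.0 < self.divergence < 1.0:
            raise SynthError("divergence must be in (0,1)")
        if self.n_genes < 1:
            raise SynthError("need at least one gene")


def _blocks(domain_count: int, tail_codons: int) -> list[tuple[str, int]]:
    if not 1 <= domain_count <= 3:
        raise SynthError(f"domain count {domain_count} out of range")
    blocks = [("leader", _LEADER_CODONS)]
    blocks += [(lab, _DOMAIN_CODONS)
               for lab in ("D0", "D1", "D2")[:domain_count]]
    blocks += [("stem", _STEM_CODONS), ("TM", _TM_CODONS),
               ("cyt", tail_codons + 1)]     # +1 holds the stop codon
    return blocks


def _random_codon(rng: random.Random) -> str:
    return rng.choice(SENSE_CODONS)


def _substitute(codon: str, rng: random.Random) -> str:
    """One random nucleotide change that yields a different sense codon."""
    options = []
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            cand = codon[:pos] + base + codon[pos + 1:]
            if cand not in STOP_CODONS:
                options.append(cand)
    if not options:
        raise SynthError(f"no substitutable neighbour for codon {codon}")
    return rng.choice(options)


def _assemble(plan: tuple[int, int], codons: list[str]
              ) -> list[tuple[str, int, int]]:
    spans = []
    pos = 0
    for label, n in _blocks(*plan):
        spans.append((label, pos * 3, (pos + n) * 3))
        pos += n
    return spans


def generate_gene_set(spec: SynthSpec
                      ) -> tuple[dict[str, AnnotatedSequence], dict]:
    """Build ``n_genes`` synthetic genes plus ground-truth labels.

    All genes derive from one ancestral sequence; gene *i* carries its own
    disjoint set of single-nucleotide substitutions sized so that every
    pair meets the target identity.  Flanking UTR blocks are shared
    (identical) across genes so non-coding mutations are attributable.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    plans = spec.plans()
    max_plan = (max(p[0] for p in plans), max(p[1] for p in plans))
    n_codons = sum(n for _, n in _blocks(*max_plan))

    # ancestral codons, start codon first, stop codon last
    codons = [_random_codon(rng) for _ in range(n_codons)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    anchored: set[int] = {0, n_codons - 1}
    offset = _LEADER_CODONS
    for _ in range(max_plan[0]):
        for cys_at in _CYS_OFFSETS:
            codons[offset + cys_at] = "TGT"
            anchored.add(offset + cys_at)
        offset += _DOMAIN_CODONS

    flank5 = "".join(rng.choice(_BASES) for _ in range(spec.flank_len))
    flank3 = "".join(rng.choice(_BASES) for _ in range(spec.flank_len))

    # disjoint per-gene mutation sets hit the pairwise identity exactly
    L = n_codons * 3
    d_per_gene = round(L * (1.0 - spec.divergence) / 2.0)
    eligible = [i for i in range(n_codons) if i not in anchored]
    rng.shuffle(eligible)
    if d_per_gene * spec.n_genes > len(eligible):
        raise SynthError(
            f"divergence {spec.divergence} unsatisfiable: need "
            f"{d_per_gene * spec.n_genes} private sites, have {len(eligible)}")

    sequences: dict[str, AnnotatedSequence] = {}
    truth: dict = {"seed": spec.seed, "divergence": spec.divergence,
                   "genes": {}}
    for g in range(spec.n_genes):
        private = sorted(eligible[g * d_per_gene:(g + 1) * d_per_gene])
        gene_codons = list(codons)
        for idx in private:
            gene_codons[idx] = _substitute(gene_codons[idx], rng)
        plan = plans[g]
        # take the blocks this plan asks for from the shared coordinate frame
        kept: list[str] = []
        pos = 0
        keep_labels = {lab for lab, _ in _blocks(*plan)}
        for label, n in _blocks(*max_plan):
            if label in keep_labels:
                take = n if label != "cyt" else plan[1] + 1
                block = gene_codons[pos:pos + take]
                if label == "cyt":
                    block[-1] = "TAA"
                kept.extend(block)
            pos += n
        name = f"SYN{g + 1}"
        seq = AnnotatedSequence(
            name=name, cds="".join(kept), exon_spans=_assemble(plan, kept),
            flank5=flank5, flank3=flank3, complete=True)
        seq.validate()
        sequences[name] = seq
        truth["genes"][name] = {
            "domain_count": plan[0], "tail_codons": plan[1],
            "n_private_mutations": len(private)}
    return sequences, truth


def _copy(seq: AnnotatedSequence, **overrides) -> AnnotatedSequence:
    kw = dict(name=seq.name, cds=seq.cds, exon_spans=list(seq.exon_spans),
              flank5=seq.flank5, flank3=seq.flank3,
              introns=list(seq.introns), complete=seq.complete,
              genomic_exons=seq.genomic_exons)
    kw.update(overrides)
    return AnnotatedSequence(**kw)


def mutate(seq: AnnotatedSequence, kind: str, count: int = 1,
           seed: int = 0, stop_fraction: float = 0.5) -> AnnotatedSequence:
    """Apply ``count`` mutations of one class, seeded and verifiable.

    ``synonymous`` rewrites codons without changing the protein;
    ``nonsynonymous`` changes the encoded residue (never to a stop);
    ``noncoding`` touches only the 3' flank; ``stop`` plants an in-frame
    stop at ``stop_fraction`` of the coding length; ``frameshift`` deletes
    one nucleotide.  Raises :class:`SynthError` when no eligible site
    remains.
    """
    rng = random.Random(seed)
    n_codons = len(seq.cds) // 3
    codons = [seq.cds[3 * i:3 * i + 3] for i in range(n_codons)]

    if kind == "synonymous":
        eligible = [i for i in range(1, n_codons - 1)
                    if _SYNONYMS.get(codons[i])]
        if len(eligible) < count:
            raise SynthError("not enough codons with synonymous variants")
        for i in rng.sample(eligible, count):
            codons[i] = rng.choice(_SYNONYMS[codons[i]])
        return _copy(seq, name=f"{seq.name}+syn{count}",
                     cds="".join(codons))

    if kind == "nonsynonymous":
        eligible = list(range(1, n_codons - 1))
        if len(eligible) < count:
            raise SynthError("not enough codons for nonsynonymous changes")
        for i in rng.sample(eligible, count):
            aa = CODON_TABLE[codons[i]]
            choices = [c for c in SENSE_CODONS if CODON_TABLE[c] != aa]
            codons[i] = rng.choice(choices)
        return _copy(seq, name=f"{seq.name}+nonsyn{count}",
                     cds="".join(codons))

    if kind == "noncoding":
        if seq.flank3 is None:
            raise SynthError("noncoding mutation requires a 3' flank")
        flank = list(seq.flank3)
        if len(flank) < count:
            raise SynthError("3' flank shorter than requested mutation count")
        for i in rng.sample(range(len(flank)), count):
            flank[i] = rng.choice([b for b in _BASES if b != flank[i]])
        return _copy(seq, name=f"{seq.name}+nc{count}",
                     flank3="".join(flank))

    if kind == "stop":
        at = min(max(1, int(stop_fraction * (n_codons - 1))), n_codons - 2)
        codons[at] = "TAA"
        return _copy(seq, name=f"{seq.name}+stop@{stop_fraction:g}",
                     cds="".join(codons))

    if kind == "frameshift":
        pos = len(seq.cds) // 2
        cds = seq.cds[:pos] + seq.cds[pos + 1:]
        spans = []
        for label, start, end in seq.exon_spans:
            spans.append((label,
                          start - (start > pos),
                          end - (end > pos)))
        return _copy(seq, name=f"{seq.name}+fs", cds=cds, exon_spans=spans)

    raise SynthError(f"unknown mutation class {kind!r}")


def chimera(parent_a: AnnotatedSequence, parent_b: AnnotatedSequence,
            breakpoint: float) -> AnnotatedSequence:
    """Recombinant cds: *parent_a* up to the breakpoint, *parent_b* after.

    The breakpoint fraction is snapped to a codon boundary.  Parents must
    share a coordinate frame (equal cds length); the annotation is taken
    from parent A.
    """
    if not 0.0 < breakpoint < 1.0:
        raise SynthError("breakpoint must be a fraction in (0,1)")
    if len(parent_a.cds) != len(parent_b.cds):
        raise SynthError("chimera parents must have equal cds length")
    bp = 3 * round(breakpoint * len(parent_a.cds) / 3)
    return _copy(parent_a,
                 name=f"{parent_a.name}x{parent_b.name}@{breakpoint:g}",
                 cds=parent_a.cds[:bp] + parent_b.cds[bp:])
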