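"""Structural features and difference tiers for candidate KIR sequences.

Two jobs live here.  :func:`extract_features` derives from an annotated
coding sequence the properties the nomenclature encodes in a name: number
of Ig-like domains (from exon labels, not motif prediction), cytoplasmic
tail class (long vs short), and the defects that flag a null allele —
premature stop, frameshift, lost start codon.

:func:`classify_difference` compares a candidate against a reference allele
and places the difference in the tier hierarchy the digit fields encode:
``non_synonymous`` (protein-changing; first field), ``synonymous``
(silent coding change; second field), ``non_coding_only`` (intron/UTR
polymorphism only; third field) or ``identical``.  Classification is
codon-by-codon under the standard genetic code over a global alignment;
any indel escalates to the non-synonymous tier.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field

from Bio.Align import PairwiseAligner
from Bio.Seq import Seq

#: Exon labels recognised in annotations. D0/D1/D2 are Ig-domain exons.
EXON_LABELS = ("leader", "D0", "D1", "D2", "stem", "TM", "cyt")
DOMAIN_LABELS = ("D0", "D1", "D2")

_VALID_BASES = frozenset("ACGT")


class AnnotationError(ValueError):
    pass


class NotComparableError(ValueError):
    """Aligned identity below the floor: almost certainly a wrong-gene pair."""


class AmbiguousSequenceError(ValueError):
    """More than the tolerated fraction of ambiguity codes in the cds."""


@dataclass
class FeatureConfig:
    """Tunables for feature extraction; defaults are reported in rationale trails."""
    long_tail_min_codons: int = 60
    itim_pattern: str = r"[ILVS].Y..[LV]"   # ITIM-like inhibitory motif
    premature_stop_fraction: float = 0.90
    max_ambiguous_fraction: float = 0.01


@dataclass
class AnnotatedSequence:
    """A coding sequence plus the light annotation the engine needs.

    ``exon_spans`` are ``(label, start, end)`` half-open 0-based intervals
    over the cds; they must tile it without overlap.  The reading frame is
    anchored at cds position 0.  ``complete`` marks a full-length sequence
    (leader through stop); partial sequences are compared only over their
    annotated region.
    """
    name: str
    cds: str
    exon_spans: list[tuple[str, int, int]] = dc_field(default_factory=list)
    flank5: str | None = None
    flank3: str | None = None
    introns: list[str] = dc_field(default_factory=list)
    complete: bool = True
    #: exon labels present in the genomic gene, when genomic sequence is
    #: available; these override cDNA content for domain counting
    genomic_exons: list[str] | None = None

    def validate(self) -> None:
        if not self.cds:
            raise AnnotationError(f"{self.name}: empty cds")
        if not self.exon_spans:
            raise AnnotationError(f"{self.name}: annotation required "
                                  "(no exon spans)")
        seen = set()
        pos = 0
        for label, start, end in self.exon_spans:
            if label not in EXON_LABELS:
                raise AnnotationError(
                    f"{self.name}: ambiguous exon label {label!r}")
            if label in seen:
                raise AnnotationError(
                    f"{self.name}: duplicate exon label {label!r}")
            seen.add(label)
            if start != pos or end <= start:
                raise AnnotationError(
                    f"{self.name}: exon spans must tile the cds without "
                    f"overlap ({label}: [{start},{end}) after {pos})")
            pos = end
        if pos != len(self.cds):
            raise AnnotationError(
                f"{self.name}: exon spans cover {pos} nt of a "
                f"{len(self.cds)} nt cds")

    def span(self, label: str) -> tuple[int, int] | None:
        for lab, start, end in self.exon_spans:
            if lab == label:
                return (start, end)
        return None

    def ambiguous_positions(self) -> set[int]:
        return {i for i, b in enumerate(self.cds) if b not in _VALID_BASES}


@dataclass
class FeatureReport:
    domain_count: int
    tail_class: str                 # "L" | "S"
    premature_stop: bool
    frameshift: bool
    start_lost: bool
    protein: str
    rationale: dict = dc_field(default_factory=dict)

    @property
    def null_candidate(self) -> bool:
        return self.premature_stop or self.frameshift or self.start_lost


@dataclass
class DifferenceReport:
    tier: str                       # identical | non_synonymous | synonymous | non_coding_only
    n_nonsyn: int
    n_syn: int
    n_noncoding: int
    aligned_identity: float
    n_ambiguous_excluded: int = 0
    partial_basis: bool = False


def read_annotated_fasta(fasta_path, annotation_path) -> dict[str, AnnotatedSequence]:
    """Load sequences (FASTA) plus their annotation sidecar (JSON).

    The sidecar maps record id to ``{"exons": [[label, start, end], ...],
    "flank5": ..., "flank3": ..., "introns": [...], "complete": bool,
    "genomic_exons": [...]}``; spans are half-open 0-based over the cds.
    """
    import json as _json
    from Bio import SeqIO
    with open(annotation_path) as fh:
        ann = _json.load(fh)
    out = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        entry = ann.get(rec.id)
        if entry is None:
            raise AnnotationError(f"{rec.id}: annotation required "
                                  "(no sidecar entry)")
        seq = AnnotatedSequence(
            name=rec.id, cds=str(rec.seq).upper(),
            exon_spans=[(lab, int(s), int(e))
                        for lab, s, e in entry.get("exons", [])],
            flank5=entry.get("flank5"), flank3=entry.get("flank3"),
            introns=list(entry.get("introns", [])),
            complete=bool(entry.get("complete", True)),
            genomic_exons=entry.get("genomic_exons"))
        seq.validate()
        out[rec.id] = seq
    return out


def write_annotated_fasta(seqs: dict[str, AnnotatedSequence],
                          fasta_path, annotation_path) -> None:
    """Inverse of :func:`read_annotated_fasta`."""
    import json as _json
    from Bio.Seq import Seq as _Seq
    from Bio.SeqIO import write as _write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(_Seq(s.cds), id=name, description="")
               for name, s in seqs.items()]
    _write(records, str(fasta_path), "fasta")
    ann = {name: {"exons": [list(span) for span in s.exon_spans],
                  "flank5": s.flank5, "flank3": s.flank3,
                  "introns": s.introns, "complete": s.complete,
                  "genomic_exons": s.genomic_exons}
           for name, s in seqs.items()}
    with open(annotation_path, "w") as fh:
        _json.dump(ann, fh, indent=1)
        fh.write("\n")


def make_aligner(match: float = 1.0, mismatch: float = -1.0,
                 gap_open: float = -4.0, gap_extend: float = -1.0
                 ) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def translate(cds: str) -> str:
    """Standard-code translation of the in-frame portion, stops included."""
    usable = len(cds) - len(cds) % 3
    return str(Seq(cds[:usable]).translate())


def extract_features(seq: AnnotatedSequence,
                     cfg: FeatureConfig | None = None) -> FeatureReport:
    """Derive the name-relevant structural features of a sequence.

    Domain counting is annotation-driven: the number of D0/D1/D2 exon spans,
    or — when a genomic exon inventory is supplied — the genomic content,
    since splice variants can drop a domain exon from the cDNA while the
    gene itself retains it.
    """
    cfg = cfg or FeatureConfig()
    seq.validate()

    cdna_domains = sum(1 for lab, _, _ in seq.exon_spans
                       if lab in DOMAIN_LABELS)
    if seq.genomic_exons is not None:
        domain_count = sum(1 for lab in seq.genomic_exons
                           if lab in DOMAIN_LABELS)
        domain_basis = "genomic"
    else:
        domain_count = cdna_domains
        domain_basis = "cdna"

    protein = translate(seq.cds)
    n_codons = len(seq.cds) // 3
    stop_at = protein.find("*")
    # the terminal stop of a complete cds is not premature
    premature_stop = (
        0 <= stop_at < cfg.premature_stop_fraction * (n_codons - 1))
    frameshift = seq.complete and len(seq.cds) % 3 != 0
    start_lost = not seq.cds.upper().startswith("ATG")

    cyt = seq.span("cyt")
    tail_codons = (cyt[1] - cyt[0]) // 3 if cyt else 0
    cyt_protein = protein[cyt[0] // 3:cyt[1] // 3] if cyt else ""
    has_itim = bool(re.search(cfg.itim_pattern, cyt_protein))
    tail_class = ("L" if tail_codons >= cfg.long_tail_min_codons or has_itim
                  else "S")

    return FeatureReport(
        domain_count=domain_count,
        tail_class=tail_class,
        premature_stop=premature_stop,
        frameshift=frameshift,
        start_lost=start_lost,
        protein=protein[:stop_at] if stop_at >= 0 else protein,
        rationale={
            "domain_basis": domain_basis,
            "cdna_domain_count": cdna_domains,
            "tail_codons": tail_codons,
            "itim_motif": has_itim,
            "long_tail_min_codons": cfg.long_tail_min_codons,
            "premature_stop_fraction": cfg.premature_stop_fraction,
        },
    )


def _aligned_columns(a: str, b: str, aligner: PairwiseAligner):
    """Best global alignment as (a_pos|None, b_pos|None) column pairs."""
    alignment = aligner.align(a, b)[0]
    cols = []
    for (astart, aend), (bstart, bend) in zip(*alignment.aligned):
        cols.append(((astart, aend), (bstart, bend)))
    # expand aligned blocks into per-column pairs, inserting gap columns
    pairs = []
    prev_a = prev_b = 0
    for (astart, aend), (bstart, bend) in cols:
        for i in range(prev_a, astart):
            pairs.append((i, None))
        for j in range(prev_b, bstart):
            pairs.append((None, j))
        for i, j in zip(range(astart, aend), range(bstart, bend)):
            pairs.append((i, j))
        prev_a, prev_b = aend, bend
    for i in range(prev_a, len(a)):
        pairs.append((i, None))
    for j in range(prev_b, len(b)):
        pairs.append((None, j))
    return pairs


def _count_flank_diffs(a: str, b: str, aligner: PairwiseAligner) -> int:
    if a == b:
        return 0
    pairs = _aligned_columns(a, b, aligner)
    diffs = 0
    for i, j in pairs:
        if i is None or j is None:
            diffs += 1
        elif a[i] != b[j]:
            diffs += 1
    return diffs


def classify_difference(novel: AnnotatedSequence, ref: AnnotatedSequence,
                        comparability_floor: float = 0.70,
                        cfg: FeatureConfig | None = None,
                        aligner: PairwiseAligner | None = None
                        ) -> DifferenceReport:
    """Tier the difference between a candidate and a reference allele.

    Substitutions within gapless aligned codons are labelled synonymous or
    non-synonymous by standard-code translation; any indel (which disrupts
    or shifts codons) counts as non-synonymous-tier.  Flank blocks are
    compared only when both sequences carry them.  Positions holding
    ambiguity codes are excluded from the counts and reported.
    """
    cfg = cfg or FeatureConfig()
    novel.validate()
    ref.validate()
    aligner = aligner or make_aligner()

    for seq in (novel, ref):
        amb = seq.ambiguous_positions()
        if len(amb) > cfg.max_ambiguous_fraction * len(seq.cds):
            raise AmbiguousSequenceError(
                f"{seq.name}: {len(amb)} ambiguous positions exceed "
                f"{cfg.max_ambiguous_fraction:.0%} of the cds")

    a, b = novel.cds.upper(), ref.cds.upper()
    amb_a = novel.ambiguous_positions()
    amb_b = ref.ambiguous_positions()

    if a == b:
        pairs = [(i, i) for i in range(len(a))]
        matches = len(a)
        n_columns = len(a)
        has_indel = False
    else:
        pairs = _aligned_columns(a, b, aligner)
        matches = sum(1 for i, j in pairs
                      if i is not None and j is not None and a[i] == b[j])
        n_columns = len(pairs)
        has_indel = any(i is None or j is None for i, j in pairs)

    identity = matches / n_columns if n_columns else 0.0
    if identity < comparability_floor:
        raise NotComparableError(
            f"{novel.name} vs {ref.name}: aligned identity "
            f"{identity:.2f} below floor {comparability_floor:.2f}; "
            "likely a wrong-gene comparison")

    # map novel positions to ref positions for codon-wise classification
    pos_map = {i: j for i, j in pairs if i is not None}
    n_syn = n_nonsyn = n_excluded = 0
    if has_indel:
        # indels disrupt the protein; escalate without codon bookkeeping
        n_nonsyn += sum(1 for i, j in pairs if i is None or j is None)
    for c in range(len(a) // 3):
        i0 = 3 * c
        js = [pos_map.get(i0 + k) for k in range(3)]
        if None in js:
            continue  # gapped codon, already escalated
        if js[1] != js[0] + 1 or js[2] != js[0] + 2 or js[0] % 3 != 0:
            # codon aligned out of frame against the reference
            n_nonsyn += 1
            continue
        codon_a = a[i0:i0 + 3]
        codon_b = b[js[0]:js[0] + 3]
        if codon_a == codon_b:
            continue
        if (any(i0 + k in amb_a for k in range(3))
                or any(js[0] + k in amb_b for k in range(3))):
            n_excluded += 1
            continue
        if translate(codon_a) == translate(codon_b):
            n_syn += 1
        else:
            n_nonsyn += 1

    # non-coding blocks: compared only when both sides carry them
    n_noncoding = 0
    if novel.flank5 is not None and ref.flank5 is not None:
        n_noncoding += _count_flank_diffs(novel.flank5.upper(),
                                          ref.flank5.upper(), aligner)
    if novel.flank3 is not None and ref.flank3 is not None:
        n_noncoding += _count_flank_diffs(novel.flank3.upper(),
                                          ref.flank3.upper(), aligner)
    for intron_a, intron_b in zip(novel.introns, ref.introns):
        n_noncoding += _count_flank_diffs(intron_a.upper(),
                                          intron_b.upper(), aligner)

    if n_nonsyn > 0:
        tier = "non_synonymous"
    elif n_syn > 0:
        tier = "synonymous"
    elif n_noncoding > 0:
        tier = "non_coding_only"
    else:
        tier = "identical"

    return DifferenceReport(
        tier=tier, n_nonsyn=n_nonsyn, n_syn=n_syn, n_noncoding=n_noncoding,
        aligned_identity=identity, n_ambiguous_excluded=n_excluded,
        partial_basis=not (novel.complete and ref.complete),
    )
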