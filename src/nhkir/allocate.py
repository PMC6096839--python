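"""The naming engine: from a novel sequence to a standards-conformant name.

Given a candidate coding sequence and a registry, the engine decides whether
the sequence is an already-registered allele, a new allele of a known gene
(and at which digit tier), or divergent enough to warrant a provisional
"workshop" gene, and it emits the assigned designation together with a
machine-readable rationale trail.

Locus assignment follows the majority rule used for recombinant alleles:
sliding windows over the candidate each vote for the gene of their nearest
registered allele, and the gene providing the majority of the sequence wins.
A strict >50% majority is required; ties surface as an explicit ambiguity
error for manual review rather than a guess.  Divergence is judged by a
configurable global-identity threshold standing in for phylogenetic
analysis: when no registered gene reaches it, the engine proposes a new
workshop gene (the ``W`` flag), numbered by continuing the species' gene
sequence.

Submission checks mirror database practice: full-length coverage (mandatory
for rhesus macaque) and replication evidence — observation in at least two
individuals or two independent PCR/cloning experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace

from .namegrammar import AlleleName, format_name
from .registry import (AlleleRecord, GeneRecord, Registry, next_available)
from .seqclass import (AnnotatedSequence, FeatureConfig, NotComparableError,
                       classify_difference, extract_features, make_aligner,
                       translate)


class AmbiguousRecombinantError(ValueError):
    """No gene holds a strict majority of window votes; needs manual review."""

    def __init__(self, message: str, votes: dict[str, int]):
        super().__init__(message)
        self.votes = votes


@dataclass
class AllocatorConfig:
    """Free parameters of the engine; the qualitative rules leave these open."""
    new_gene_identity_threshold: float = 0.96
    window_size: int = 100          # nt
    window_step: int = 50           # nt
    comparability_floor: float = 0.70
    premature_stop_fraction: float = 0.90

    def validate(self) -> None:
        for name in ("new_gene_identity_threshold", "comparability_floor"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.window_step > self.window_size:
            raise ValueError("window_step must not exceed window_size")

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            premature_stop_fraction=self.premature_stop_fraction)


@dataclass
class NewGeneProposal:
    species: str
    symbol: AlleleName              # workshop gene-level name
    best_identity: float


@dataclass
class NamingDecision:
    status: str    # existing_allele | new_tier1 | new_tier2 | new_tier3
                   # | new_gene_workshop | rejected
    assigned: AlleleName | None
    nearest: list[tuple[str, float]] = dc_field(default_factory=list)
    window_votes: list[tuple[int, str | None]] | None = None
    suffix_triggers: list[str] = dc_field(default_factory=list)
    checks: dict = dc_field(default_factory=dict)
    rationale: dict = dc_field(default_factory=dict)

    @property
    def designation(self) -> str | None:
        return format_name(self.assigned) if self.assigned else None

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "assigned": self.designation,
            "nearest": [[d, round(i, 4)] for d, i in self.nearest],
            "window_votes": self.window_votes,
            "suffix_triggers": self.suffix_triggers,
            "checks": self.checks,
            "rationale": self.rationale,
        }


# the macaque rule generalises: sequences from other macaque species are
# named to match the closest rhesus gene, keeping their own prefix
REFERENCE_SPECIES = {"Mafa": "Mamu", "Mane": "Mamu"}


def _as_annotated(record: AlleleRecord) -> AnnotatedSequence:
    """Wrap a registry allele for comparison.

    When the record carries no exon annotation a frame-only single span is
    used: difference tiering needs only the reading frame (anchored at cds
    position 0), not the domain boundaries.
    """
    spans = [tuple(s) for s in record.exon_spans]
    if not spans:
        spans = [("leader", 0, len(record.cds or ""))]
    return AnnotatedSequence(
        name=record.designation, cds=record.cds or "",
        exon_spans=spans, flank5=record.flank5, flank3=record.flank3)


def _match_vector(novel_cds: str, ref_cds: str, aligner) -> tuple[list, float]:
    """Per-novel-position match flags and the global aligned identity."""
    from .seqclass import _aligned_columns
    vec = [False] * len(novel_cds)
    if novel_cds == ref_cds:
        return [True] * len(novel_cds), 1.0
    pairs = _aligned_columns(novel_cds, ref_cds, aligner)
    matches = 0
    for i, j in pairs:
        if i is not None and j is not None and novel_cds[i] == ref_cds[j]:
            vec[i] = True
            matches += 1
    return vec, matches / len(pairs) if pairs else 0.0


def assign_locus(novel: AnnotatedSequence, reg: Registry, species: str,
                 cfg: AllocatorConfig | None = None
                 ) -> tuple[GeneRecord | NewGeneProposal,
                            list[tuple[int, str | None]],
                            list[tuple[str, float]]]:
    """Pick the locus for a candidate by windowed nearest-neighbour vote.

    Returns ``(gene-or-proposal, window_votes, nearest)`` where
    ``window_votes`` lists ``(window_start, gene_symbol-or-None)`` (``None``
    marks an abstained tied window) and ``nearest`` the best global identity
    per registered allele, descending.

    Raises :class:`AmbiguousRecombinantError` when no gene commands a strict
    majority of the windows.
    """
    cfg = cfg or AllocatorConfig()
    cfg.validate()
    novel.validate()
    ref_species = REFERENCE_SPECIES.get(species, species)
    aligner = make_aligner()
    cds = novel.cds.upper()

    candidates = [a for a in reg.alleles_of(ref_species) if a.cds]
    identities: dict[str, float] = {}
    vectors: dict[str, tuple[str, list]] = {}     # designation -> (gene, vec)
    for allele in candidates:
        vec, ident = _match_vector(cds, allele.cds.upper(), aligner)
        identities[allele.designation] = ident
        vectors[allele.designation] = (allele.gene_symbol, vec)
    nearest = sorted(identities.items(), key=lambda kv: (-kv[1], kv[0]))
    best = nearest[0][1] if nearest else 0.0

    # windowed vote among comparable alleles
    comparable = {d: gv for d, gv in vectors.items()
                  if identities[d] >= cfg.comparability_floor}
    starts = list(range(0, max(len(cds) - cfg.window_size, 0) + 1,
                        cfg.window_step)) or [0]
    votes: dict[str, int] = {}
    window_votes: list[tuple[int, str | None]] = []
    window_best: list[float] = []
    for start in starts:
        end = min(start + cfg.window_size, len(cds))
        per_gene: dict[str, float] = {}
        for _, (gene_sym, vec) in comparable.items():
            ident = sum(vec[start:end]) / (end - start)
            if ident > per_gene.get(gene_sym, -1.0):
                per_gene[gene_sym] = ident
        if not per_gene:
            window_votes.append((start, None))
            window_best.append(0.0)
            continue
        top = max(per_gene.values())
        window_best.append(top)
        leaders = sorted(g for g, v in per_gene.items() if v == top)
        if len(leaders) == 1:
            votes[leaders[0]] = votes.get(leaders[0], 0) + 1
            window_votes.append((start, leaders[0]))
        else:
            window_votes.append((start, None))    # tied window abstains

    # Divergence test: a sequence is a new-gene candidate only if neither
    # its best global identity nor its mosaic identity (per-window nearest
    # neighbour, averaged) reaches the threshold.  The mosaic term keeps
    # recombinants of registered genes — whose global identity to each
    # parent is depressed by construction — on the allele path.
    mosaic = (sum(window_best) / len(window_best)) if window_best else 0.0
    if max(best, mosaic) < cfg.new_gene_identity_threshold:
        feats = extract_features(novel, cfg.feature_config())
        genes = reg.genes_of(ref_species)
        numeric_ids = [int(g.symbol.gene_id) for g in genes
                       if g.symbol.gene_id]
        width = reg.config_for(ref_species).gene_id_width
        next_id = str(max(numeric_ids, default=0) + 1).zfill(width)
        symbol = AlleleName(
            species_prefix=species, domain_count=feats.domain_count,
            tail_class=feats.tail_class, workshop=True, gene_id=next_id)
        return (NewGeneProposal(species=species, symbol=symbol,
                                best_identity=best),
                [], nearest)

    total = len(starts)
    winner = [g for g, n in votes.items() if n > total / 2]
    if not winner:
        raise AmbiguousRecombinantError(
            f"no gene holds a majority of {total} windows "
            f"(votes: {dict(sorted(votes.items()))}); manual review required",
            votes)
    gene = reg.genes[(ref_species, winner[0])]
    return gene, window_votes, nearest


def _check_full_length(novel: AnnotatedSequence) -> bool:
    """Full length = annotated leader through a stop codon, marked complete."""
    return (novel.complete and novel.span("leader") is not None
            and "*" in translate(novel.cds))


def _check_evidence(evidence: list[dict]) -> bool:
    individuals = {e.get("label") for e in evidence
                   if e.get("kind") == "individual"}
    pcr = {e.get("label") for e in evidence
           if e.get("kind") == "independent_pcr"}
    return len(individuals) >= 2 or len(pcr) >= 2


def assign_name(novel: AnnotatedSequence, reg: Registry, species: str,
                meta: dict | None = None,
                cfg: AllocatorConfig | None = None,
                commit: bool = False) -> NamingDecision:
    """Run the full naming pipeline and (optionally) commit the result.

    ``meta`` carries ``date`` (ISO), ``evidence`` (list of ``{kind, label}``
    with kind ``individual`` or ``independent_pcr``) and optional curator
    fields.  With ``commit`` the registry gains the new allele (and gene,
    for a workshop proposal); an ``existing_allele`` outcome never mutates
    the registry, so resubmission is idempotent.
    """
    cfg = cfg or AllocatorConfig()
    cfg.validate()
    meta = meta or {}
    novel.validate()

    checks: dict[str, str] = {}
    mandatory = reg.config_for(
        REFERENCE_SPECIES.get(species, species)).full_length_mandatory
    full = _check_full_length(novel)
    checks["full_length"] = "pass" if full else ("fail" if mandatory
                                                 else "waived")
    checks["evidence"] = ("pass" if _check_evidence(meta.get("evidence", []))
                          else "fail")
    failed = [k for k, v in checks.items() if v == "fail"]
    if failed:
        return NamingDecision(status="rejected", assigned=None, checks=checks,
                              rationale={"failed_checks": failed})

    feats = extract_features(novel, cfg.feature_config())
    suffix_triggers = [flag for flag in
                       ("premature_stop", "frameshift", "start_lost")
                       if getattr(feats, flag)]
    suffix = "N" if suffix_triggers else "none"

    locus, window_votes, nearest = assign_locus(novel, reg, species, cfg)
    nearest_out = nearest[:5]

    if isinstance(locus, NewGeneProposal):
        assigned = replace(locus.symbol, field1="001", suffix=suffix)
        decision = NamingDecision(
            status="new_gene_workshop", assigned=assigned,
            nearest=nearest_out, window_votes=window_votes or None,
            suffix_triggers=suffix_triggers, checks=checks,
            rationale={
                "best_identity": round(locus.best_identity, 4),
                "new_gene_identity_threshold": cfg.new_gene_identity_threshold,
                "workshop": "divergence below threshold for every "
                            "registered gene; W flag pending genomic or "
                            "family evidence",
            })
        if commit:
            _commit(reg, decision, novel, meta, species)
        return decision

    gene: GeneRecord = locus
    ref_species = gene.species
    reports = []
    for allele in reg.alleles_of(ref_species, gene.bare_symbol):
        if not allele.cds:
            continue
        try:
            rep = classify_difference(novel, _as_annotated(allele),
                                      comparability_floor=cfg.comparability_floor,
                                      cfg=cfg.feature_config())
        except NotComparableError:
            continue
        reports.append((allele, rep))

    def best_of(tier: str):
        hits = [(a, r) for a, r in reports if r.tier == tier]
        hits.sort(key=lambda ar: (-ar[1].aligned_identity,
                                  ar[0].designation))
        return hits[0] if hits else None

    rationale: dict = {"gene": gene.designation,
                       "window_majority": _vote_summary(window_votes)}

    hit = best_of("identical")
    if hit is not None:
        allele, rep = hit
        decision = NamingDecision(
            status="existing_allele", assigned=allele.name,
            nearest=nearest_out, window_votes=window_votes,
            suffix_triggers=suffix_triggers, checks=checks,
            rationale={**rationale,
                       "identical_to": allele.designation,
                       "partial_basis": rep.partial_basis})
        return decision     # never mutates the registry

    hit = best_of("synonymous")
    if hit is not None:
        parent, rep = hit
        field2 = next_available(reg, gene, 2, parent=parent)
        assigned = replace(gene.symbol, species_prefix=species,
                           field1=parent.name.field1, field2=field2,
                           field3=None, suffix=suffix, raw="")
        incumbent_long = format_name(replace(
            parent.name, field2=parent.name.field2 or "01", raw=""))
        decision = NamingDecision(
            status="new_tier2", assigned=assigned, nearest=nearest_out,
            window_votes=window_votes, suffix_triggers=suffix_triggers,
            checks=checks,
            rationale={**rationale, "parent": parent.designation,
                       "n_syn": rep.n_syn,
                       "incumbent_canonical": incumbent_long,
                       "partial_basis": rep.partial_basis})
        if commit:
            _commit(reg, decision, novel, meta, species)
        return decision

    hit = best_of("non_coding_only")
    if hit is not None:
        parent, rep = hit
        field3 = next_available(reg, gene, 3, parent=parent)
        assigned = replace(gene.symbol, species_prefix=species,
                           field1=parent.name.field1,
                           field2=parent.name.field2 or "01",
                           field3=field3, suffix=suffix, raw="")
        incumbent_long = format_name(replace(
            parent.name, field2=parent.name.field2 or "01",
            field3=parent.name.field3 or "01", raw=""))
        decision = NamingDecision(
            status="new_tier3", assigned=assigned, nearest=nearest_out,
            window_votes=window_votes, suffix_triggers=suffix_triggers,
            checks=checks,
            rationale={**rationale, "parent": parent.designation,
                       "n_noncoding": rep.n_noncoding,
                       "incumbent_canonical": incumbent_long,
                       "partial_basis": rep.partial_basis})
        if commit:
            _commit(reg, decision, novel, meta, species)
        return decision

    field1 = next_available(reg, gene, 1)
    assigned = replace(gene.symbol, species_prefix=species, field1=field1,
                       field2=None, field3=None, suffix=suffix, raw="")
    decision = NamingDecision(
        status="new_tier1", assigned=assigned, nearest=nearest_out,
        window_votes=window_votes, suffix_triggers=suffix_triggers,
        checks=checks,
        rationale={**rationale,
                   "novel_protein": True,
                   "n_compared": len(reports)})
    if commit:
        _commit(reg, decision, novel, meta, species)
    return decision


def _vote_summary(window_votes) -> dict:
    out: dict[str, int] = {}
    for _, gene in window_votes or []:
        key = gene if gene is not None else "(tie)"
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))


def _commit(reg: Registry, decision: NamingDecision,
            novel: AnnotatedSequence, meta: dict, species: str) -> None:
    assert decision.assigned is not None
    record = AlleleRecord(
        species=species, name=decision.assigned,
        accessions=list(meta.get("accessions", [])),
        references=list(meta.get("references", [])),
        origin=meta.get("origin", ""),
        cds=novel.cds,
        flank5=novel.flank5, flank3=novel.flank3,
        exon_spans=list(novel.exon_spans),
        submission_date=meta.get("date"),
        evidence=list(meta.get("evidence", [])))
    reg.add_allele(record, create_gene=True)
    gene_key = (species, decision.assigned.gene_symbol())
    if decision.status == "new_gene_workshop":
        reg.genes[gene_key].lineage_label = "workshop"


def rename_gene(reg: Registry, species: str, old_symbol: str,
                new_symbol_name: AlleleName) -> None:
    """Admin operation: rename a gene (e.g. promote a workshop gene).

    Every allele of the gene is renamed in place; the old designations are
    preserved as previous designations.  No automatic trigger exists —
    promotion needs genomic or segregation evidence a curator must judge.
    """
    key = (species, old_symbol)
    if key not in reg.genes:
        raise KeyError(f"no gene {old_symbol} in species {species}")
    gene = reg.genes.pop(key)
    old_designation = gene.designation
    gene.symbol = new_symbol_name.gene_name()
    gene.previous_designations = list(gene.previous_designations)
    gene.previous_designations.append(old_designation)
    reg.genes[(species, gene.bare_symbol)] = gene
    for (sp, desig) in list(reg.alleles):
        allele = reg.alleles[(sp, desig)]
        if sp == species and allele.gene_symbol == old_symbol:
            del reg.alleles[(sp, desig)]
            allele.name = replace(
                gene.symbol, field1=allele.name.field1,
                field2=allele.name.field2, field3=allele.name.field3,
                suffix=allele.name.suffix, raw="")
            allele.previous_designations = list(allele.previous_designations)
            allele.previous_designations.append(desig)
            reg.alleles[(sp, allele.designation)] = allele
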