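"""Species/gene/allele registry: data model, integrity rules and I/O.

The registry holds, per species, the named KIR genes and alleles together
with their previous designations, sequence-databank accessions, literature
keys and (for cattle) breed of origin.  The packaged fixture transcribes the
published renaming tables for rhesus macaque (Mamu), chimpanzee (Patr),
both orangutan species (Poab/Popy) and cattle (Bota).

Two interchange dialects are supported: a canonical JSON document and TSV
tables mirroring the published column layout (designation, previous
designations, accessions, reference, optional breed).  Allele coding
sequences travel separately as FASTA keyed by full designation.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field as dc_field
from importlib import resources

from .namegrammar import AlleleName, NameParseError, format_name, parse

_ACCESSION_RE = re.compile(r"^[A-Za-z0-9_.]+$")

#: Orangutan is one taxon split over two species codes; combined statistics
#: union their gene symbols after stripping the prefix.
ORANGUTAN_SPECIES = ("Poab", "Popy")


class RegistryError(Exception):
    pass


class IntegrityError(RegistryError):
    """One or more registry invariants are violated; carries all of them."""

    def __init__(self, problems: list[str]):
        super().__init__("; ".join(problems))
        self.problems = problems


class AllocationError(RegistryError):
    pass


@dataclass
class SpeciesConfig:
    gene_id_width: int = 1            # macaques use two-digit gene numbers
    full_length_mandatory: bool = False


#: Species-specific conventions.  Macaque gene numbering is two-digit and
#: full-length submission is mandatory; other macaque species (Mafa, Mane)
#: follow the rhesus conventions.
DEFAULT_SPECIES_CONFIG = {
    "Mamu": SpeciesConfig(gene_id_width=2, full_length_mandatory=True),
    "Mafa": SpeciesConfig(gene_id_width=2),
    "Mane": SpeciesConfig(gene_id_width=2),
    "Patr": SpeciesConfig(),
    "Poab": SpeciesConfig(),
    "Popy": SpeciesConfig(),
    "Bota": SpeciesConfig(),
}


@dataclass
class GeneRecord:
    species: str
    symbol: AlleleName                       # gene-level name, no digit fields
    previous_designations: list[str] = dc_field(default_factory=list)
    lineage_label: str = ""

    @property
    def pseudogene(self) -> bool:
        return self.symbol.is_pseudogene_symbol

    @property
    def designation(self) -> str:
        return format_name(self.symbol)

    @property
    def bare_symbol(self) -> str:
        return self.symbol.gene_symbol()


@dataclass
class AlleleRecord:
    species: str
    name: AlleleName                         # field1 present
    previous_designations: list[str] = dc_field(default_factory=list)
    accessions: list[str] = dc_field(default_factory=list)
    references: list[str] = dc_field(default_factory=list)
    origin: str = ""                         # animal id / breed, free text
    cds: str | None = None
    flank5: str | None = None
    flank3: str | None = None
    #: optional (label, start, end) exon spans over the cds
    exon_spans: list[tuple[str, int, int]] = dc_field(default_factory=list)
    submission_date: str | None = None       # ISO date
    evidence: list[dict] = dc_field(default_factory=list)

    @property
    def designation(self) -> str:
        return format_name(self.name)

    @property
    def gene_symbol(self) -> str:
        return self.name.gene_symbol()


class Registry:
    """Per-species gene and allele collections with referential integrity."""

    def __init__(self, species_config: dict[str, SpeciesConfig] | None = None,
                 metadata: dict | None = None):
        self.genes: dict[tuple[str, str], GeneRecord] = {}
        self.alleles: dict[tuple[str, str], AlleleRecord] = {}
        self.species_config = dict(DEFAULT_SPECIES_CONFIG)
        if species_config:
            self.species_config.update(species_config)
        self.metadata = metadata or {}

    # -- construction ----------------------------------------------------

    def add_gene(self, record: GeneRecord) -> None:
        if record.symbol.field1 is not None:
            raise IntegrityError(
                [f"gene record {record.designation} carries allele fields"])
        key = (record.species, record.bare_symbol)
        if key in self.genes:
            raise IntegrityError(
                [f"duplicate gene designation {record.designation}"])
        self.genes[key] = record

    def add_allele(self, record: AlleleRecord, create_gene: bool = False) -> None:
        if record.name.field1 is None:
            raise IntegrityError(
                [f"allele record {record.designation} lacks an allele number"])
        gene_key = (record.species, record.gene_symbol)
        if gene_key not in self.genes:
            if not create_gene:
                raise IntegrityError(
                    [f"allele {record.designation} names an unregistered gene"])
            self.genes[gene_key] = GeneRecord(
                species=record.species, symbol=record.name.gene_name())
        key = (record.species, record.designation)
        if key in self.alleles:
            raise IntegrityError(
                [f"duplicate allele designation {record.designation}"])
        self.alleles[key] = record

    # -- queries ---------------------------------------------------------

    def species(self) -> list[str]:
        out = {sp for sp, _ in self.genes} | {sp for sp, _ in self.alleles}
        return sorted(out)

    def genes_of(self, species: str) -> list[GeneRecord]:
        return sorted((g for (sp, _), g in self.genes.items() if sp == species),
                      key=lambda g: g.symbol.sort_key())

    def alleles_of(self, species: str, gene_symbol: str | None = None
                   ) -> list[AlleleRecord]:
        out = [a for (sp, _), a in self.alleles.items()
               if sp == species and
               (gene_symbol is None or a.gene_symbol == gene_symbol)]
        return sorted(out, key=lambda a: a.name.sort_key())

    def get_allele(self, species: str, designation: str) -> AlleleRecord | None:
        return self.alleles.get((species, designation))

    def config_for(self, species: str) -> SpeciesConfig:
        return self.species_config.get(species, SpeciesConfig())

    # -- integrity -------------------------------------------------------

    def validate(self) -> list[str]:
        """Collect invariant violations; an empty list means a clean registry."""
        problems = []
        for (sp, _), gene in self.genes.items():
            if gene.symbol.field1 is not None:
                problems.append(
                    f"gene {gene.designation} carries allele fields")
        seen_fields: dict[tuple, str] = {}
        for (sp, desig), allele in self.alleles.items():
            if (sp, allele.gene_symbol) not in self.genes:
                problems.append(f"allele {desig} names an unregistered gene")
            fields_key = (sp, allele.gene_symbol, allele.name.field1,
                          allele.name.field2, allele.name.field3,
                          allele.name.suffix)
            if fields_key in seen_fields:
                problems.append(
                    f"alleles {seen_fields[fields_key]} and {desig} share "
                    "identical digit fields and suffix")
            seen_fields[fields_key] = desig
            for acc in allele.accessions:
                if not _ACCESSION_RE.match(acc):
                    problems.append(
                        f"allele {desig}: accession {acc!r} is not "
                        "letters+digits")
        return problems


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _split_list(cell: str) -> list[str]:
    cell = (cell or "").strip()
    if not cell or cell == "None":
        return []
    return [part.strip() for part in cell.split("|") if part.strip()]


def _parse_designation(text: str, where: str) -> AlleleName:
    try:
        return parse(text)
    except NameParseError as exc:
        raise RegistryError(f"{where}: cannot parse {text!r}: {exc}") from exc


def load_gene_table(handle: io.TextIOBase, registry: Registry) -> list[str]:
    """Read a gene TSV (species, designation, previous, lineage) into *registry*."""
    problems = []
    reader = csv.DictReader(handle, delimiter="\t")
    for i, row in enumerate(reader, start=2):
        desig = (row.get("designation") or "").strip()
        if not desig:
            continue
        name = _parse_designation(desig, f"gene table row {i}")
        rec = GeneRecord(
            species=(row.get("species") or "").strip() or (name.species_prefix or ""),
            symbol=name,
            previous_designations=_split_list(row.get("previous_designations", "")),
            lineage_label=(row.get("lineage") or "").strip(),
        )
        try:
            registry.add_gene(rec)
        except IntegrityError as exc:
            problems.extend(f"gene table row {i}: {p}" for p in exc.problems)
    return problems


def load_allele_table(handle: io.TextIOBase, registry: Registry,
                      create_genes: bool = False) -> list[str]:
    """Read an allele TSV mirroring the published table columns."""
    problems = []
    reader = csv.DictReader(handle, delimiter="\t")
    for i, row in enumerate(reader, start=2):
        desig = (row.get("designation") or "").strip()
        if not desig:
            continue
        name = _parse_designation(desig, f"allele table row {i}")
        rec = AlleleRecord(
            species=(row.get("species") or "").strip() or (name.species_prefix or ""),
            name=name,
            previous_designations=_split_list(row.get("previous_designations", "")),
            accessions=_split_list(row.get("accessions", "")),
            references=_split_list(row.get("references", "")),
            origin=(row.get("breed") or row.get("origin") or "").strip(),
            cds=(row.get("cds") or "").strip() or None,
        )
        try:
            registry.add_allele(rec, create_gene=create_genes)
        except IntegrityError as exc:
            problems.extend(f"allele table row {i}: {p}" for p in exc.problems)
    return problems


def registry_to_dict(reg: Registry) -> dict:
    return {
        "format": "nhkir-registry",
        "version": 1,
        "metadata": reg.metadata,
        "species_config": {
            sp: {"gene_id_width": cfg.gene_id_width,
                 "full_length_mandatory": cfg.full_length_mandatory}
            for sp, cfg in sorted(reg.species_config.items())
        },
        "genes": [
            {"species": g.species, "designation": g.designation,
             "previous_designations": g.previous_designations,
             "lineage_label": g.lineage_label}
            for g in sorted(reg.genes.values(),
                            key=lambda g: (g.species, g.symbol.sort_key()))
        ],
        "alleles": [
            {"species": a.species, "designation": a.designation,
             "previous_designations": a.previous_designations,
             "accessions": a.accessions, "references": a.references,
             "origin": a.origin, "cds": a.cds,
             "flank5": a.flank5, "flank3": a.flank3,
             "exon_spans": [list(s) for s in a.exon_spans],
             "submission_date": a.submission_date, "evidence": a.evidence}
            for a in sorted(reg.alleles.values(),
                            key=lambda a: (a.species, a.name.sort_key()))
        ],
    }


def registry_from_dict(doc: dict) -> tuple[Registry, list[str]]:
    cfg = {sp: SpeciesConfig(**vals)
           for sp, vals in doc.get("species_config", {}).items()}
    reg = Registry(species_config=cfg, metadata=doc.get("metadata", {}))
    problems: list[str] = []
    for g in doc.get("genes", []):
        name = _parse_designation(g["designation"], "genes[]")
        try:
            reg.add_gene(GeneRecord(
                species=g.get("species") or name.species_prefix or "",
                symbol=name,
                previous_designations=list(g.get("previous_designations", [])),
                lineage_label=g.get("lineage_label", "")))
        except IntegrityError as exc:
            problems.extend(exc.problems)
    for a in doc.get("alleles", []):
        name = _parse_designation(a["designation"], "alleles[]")
        try:
            reg.add_allele(AlleleRecord(
                species=a.get("species") or name.species_prefix or "",
                name=name,
                previous_designations=list(a.get("previous_designations", [])),
                accessions=list(a.get("accessions", [])),
                references=list(a.get("references", [])),
                origin=a.get("origin", ""),
                cds=a.get("cds"),
                flank5=a.get("flank5"), flank3=a.get("flank3"),
                exon_spans=[tuple(s) for s in a.get("exon_spans", [])],
                submission_date=a.get("submission_date"),
                evidence=list(a.get("evidence", []))))
        except IntegrityError as exc:
            problems.extend(exc.problems)
    return reg, problems


def save_registry(reg: Registry, path) -> None:
    with open(path, "w") as fh:
        json.dump(registry_to_dict(reg), fh, indent=1)
        fh.write("\n")


def load_registry(path, strict: bool = True) -> Registry:
    """Load a registry from canonical JSON or from a TSV table.

    A TSV whose header carries an ``accessions`` column is read as an allele
    table (gene records are implied); any other TSV is read as a gene table.
    With ``strict`` (default), integrity violations raise
    :class:`IntegrityError` listing every problem; they are never silently
    dropped.
    """
    path = str(path)
    with open(path) as fh:
        head = fh.read(4096)
        fh.seek(0)
        if head.lstrip().startswith("{"):
            reg, problems = registry_from_dict(json.load(fh))
        else:
            reg = Registry()
            header = head.splitlines()[0] if head.strip() else ""
            if "accessions" in header.split("\t"):
                problems = load_allele_table(fh, reg, create_genes=True)
            else:
                problems = load_gene_table(fh, reg)
    problems.extend(reg.validate())
    if problems and strict:
        raise IntegrityError(problems)
    return reg


def load_default_registry() -> Registry:
    """The packaged registry transcribed from the published tables."""
    reg = Registry(metadata={
        "source": "published non-human KIR renaming tables",
        "notes": [
            "cattle: prose reports 16 genes while the allele table prints "
            "17 distinct gene designations; all 17 are recorded",
        ],
    })
    data = resources.files("nhkir.data")
    problems = []
    with (data / "genes.tsv").open() as fh:
        problems += load_gene_table(fh, reg)
    with (data / "alleles.tsv").open() as fh:
        problems += load_allele_table(fh, reg)
    problems += reg.validate()
    if problems:
        raise IntegrityError(problems)
    return reg


def write_fasta(reg: Registry, path) -> int:
    """Write every allele cds as FASTA keyed by full designation."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    records = [SeqRecord(Seq(a.cds), id=a.designation, description="")
               for a in sorted(reg.alleles.values(),
                               key=lambda a: (a.species, a.name.sort_key()))
               if a.cds]
    return seqio_write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# statistics and number allocation
# ---------------------------------------------------------------------------

def registry_stats(reg: Registry, species: str,
                   combined_orangutan: bool = False) -> dict:
    """Census of a species: gene, pseudogene and allele counts.

    With ``combined_orangutan`` the two orangutan species are treated as one
    taxon: gene symbols are unioned after stripping the species prefix.
    """
    if combined_orangutan:
        members = ORANGUTAN_SPECIES
        if species not in members:
            raise RegistryError(
                f"combined mode applies to orangutan species, not {species!r}")
    else:
        members = (species,)
        if species not in reg.species():
            raise RegistryError(f"unknown species {species!r}")
    symbols: dict[str, bool] = {}
    for sp in members:
        for gene in reg.genes_of(sp):
            symbols.setdefault(gene.bare_symbol, gene.pseudogene)
    per_gene = {sym: 0 for sym in symbols}
    n_alleles = 0
    for sp in members:
        for allele in reg.alleles_of(sp):
            per_gene[allele.gene_symbol] = per_gene.get(allele.gene_symbol, 0) + 1
            n_alleles += 1
    return {
        "n_genes": sum(1 for p in symbols.values() if not p),
        "n_pseudogenes": sum(1 for p in symbols.values() if p),
        "n_alleles": n_alleles,
        "per_gene_counts": dict(sorted(per_gene.items())),
    }


def next_available(reg: Registry, gene: GeneRecord, tier: int,
                   parent: AlleleRecord | None = None) -> str:
    """Next unassigned digit field at *tier* (1-3), zero-padded.

    Allocation is always max+1 in deposition order; gaps left by withdrawn
    names are never refilled.  Tiers 2 and 3 are scoped to *parent*'s name:
    an incumbent printed without the lower tier counts as ``:01`` there.
    """
    alleles = reg.alleles_of(gene.species, gene.bare_symbol)
    if tier == 1:
        width, cap = 3, 999
        values = [int(a.name.field1) for a in alleles]
    elif tier in (2, 3):
        if parent is None:
            raise AllocationError(f"tier {tier} allocation requires a parent allele")
        width, cap = 2, 99
        if tier == 2:
            scoped = [a for a in alleles if a.name.field1 == parent.name.field1]
            values = [int(a.name.field2) if a.name.field2 is not None else 1
                      for a in scoped]
        else:
            scoped = [a for a in alleles
                      if a.name.field1 == parent.name.field1
                      and (a.name.field2 or "01") == (parent.name.field2 or "01")]
            values = [int(a.name.field3) if a.name.field3 is not None else 1
                      for a in scoped]
    else:
        raise AllocationError(f"no such tier {tier}")
    nxt = (max(values) + 1) if values else 1
    if nxt > cap:
        raise AllocationError(f"tier {tier} exhausted for {gene.designation}")
    return str(nxt).zfill(width)
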