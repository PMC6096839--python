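"""Resolution of legacy (pre-standardization) KIR names to current ones.

Before the common nomenclature, the same sequence could circulate under
several laboratory names, and one legacy symbol could cover what are now
several genes (macaque "KIR3DL2" ended up split over two loci).  The
resolver indexes every previous designation recorded in the registry —
gene-level and allele-level — and returns *all* matching current
designations; genuine ambiguity is preserved, never arbitrated.  An
accession identifier, when supplied, narrows the candidates to alleles
carrying it.

Legacy strings are opaque keys: they are not required to (and mostly do
not) parse under the current grammar.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .registry import Registry

_PREFIX_STRIP_RE = re.compile(r"^[A-Za-z]{2,4}-(?=KIR)")
_MIN_SPLIT_PART = 3   # slash-compounds split only into plausible name parts


@dataclass(frozen=True)
class ResolutionHit:
    designation: str            # current designation
    species: str
    level: str                  # "gene" | "allele"
    accessions: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class Resolution:
    """Outcome of a legacy lookup.

    ``status`` distinguishes an empty result ("no_mapping") from success;
    a malformed query raises instead.
    """
    query: str
    targets: tuple[ResolutionHit, ...]

    @property
    def status(self) -> str:
        return "resolved" if self.targets else "no_mapping"

    @property
    def designations(self) -> set[str]:
        return {t.designation for t in self.targets}


def normalize(name: str) -> str:
    """Normalization used for index keys and queries.

    Strips surrounding whitespace and an optional species prefix directly
    preceding ``KIR`` (``Mamu-KIR...``, ``Pt-KIR...``); matching is
    case-insensitive.  Everything else — punctuation, lab suffixes — is
    significant.
    """
    s = name.strip()
    s = _PREFIX_STRIP_RE.sub("", s)
    return s.upper()


class LegacyIndex:
    """Index of previous designations built from a registry."""

    def __init__(self, registry: Registry):
        self._index: dict[str, list[ResolutionHit]] = {}
        for gene in registry.genes.values():
            hit = ResolutionHit(gene.designation, gene.species, "gene")
            for prev in gene.previous_designations:
                self._add(prev, hit)
            # idempotence: a current designation resolves to itself
            self._add(gene.designation, hit)
        for allele in registry.alleles.values():
            hit = ResolutionHit(allele.designation, allele.species, "allele",
                                tuple(allele.accessions))
            for prev in allele.previous_designations:
                self._add(prev, hit)
            self._add(allele.designation, hit)

    def _add(self, legacy: str, hit: ResolutionHit) -> None:
        keys = {normalize(legacy)}
        # orangutan tables mix whole compounds ("2DSD/2DSA") with the parts;
        # index both, but only split into plausible name-sized pieces
        if "/" in legacy:
            parts = [p.strip() for p in legacy.split("/")]
            if all(len(p) >= _MIN_SPLIT_PART for p in parts):
                keys.update(normalize(p) for p in parts)
        for key in keys:
            bucket = self._index.setdefault(key, [])
            if hit not in bucket:
                bucket.append(hit)

    def resolve(self, query: str, species: str | None = None,
                accession: str | None = None) -> Resolution:
        """All current designations whose previous names contain *query*.

        ``species`` restricts to one species; without it every species is
        searched and the union returned (hits are tagged by species).
        ``accession`` keeps only targets recorded with that accession —
        a filter that can never enlarge the result set.
        """
        if not query.strip():
            raise ValueError("empty legacy query")
        hits = self._index.get(normalize(query), [])
        if species is not None:
            hits = [h for h in hits if h.species == species]
        if accession is not None:
            acc = accession.strip().upper()
            hits = [h for h in hits
                    if any(a.upper() == acc for a in h.accessions)]
        ordered = tuple(sorted(hits, key=lambda h: (h.species, h.designation)))
        return Resolution(query=query, targets=ordered)

    def known_keys(self) -> set[str]:
        return set(self._index)


def resolve_legacy(registry: Registry, query: str, species: str | None = None,
                   accession: str | None = None) -> Resolution:
    """One-shot resolution; builds a throwaway index. See :class:`LegacyIndex`."""
    return LegacyIndex(registry).resolve(query, species, accession)
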