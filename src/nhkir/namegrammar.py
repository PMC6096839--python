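"""Grammar for non-human KIR gene and allele designations.

A designation names a killer-cell immunoglobulin-like receptor (KIR) gene or
allele, e.g. ``Mamu-KIR3DL01*019:02``.  Reading left to right it carries an
optional four-letter species code, the ``KIR`` acronym, the number of
extracellular Ig-like domains, a cytoplasmic-tail class (``L`` long, ``S``
short, ``P`` pseudogene), an optional ``W`` marking a provisional "workshop"
gene, an optional ``X`` marking membership of the deeply divergent KIR3DX
lineage, a gene number, and — after ``*`` — up to three colon-separated digit
fields plus an optional expression suffix.  The three digit tiers encode,
respectively, protein-level (non-synonymous) differences, synonymous coding
differences, and intron/UTR-only differences.

Two degenerate symbol forms exist: ``KIR1D`` (a single-domain gene with no
tail letter) and ``KIRDP`` (a pseudogene symbol with no domain digit).  The
``X`` marker occurs in two printed positions which are deliberately kept
distinct: between ``D`` and the tail letter in cattle (``3DXL1``) and after
the tail letter in the macaque ``3DLX1``.

Zero padding of the gene number is data, not presentation: macaque genes are
two-digit (``3DL01``), ape and cattle genes unpadded (``3DL1``).  Parsing
preserves the printed form and :func:`format_name` reproduces it byte for
byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from functools import total_ordering


class NameParseError(ValueError):
    """A designation string does not conform to the nomenclature grammar.

    Carries the offending token and its character position in the input.
    """

    def __init__(self, message: str, token: str = "", position: int = 0):
        super().__init__(message)
        self.token = token
        self.position = position


class XLineage(str, Enum):
    NONE = "none"
    PRE_TAIL = "pre_tail"    # cattle style: 3DXL1
    POST_TAIL = "post_tail"  # macaque style: 3DLX1


#: Valid expression-status suffixes. N = null (not expressed); L/S/C/A/Q
#: describe low / secreted / cytoplasmic / aberrant / questionable expression.
SUFFIXES = frozenset("NLSCAQ")

_TAIL_ORDER = {"L": 0, "S": 1, "P": 2, "none": 3}
_X_ORDER = {XLineage.NONE: 0, XLineage.PRE_TAIL: 1, XLineage.POST_TAIL: 2}

_PREFIX_RE = re.compile(r"^([A-Z][a-z]{3})-")
_FIELD1_RE = re.compile(r"^\d{3}$")
_FIELD23_RE = re.compile(r"^\d{2}$")


@total_ordering
@dataclass(frozen=True)
class AlleleName:
    """Structured decomposition of a KIR designation string.

    ``field1`` absent means a gene-level name.  ``gene_id`` is the printed
    gene number with zero padding preserved; it is empty for the ``KIR1D``
    and ``KIRDP`` symbol forms.
    """

    species_prefix: str | None = None
    domain_count: int | None = None      # None only for the KIRDP form
    x_lineage: XLineage = XLineage.NONE
    tail_class: str = "L"                # "L" | "S" | "P" | "none"
    workshop: bool = False
    gene_id: str = ""
    field1: str | None = None
    field2: str | None = None
    field3: str | None = None
    suffix: str = "none"                 # "none" or one of SUFFIXES
    raw: str = field(default="", compare=False)

    # -- derived views ---------------------------------------------------

    @property
    def is_gene_level(self) -> bool:
        return self.field1 is None

    @property
    def is_pseudogene_symbol(self) -> bool:
        return self.tail_class == "P"

    def gene_symbol(self) -> str:
        """The bare gene symbol, e.g. ``3DL01`` or ``DP`` (no species/KIR)."""
        if self.domain_count is None:
            return "DP"
        parts = [str(self.domain_count), "D"]
        if self.x_lineage is XLineage.PRE_TAIL:
            parts.append("X")
        if self.tail_class != "none":
            parts.append(self.tail_class)
        if self.workshop:
            parts.append("W")
        if self.x_lineage is XLineage.POST_TAIL:
            parts.append("X")
        parts.append(self.gene_id)
        return "".join(parts)

    def gene_name(self) -> "AlleleName":
        """This name stripped to gene level (no digit fields, no suffix)."""
        return replace(self, field1=None, field2=None, field3=None,
                       suffix="none", raw="")

    def violations(self) -> list[str]:
        """Invariant violations, empty when the name is well formed."""
        problems = []
        if self.domain_count is not None and not 1 <= self.domain_count <= 3:
            problems.append(f"domain count {self.domain_count} out of range 1-3")
        if self.tail_class not in ("L", "S", "P", "none"):
            problems.append(f"invalid tail class {self.tail_class!r}")
        if self.tail_class == "none" and self.domain_count != 1:
            problems.append("tail class absent is legal only for the 1D form")
        if self.workshop and self.tail_class not in ("L", "S", "P"):
            problems.append("workshop flag requires an L/S/P tail letter")
        if self.domain_count is None and self.tail_class != "P":
            problems.append("missing domain count outside the DP form")
        if self.field2 is not None and self.field1 is None:
            problems.append("second digit field without a first")
        if self.field3 is not None and self.field2 is None:
            problems.append("third digit field without a second")
        if self.suffix != "none" and self.suffix not in SUFFIXES:
            problems.append(f"invalid suffix {self.suffix!r}")
        if self.suffix != "none" and self.field1 is None:
            problems.append("suffix on a gene-level name")
        if self.field1 is not None and not _FIELD1_RE.match(self.field1):
            problems.append(f"first field {self.field1!r} is not 3 digits")
        for f in (self.field2, self.field3):
            if f is not None and not _FIELD23_RE.match(f):
                problems.append(f"field {f!r} is not 2 digits")
        if self.gene_id and not re.match(r"^\d{1,2}$", self.gene_id):
            problems.append(f"gene id {self.gene_id!r} is not 1-2 digits")
        return problems

    def sort_key(self):
        return (
            self.species_prefix or "",
            self.domain_count or 0,
            _X_ORDER[self.x_lineage],
            _TAIL_ORDER[self.tail_class],
            self.workshop,
            int(self.gene_id) if self.gene_id else -1,
            -1 if self.field1 is None else int(self.field1),
            -1 if self.field2 is None else int(self.field2),
            -1 if self.field3 is None else int(self.field3),
            "" if self.suffix == "none" else self.suffix,
        )

    def __lt__(self, other: "AlleleName") -> bool:
        return self.sort_key() < other.sort_key()

    def __str__(self) -> str:
        return format_name(self)

    def to_dict(self) -> dict:
        return {
            "species_prefix": self.species_prefix,
            "domain_count": self.domain_count,
            "x_lineage": self.x_lineage.value,
            "tail_class": self.tail_class,
            "workshop": self.workshop,
            "gene_id": self.gene_id,
            "field1": self.field1,
            "field2": self.field2,
            "field3": self.field3,
            "suffix": self.suffix,
            "raw": self.raw,
        }


def _parse_symbol(symbol: str, offset: int) -> dict:
    """Decompose the gene-symbol portion (after ``KIR``, before ``*``)."""
    if symbol == "DP":
        return dict(domain_count=None, tail_class="P",
                    x_lineage=XLineage.NONE, workshop=False, gene_id="")
    if not symbol:
        raise NameParseError("missing gene symbol after 'KIR'",
                             token=symbol, position=offset)
    m = re.match(r"^(\d)D", symbol)
    if not m:
        raise NameParseError(
            f"gene symbol {symbol!r} must start with a domain digit and 'D'",
            token=symbol, position=offset)
    domain_count = int(m.group(1))
    if not 1 <= domain_count <= 3:
        raise NameParseError(
            f"domain count {domain_count} out of range 1-3",
            token=m.group(1), position=offset)
    rest = symbol[2:]
    if not rest:
        # the KIR1D form: one Ig domain, no tail letter, no gene number
        if domain_count != 1:
            raise NameParseError(
                f"gene symbol {symbol!r} lacks a tail letter",
                token=symbol, position=offset)
        return dict(domain_count=1, tail_class="none",
                    x_lineage=XLineage.NONE, workshop=False, gene_id="")
    m = re.match(r"^(X?)([LSP])(W?)(X?)(\d{0,2})$", rest)
    if not m:
        bad = rest[0] if rest[0] not in "XLSPW" else rest
        raise NameParseError(
            f"invalid tail/gene-number token {rest!r} in symbol {symbol!r}",
            token=bad, position=offset + 2)
    x_pre, tail, w, x_post, gene_id = m.groups()
    if x_pre and x_post:
        raise NameParseError(
            f"'X' marker on both sides of the tail letter in {symbol!r}",
            token=rest, position=offset + 2)
    x_lineage = (XLineage.PRE_TAIL if x_pre
                 else XLineage.POST_TAIL if x_post else XLineage.NONE)
    return dict(domain_count=domain_count, tail_class=tail,
                x_lineage=x_lineage, workshop=bool(w), gene_id=gene_id)


def parse(designation: str) -> AlleleName:
    """Parse a designation string into an :class:`AlleleName`.

    Unknown species prefixes are accepted — the set of valid codes is
    registry data, not grammar.  Legacy pre-standardization names (``3DH``
    hybrids, lab-suffixed strings, slashed compounds) are rejected; those are
    opaque keys for the legacy resolver.

    Raises :class:`NameParseError` naming the offending token and position.
    """
    raw = designation
    s = designation.strip()
    if not s:
        raise NameParseError("empty designation", token="", position=0)
    species = None
    m = _PREFIX_RE.match(s)
    body = s
    offset = 0
    if m:
        species = m.group(1)
        body = s[m.end():]
        offset = m.end()
    elif "-" in s.split("*")[0]:
        tok = s.split("-")[0]
        raise NameParseError(
            f"species prefix {tok!r} is not a four-letter code",
            token=tok, position=0)
    if not body.startswith("KIR"):
        raise NameParseError(
            f"designation must contain the 'KIR' acronym, got {body!r}",
            token=body[:3], position=offset)
    body = body[3:]
    offset += 3

    star = body.find("*")
    symbol_part = body if star < 0 else body[:star]
    sym = _parse_symbol(symbol_part, offset)

    field1 = field2 = field3 = None
    suffix = "none"
    if star >= 0:
        fields_part = body[star + 1:]
        fields_off = offset + star + 1
        if fields_part and fields_part[-1] in SUFFIXES and not fields_part[-1].isdigit():
            suffix = fields_part[-1]
            fields_part = fields_part[:-1]
        elif fields_part and fields_part[-1].isalpha():
            raise NameParseError(
                f"invalid suffix {fields_part[-1]!r} (must be one of N,L,S,C,A,Q)",
                token=fields_part[-1], position=offset + star + len(fields_part))
        pieces = fields_part.split(":")
        if not 1 <= len(pieces) <= 3:
            raise NameParseError(
                f"too many digit fields in {fields_part!r}",
                token=fields_part, position=fields_off)
        if not _FIELD1_RE.match(pieces[0]):
            raise NameParseError(
                f"first digit field {pieces[0]!r} must be exactly 3 digits",
                token=pieces[0], position=fields_off)
        field1 = pieces[0]
        for i, piece in enumerate(pieces[1:], start=2):
            if not _FIELD23_RE.match(piece):
                raise NameParseError(
                    f"digit field {piece!r} (tier {i}) must be exactly 2 digits",
                    token=piece, position=fields_off)
        if len(pieces) > 1:
            field2 = pieces[1]
        if len(pieces) > 2:
            field3 = pieces[2]
        if suffix != "none" and field1 is None:
            raise NameParseError("suffix without an allele number",
                                 token=suffix, position=len(s) - 1)

    name = AlleleName(species_prefix=species, field1=field1, field2=field2,
                      field3=field3, suffix=suffix, raw=raw, **sym)
    problems = name.violations()
    if problems:
        raise NameParseError("; ".join(problems), token=s, position=0)
    return name


def format_name(name: AlleleName) -> str:
    """Render an :class:`AlleleName` canonically; inverse of :func:`parse`.

    Refuses invariant-violating names.  Gene symbols are emitted as plain
    text; italicization is a typesetting concern, out of band here.
    """
    problems = name.violations()
    if problems:
        raise ValueError("cannot format invalid name: " + "; ".join(problems))
    out = []
    if name.species_prefix:
        out.append(name.species_prefix + "-")
    out.append("KIR")
    out.append(name.gene_symbol())
    if name.field1 is not None:
        out.append("*" + name.field1)
        if name.field2 is not None:
            out.append(":" + name.field2)
        if name.field3 is not None:
            out.append(":" + name.field3)
        if name.suffix != "none":
            out.append(name.suffix)
    return "".join(out)


def compare(a: AlleleName, b: AlleleName) -> int:
    """Total order over designations: -1, 0 or 1.

    Species first (lexicographic), then gene symbol (domain count, X marker,
    tail, workshop, numeric gene number), then the digit fields numerically
    with absent sorting before present, then suffix.
    """
    ka, kb = a.sort_key(), b.sort_key()
    return -1 if ka < kb else (0 if ka == kb else 1)
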