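# Methods

## The naming model

A non-human KIR designation encodes, left to right: a four-letter species
code (`Mamu`, `Patr`, `Poab`, `Popy`, `Bota`, and by extension `Mafa`,
`Mane`); the `KIR` acronym; the number of extracellular Ig-like domains
(1–3); `D` for domain; a tail letter — `L` (long, typically inhibitory),
`S` (short, typically activating) or `P` (pseudogene); optionally `W`
("workshop": divergent enough to be a new gene but lacking genomic or
segregation evidence); optionally `X` marking the deeply divergent KIR3DX
lineage; and a gene number.  After `*`, up to three colon-separated digit
fields name the allele: the first (3 digits) separates proteins
(non-synonymous differences), the second (2 digits) synonymous coding
differences, the third (2 digits) intron/UTR-only differences.  A trailing
letter records expression status (`N` null; `L`/`S`/`C`/`A`/`Q` low /
secreted / cytoplasmic / aberrant / questionable).

Structural decisions embodied in the grammar:

- **Zero padding is data.**  Macaque gene numbers are two-digit (`3DL01`),
  ape and cattle numbers unpadded (`3DL1`).  The two-digit macaque series
  was introduced deliberately to break with the old one-digit names, so the
  grammar preserves the printed form and equality is string equality on the
  gene number.  Gene numbers of one or two digits are accepted; longer
  numbers are rejected pending committee guidance.
- **Two `X` positions, never unified.**  Cattle print the lineage marker
  between `D` and the tail letter (`3DXL1`); the macaque X-divergent gene
  prints it after (`3DLX1`).  Both orders occur in the registry and are
  parsed to distinct positions.
- **Degenerate symbols.**  `KIR1D` (one domain, no tail letter) and `KIRDP`
  (pseudogene, no domain digit) are the only legal tail-less/domain-less
  forms.
- **Legacy names are opaque.**  Pre-standardization strings (`KIR3DH1`,
  `Pt-KIR3DL1/2`, `2DL501NK`, lab-suffixed `…-BNB`/`…-JHB` forms) are not
  parseable; they live only as lookup keys in the legacy index.  The `3DH`
  (hybrid/activating) convention is not part of the current syntax.

Ordering is total: species lexicographic, then gene symbol (domain count,
X marker, tail, workshop, numeric gene number), then the digit fields
numerically with absent before present, then suffix.

## The packaged registry

`nhkir/data/genes.tsv` and `alleles.tsv` transcribe the published renaming
tables for the five taxa: 75 gene records and 289 allele records, with
previous designations, accessions, literature keys, and breed for cattle.
Notes on curation:

- The chimpanzee gene table lists 11 rows, but two further genes
  (`Patr-KIR2DS4`, `Patr-KIR3DS2`) carry alleles in the allele table; the
  registry records all 13, matching the stated chimpanzee gene count.
- The cattle prose reports 16 genes while the cattle table prints 17
  distinct gene designations; the registry records the table and flags the
  discrepancy in its metadata rather than resolving it.
- Orangutan is one taxon split over two species codes; combined statistics
  union gene symbols after stripping the prefix (11 genes + 1 pseudogene),
  while per-species counts remain available.
- Accessions are validated by shape only (letters/digits) and are *not*
  unique per allele: one accession legitimately backs two distinct macaque
  alleles.
- Allele numbering gaps (e.g. a missing `*009` in a macaque series) are
  preserved; allocation is always max+1 in deposition order, never
  gap-filling, because withdrawn names leave holes.

## Legacy resolution

Every previous designation — gene-level and allele-level — is indexed under
a normalized key: whitespace-trimmed, case-insensitive, with an optional
species prefix (`Mamu-`, `Pt-`, …) stripped when it directly precedes
`KIR`.  Slash compounds are indexed whole *and* split into parts of at
least three characters (the orangutan tables mix both conventions); lab
suffixes are kept verbatim as stripping them is collision-prone.  A query
returns *all* matching current designations; an accession narrows but can
never enlarge the set; current designations resolve to themselves, making
resolution idempotent.

## Difference tiers

`classify_difference` globally aligns two coding sequences (affine gaps;
match +1, mismatch −1, open −4, extend −1 — conventional nucleotide scores)
and classifies codon-by-codon under the standard genetic code, frame
anchored at cds position 0.  Substitutions inside gapless aligned codons
are synonymous or non-synonymous by translation; any indel or out-of-frame
codon escalates to the non-synonymous tier, since it disrupts the protein.
Flank/intron blocks are compared only when both sequences carry them.
Guard rails:

- aligned identity below the comparability floor (default 0.70) raises a
  "not comparable" error instead of returning a tier — a signal that the
  wrong gene is being compared;
- positions with ambiguity codes are excluded from counts and reported; a
  sequence with more than 1% ambiguous positions is rejected;
- comparisons involving a sequence marked partial are restricted to the
  shared region and flagged `partial_basis` in the report, since how
  partial sequences should be named at the lower tiers is not settled.

## Feature extraction

Domain counting is annotation-driven (the number of D0/D1/D2 exon spans),
never motif-predicted.  When a genomic exon inventory is supplied it
overrides cDNA content: splice variants can drop a domain exon from the
message while the gene retains it, and the gene, not the transcript,
carries the name.  Tail typing has no published boundary, so the default is
operational: long if the annotated cytoplasmic span is ≥ 60 codons *or*
contains an ITIM-like motif (`[ILVS]-x-Y-x-x-[LV]`); both knobs are
configurable and echoed in the rationale trail.  Null-candidate flags: an
in-frame stop before 90% of the annotated codon length (configurable),
a length not divisible by three in a sequence marked complete (frameshift),
or a lost start codon.  These trigger the `N` suffix.  The other expression
suffixes encode measurements no sequence analysis can infer; they are
accepted as curator metadata only.

## Locus assignment and allocation

Windows of 100 nt at 50 nt step slide over the candidate; each window votes
for the gene of its nearest registered allele (by match count within the
window, from one global alignment per allele).  A gene needs a strict
majority (>50%) of windows; exact window ties abstain, and a vote with no
majority raises an explicit "ambiguous recombinant" error — what fraction
constitutes a majority when three or more loci contribute is not settled,
so ties are surfaced, not guessed.

New-gene detection is an identity-threshold proxy (default 0.96) for
phylogenetic divergence, which is out of scope.  The test is applied to the
*maximum* of the best global identity and the mosaic identity (per-window
nearest-neighbour identity, averaged): a recombinant of two registered
genes has depressed global identity to each parent but near-perfect mosaic
identity, and must take the allele path, while a uniformly divergent
sequence fails both and becomes a workshop proposal.  Workshop genes
continue the species' gene-number sequence at the species' digit width —
`W` is a flag, not a namespace.

Tier naming on the allele path: identical over the full shared region →
existing allele (the registry is never touched, so resubmission is
idempotent); same protein, different cds → second-tier name under the
incumbent; same cds, non-coding differences only → third-tier name; else a
new first-tier number.  When an incumbent printed in short form (`*001`) is
extended, it keeps the short form as an alias and its canonical form gains
`:01`; the newcomer takes `:02` — longer names are assigned only when
necessary.  Sequences from other macaque species (`Mafa`, `Mane`) are
assigned against the rhesus registry and emitted with their own prefix.

Submission checks precede everything: full-length (annotated leader through
a stop codon; mandatory for rhesus macaque, waived elsewhere) and
replication evidence (≥2 individuals or ≥2 independent PCR/cloning
experiments).  Failures reject the submission with the failed check named.
Promotion of a workshop gene once genomic or family evidence arrives is a
manual `rename_gene` operation that preserves the old names as previous
designations; nothing triggers it automatically.

## Synthetic data

The generator emulates the anatomy the engine reads — leader (21 codons),
1–3 Ig-domain blocks (100 codons each, cysteine pair at the canonical
offsets), stem (24), TM (21), tail of requested length, stop codon, and
60 nt UTR flanks — with every codon drawn from the sense codons (no
incidental stops).  Divergence between genes is engineered, not sampled:
each gene receives single-nucleotide substitutions at a private, disjoint
set of codons sized so every pair lands on the target identity to within
rounding; the realised pairwise identities sit within ±2% of the request.
Mutation requests (synonymous / non-synonymous / non-coding / stop /
frameshift) are verified constructions, giving closed-loop ground truth for
the classifier.  The RNG is Python's Mersenne Twister seeded explicitly;
identical seeds give byte-identical output.

What the generator does **not** emulate: real substitution-rate structure,
codon usage, recombination hotspots, paralogue-specific conservation, or
sequencing error.  Passing tests therefore demonstrate the engine's logic
under controlled conditions, not its behaviour on every real-world edge
case (e.g. highly diverged true alleles, or chimeras of more than two
loci).

## Problem sizes and determinism

The verification suite uses full-length (3-domain, 84-codon-tail,
1,353 nt) constructs for classification and recombinant checks, and short
(1-domain, 14-codon-tail, 543 nt) constructs for the 50-submission
allocation sequence; sequential tier-1 novelties are built as allelic
variants (three codon changes) so they stay unambiguously within their
gene.  The engine itself contains no randomness: identical inputs and
configuration produce identical decisions, and all synthetic inputs derive
from explicit seeds.

## Known limitations

- New-gene calls rest on an identity threshold, not phylogeny; borderline
  sequences near 0.96 should go to manual review.
- Lineage labels are registry metadata; the engine never infers lineage.
- Human KIR names (five-digit fields) are out of scope, as are haplotype
  inference, accession retrieval, and the database service itself.
- Tail typing of proteins whose cytoplasmic annotation is missing defaults
  to short; supply the `cyt` span for a meaningful call.
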