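# nhkir — nomenclature engine for non-human KIR genes and alleles

Killer-cell immunoglobulin-like receptors (KIR) are NK-cell receptors whose
gene complex is one of the most variable regions of mammalian genomes:
alleles are highly polymorphic, haplotypes differ in gene content, and
recombination constantly shuffles loci.  Before a common nomenclature was
agreed for the non-human species — rhesus macaque (Mamu), chimpanzee
(Patr), the two orangutan species (Popy/Poab) and cattle (Bota) — the same
sequence could circulate under several laboratory names and one legacy
symbol could cover several of today's genes.

`nhkir` implements that naming system as a reusable engine for
immunogeneticists and registry curators:

- **Grammar** — parse, validate, format and order designations such as
  `Mamu-KIR3DL01*019:02`: species prefix, Ig-domain count, cytoplasmic-tail
  class (`L`/`S`/`P`), the `W` workshop flag, the `X` marker of the
  divergent KIR3DX lineage (cattle `3DXL1` vs macaque `3DLX1`), gene
  number, up to three colon-separated digit fields, and expression
  suffixes (`N` null, `L`, `S`, `C`, `A`, `Q`).
- **Registry** — the packaged renaming tables (≈290 designations across the
  five taxa) with previous designations, accessions, references and
  cattle breeds, plus JSON/TSV/FASTA I/O and integrity checking.
- **Legacy resolution** — map any pre-standardization name to all current
  designations, preserving genuine ambiguity (macaque `KIR3DL2` was split
  over two loci) and narrowing by accession when one is supplied.
- **Difference tiers** — classify a novel coding sequence against a
  reference allele as non-synonymous (first digit field), synonymous
  (second field) or intron/UTR-only (third field), codon by codon under
  the standard genetic code over a global alignment.
- **Allocation** — decide existing-allele / new-allele / new-workshop-gene,
  apply the recombinant majority-locus rule by windowed nearest-neighbour
  voting, flag null candidates (`N`), enforce the full-length and
  replication-evidence submission checks, and emit a rationale trail.
- **Synthetic data** — a seeded generator of KIR-like annotated sequences
  (leader, D0/D1/D2 Ig domains with canonical cysteine spacing, stem, TM,
  tail) with controlled mutation classes, so everything is testable
  without downloads.

## Worked example

Decompose a published designation:

```sh
$ nhkir parse 'Mamu-KIR3DL01*019:02' --json
{
 "species_prefix": "Mamu",
 "domain_count": 3,
 "x_lineage": "none",
 "tail_class": "L",
 "workshop": false,
 "gene_id": "01",
 "field1": "019",
 "field2": "02",
 "field3": null,
 "suffix": "none",
 "raw": "Mamu-KIR3DL01*019:02"
}
```

— three Ig domains, long (inhibitory-type) tail, gene number `01`, protein
variant `019`, synonymous variant `02`.

Resolve a legacy name (ambiguity is preserved, never arbitrated):

```sh
$ nhkir resolve KIR3DL2 --species Mamu
Mamu-KIR3DL01 (Mamu, gene)
Mamu-KIR3DL02 (Mamu, gene)
Mamu-KIR3DL02*001 (Mamu, allele)
```

Census a species against the packaged registry:

```sh
$ nhkir stats --species Patr
Patr: 13 genes, 0 pseudogenes, 39 alleles
$ nhkir stats --species Poab --combined-orangutan
Poab: 11 genes, 1 pseudogenes, 25 alleles
```

Name novel sequences from the library:

```python
from nhkir import (SynthSpec, generate_gene_set, mutate, assign_name,
                   Registry, GeneRecord, AlleleRecord, parse)

seqs, _ = generate_gene_set(SynthSpec(seed=7, n_genes=3, divergence=0.90))
reg = Registry()                                 # *001 allele per gene
for i, seq in enumerate(seqs.values(), start=1):
    reg.add_gene(GeneRecord(species="Mamu", symbol=parse(f"Mamu-KIR3DL{i:02d}")))
    reg.add_allele(AlleleRecord(species="Mamu",
                                name=parse(f"Mamu-KIR3DL{i:02d}*001"),
                                cds=seq.cds, flank5=seq.flank5,
                                flank3=seq.flank3,
                                exon_spans=list(seq.exon_spans)))
meta = {"date": "2018-05-01",
        "evidence": [{"kind": "independent_pcr", "label": "A"},
                     {"kind": "independent_pcr", "label": "B"}]}

variant = mutate(seqs["SYN1"], "synonymous", 2, seed=9)
decision = assign_name(variant, reg, "Mamu", meta)
print(decision.status, decision.designation)
# new_tier2 Mamu-KIR3DL01*001:02
print(decision.rationale["incumbent_canonical"])
# Mamu-KIR3DL01*001:01
```

The silent variant extends the incumbent `*001` at the second digit tier:
the newcomer becomes `*001:02` and the incumbent's canonical long form is
`*001:01` (its short printed form remains valid — longer names are assigned
only when necessary).

The same pipeline run on a sequence below the gene-identity threshold for
every registered locus yields a provisional workshop gene
(`new_gene_workshop`, e.g. `Mamu-KIR3DLW04*001`), and a recombinant whose
windows split evenly between two loci raises an explicit
"ambiguous recombinant" error for manual review.

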