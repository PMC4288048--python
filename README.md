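# luxcart

A genome-wide census pipeline for *luxI/luxR*-type quorum-sensing (QS) gene
circuits in annotated bacterial genomes, built for comparative surveys such
as those of the *Sphingomonadaceae* (sphingomonads).

In acyl-homoserine-lactone (AHL) quorum sensing, a LuxI-family synthase
produces the AHL signal and a LuxR-family transcriptional regulator perceives
it. Beyond the canonical *luxI/R* pair, genomes carry *luxR* solos (orphan
regulators with no cognate synthase nearby), *luxI* solos, and convergently
oriented *luxR-luxR-luxI* "double" loci whose downstream neighborhood
(*phyH*–X–*virB1*–*virB2*–*virB3*, topology T) recurs across strains.
`luxcart` detects and classifies all of these from standard annotation
outputs, for microbial genomicists who want the census to be reproducible and
testable rather than assembled by hand.

## What it does

1. **Homolog authentication** (`homolog_detection`) — a two-tier rule:
   a Pfam-domain prefilter (PF00765 autoinducer synthase, PF03472 autoinducer
   binding; per-domain *E* < 1e-5), then an InterPro completeness test.
   Authentic LuxR = {IPR005143, IPR016032, IPR011991, IPR000792};
   authentic LuxI = {IPR001690, IPR018311}. Proper subsets of the LuxR set
   yield `LUXR_LIKE_INCOMPLETE`, with an N-terminal-truncation flag when the
   autoinducer-binding signature is the missing piece.
2. **Arrangement calling** (`circuit_classification`) — groups authentic
   genes per contig into canonical pairs, doubles, and solos under a
   proximity policy (default: ≤ 3 intervening genes and ≤ 5 kb), doubles
   taking precedence; types double neighborhoods against a topology catalog.
3. **Residue profiling** (`residue_analysis`) — global alignment
   (Needleman–Wunsch, BLOSUM62, affine gaps) onto TraR/TraI reference
   numbering; reports conservation or substitutions (e.g. `W57V`, `L182I`)
   at the invariant ligand-binding (W57, Y61, D70, W85) and DNA-binding
   (E178, L182, G188) sites, flagging the PAB-solo hallmark `Y61W`.
4. **Identity matrices** (`identity_matrix`) — SDT-style pairwise percent
   identity, with within-locus vs between-locus summaries for double-LuxR
   partner sets.
5. **Census aggregation** (`summary_reporting`) — per-genome rows and genus
   roll-ups; a packaged fixture transcribes a published 62-genome census for
   exact aggregation tests.
6. **Synthetic genomes** (`synthetic_genomes`) — generates annotated
   multi-contig genome bundles with planted arrangements, decoy regulators
   and truth labels, so the whole pipeline is testable without downloads.

Inputs are per-genome bundles: protein FASTA, GFF3 gene coordinates, and
domain-hit tables (HMMER3 `domtblout` and/or InterProScan 5 TSV).

## Worked example

```python
from luxcart import (SyntheticConfig, PlantedArrangement, generate_bundle,
                     run_genome)

cfg = SyntheticConfig(
    n_contigs=2, n_background_genes=12,
    planted_arrangements=(
        PlantedArrangement("canonical_pair"),
        PlantedArrangement("double_luxR_luxI", "T"),
        PlantedArrangement("luxI_solo"),
    ),
    seed=42,
)
bundle = generate_bundle(cfg)
verdicts, calls, summary = run_genome(bundle.genes, bundle.hits,
                                      "synthetic", "Sphingobium")
for c in calls:
    print(c.contig_id, c.category, c.members, c.strands,
          c.topology_label, c.upstream_intergenic_bp)
print(summary)
```

prints

```
ctg1 canonical_pair ('g0002', 'g0003') ('+', '-') N/A None
ctg2 double_luxR_luxI ('g0008', 'g0009', 'g0010') ('+', '+', '-') T None
ctg2 luxI_solo ('g0023',) ('+',) N/A 5511
GenomeSummary(genome_id='synthetic', genus='Sphingobium', n_canonical=1,
              n_double=1, double_topologies=('T',), n_luxI_solo=1, n_luxR_solo=0)
```

The canonical pair is the planted convergent *luxI*(+)/*luxR*(−) couple; the
double locus carries the full topology-T neighborhood and is labelled `T`;
the *luxI* solo reports 5,511 bp of upstream non-coding region (solos with
long upstream intergenic stretches are the ones unlikely to descend from a
broken pair). Residue profiling on an engineered query with tryptophan at
TraR position 61 reports the substitution `Y61W` and raises the PAB-like
flag.

A command-line interface wraps the same pipeline:

```sh
luxcart simulate --seed 4 --out bundle/
luxcart run --manifest genomes.tsv --out results/
luxcart table3 --out census/
```

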