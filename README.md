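# lectinfam

Genome-wide analysis of plant lectin gene-family evolution: how the 12
lectin families (B_lectin, Lectin_legB, Jacalin, Phloem, Lectin_C,
Chitin_bind_1, Ricin_B_Lectin, Gal_lectin, Gal_binding_Lectin,
Calreticulin, EEA, LysM) expanded in soybean, rice and Arabidopsis, by
which duplication mechanisms, and how the duplicated copies diverged in
stress and tissue expression.

The package is aimed at comparative genomicists studying gene-family
birth-and-death evolution. It consumes the standard artifacts such a study
produces — GFF3 gene models, domain-hit tables, all-vs-all protein
homology in BLAST tabular form, species-labeled gene trees in Newick,
segmental-block lists, TE annotations in BED, and replicated expression
matrices — and implements the full analysis chain as a library plus a
`lectinfam` command-line pipeline. A synthetic-data generator emulates all
of these inputs with known ground truth, so every stage is testable
without any genome download.

## What it computes

**Family classification.** Genes are assigned to the lectin family of
their best-e-value carbohydrate-binding domain hit (e-value cutoff 1.0);
members whose best hit covers < 70% of the domain model are flagged
`partial` (pseudogene-like) and excluded from the evolutionary counts.

**Tandem duplication.** Two same-family genes are tandem partners when
they are ≤ 10 genes apart on the same chromosome and within 100 kb
(Arabidopsis) or 350 kb (soybean, rice), start-to-start. Clusters are
maximal chains of such pairs.

**Segmental duplication.** A gene pair is segmental when the two genes sit
in the paired intervals of a duplicated chromosomal block and share a
family; tandem arrays are collapsed to a single copy first. Blocks may be
supplied or inferred by finding ≥ 2 collinear (or fully reversed)
homologous gene pairs in the 50-kb flanking windows of a candidate pair.

**Ancestral units and birth rate.** Each gene-tree node is mapped onto the
species tree ((soybean, Arabidopsis), rice) by LCA reconciliation; the
number of ancestral units N_anc is the number of speciation nodes mapped
to the root — the minimal count of gene lineages already present in the
most recent common ancestor. The per-lineage birth rate of surviving
copies is

    rate = 100 · (N_extant − N_anc) / N_anc / T    [genes / 100 MY / ancestral gene]

with T = 150 MY for the monocot–dicot split (140–150 MYA). With the
published B-lectin inputs (105/87/38 extant genes over 5 ancestral genes)
this yields 13.3, 10.9 and 4.4 for soybean, rice and Arabidopsis.

**Retrogenes.** Single-exon lectins matching a multi-exon family member at
≥ 70% query coverage and e-value ≤ 1e-8 are retrogene candidates; genomic
flanks are then scanned for target-site duplications (4–20 bp direct
repeats within 100 bp of the insertion) and a 3′ poly(A) tract (≥ 8 bp at
≥ 80% adenine within 200 bp), grading each call's evidence tier.

**TE overlap.** Each gene is classified against MULE/CACTA/hAT/Helitron
annotations within 50-kb windows, most specific relationship first:
gene-within-TE > TE-within-intron > TE-overlapping-exons > TE-in-flank.

**Expression divergence.** A gene is differentially expressed under a
stress contrast when its mean signal changes ≥ 2-fold and a classical
two-sample t-test on the replicates gives p < 0.05. Family summaries use
inclusion-exclusion over the per-contrast regulated sets; a tandem cluster
or segmental pair is *divergent* when any two members disagree in status
under any contrast.

## Worked example

Simulate a three-species dataset with two ancestral genes per family and
run the whole pipeline:

```bash
lectinfam simulate --out demo --seed 11 --n-anc 2
lectinfam run-all --data demo --out demo_out
```

`demo_out/report.txt` then contains, among other sections:

```
== Ancestral units and birth rates ==

B_lectin       soybean      N_extant=41   N_anc=2   T=150 MY rate=13.0 /100MY/ancestral gene
B_lectin       rice         N_extant=29   N_anc=2   T=150 MY rate=9.0 /100MY/ancestral gene
B_lectin       arabidopsis  N_extant=10   N_anc=2   T=150 MY rate=2.7 /100MY/ancestral gene

== Stress regulation (with inclusion-exclusion) ==

rice:
  biotic: 41 (37%)
  abiotic: 67 (60%)
  biotic_and_abiotic: 23 (21%)
  any: 85 (76%)
  union check: |any| = 41 + 67 - 23 = 85
```

Reading the first block: the simulated soybean B-lectin family grew from
2 ancestral genes to 41 surviving copies in 150 MY, a birth rate of
13.0 genes per 100 MY per ancestral gene — the same arithmetic that gives
13.3 for the real soybean family (105 genes from 5 ancestral units). The
stress block shows the regulated-set union computed on the gene sets
themselves, so the inclusion-exclusion identity holds exactly.

The same quantities are available programmatically:

```python
>>> from lectinfam import estimate_birth_rate
>>> estimate_birth_rate(105, 5, 150).rate_rounded
13.3
```

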