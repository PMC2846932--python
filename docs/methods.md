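# Methods

This note documents the models, conventions and design decisions behind
`lectinfam`, in the order the pipeline runs them, followed by an account
of what the synthetic-data generator does and does not emulate.

## Coordinates and gene ranks

All internal coordinates are 0-based half-open; GFF3 (1-based inclusive)
converts at the read/write boundary, BED passes through. One gene model is
kept per locus — the mRNA with the greatest total exon length (ties: more
exons, then transcript id) — because the analysis treats one protein per
gene. Gene *ranks* are per-chromosome ordinals assigned after sorting by
start (ties: end, then gene id); the rank difference between two genes is
the "genes apart" distance used by tandem clustering. The deterministic
tie order makes clustering reproducible under input shuffling. Ranks count
every gene present in the annotation, protein-coding or not; if an
annotation mixes feature classes the caller should filter before ranking.

## Family classification

Families are defined by one domain model each. The catalog maps domain
model names to the 12 families; the Phloem and EEA (Euonymus-lectin, EUL
domain) families have no standard profile accession, so the catalog names
their custom profiles `PHLOEM_CUSTOM` and `EUL_CUSTOM`. Domain hits with
e-value > 1.0 are dropped; each gene takes the family of its best
surviving lectin hit. Multiple hits of one domain in a gene (hololectins)
collapse to a single assignment; unrelated domains (kinase, F-box,
glycoside hydrolases, …) are recorded but do not influence the call. A
gene hitting two distinct lectin families — not a configuration the data
model expects — is assigned by best e-value with an explicit warning,
never dropped silently.

Completeness is a reproducible surrogate for manual curation of
partial-domain members: an assignment is `partial` when the best hit
covers < 70% of the domain model (inclusive bound: exactly 70% is
complete). Partial members are excluded from the evolutionary analyses by
default, since sequences lacking the sugar-binding region behave as
pseudogenes. The threshold is configurable; 0.7 is a judgement call, not
a published rule.

## Tandem clustering

The pairwise predicate — same family, same chromosome, rank gap ≤ 10,
start-to-start distance ≤ 100 kb (compact genomes) or 350 kb
(soybean/rice) — is applied between rank-adjacent family members and
chained transitively. Applying the base-pair cap per adjacent pair rather
than to the whole cluster is the only reading under which long arrays
(e.g. a 19-gene array) remain single clusters. Because both the rank gap
and the start distance are monotone along the sorted order, chaining
adjacent members is provably identical to the transitive closure of the
predicate over all pairs, which the tests verify against an independent
union-find closure. Start-to-start distance is used because it is
unambiguous under nested or overlapping loci. Singletons are not
clusters; clusters are disjoint by construction.

## Segmental duplication

Tandem arrays are collapsed to their lowest-rank member before block
matching, so an array counts as one gene copy. A representative pair is
segmental when the two representatives lie in the paired intervals of a
block and share a family; a representative is "in" an interval when *any
member of its array* is (the collapsed array is located wherever its
members sit — strict representative-only containment would miss a block
whenever the array's first-rank member happens to fall outside it). All
members of a matched array inherit segmental status, since the analysis
counts genes, not representatives.

Flank-based block inference seeds on a candidate gene pair: both loci are
extended by 50 kb on each side, and homologous gene pairs linking the two
windows are collected (greedy best-partner per gene, scanning window A in
positional order). The block is accepted when, beyond the seed pair
itself, at least `min_extra_anchors = 2` anchors form a consistent
relative order — operationalized as the longest strictly increasing or
strictly decreasing subsequence of partner positions covering that many
anchors. Overlapping windows on one chromosome ("self-overlap") return no
block. The anchor count is configurable; two extra anchors is the weakest
evidence worth calling collinearity.

Expansion classes partition each family: `tandem` (cluster only),
`segmental` (block only), `both`, `other`. Percentages are integer-rounded
(halves away from zero) against family totals.

## Ancestral units and birth rates

Gene trees are species-labeled via gene-id prefix rules (`Glyma` →
soybean, `LOC_Os` → rice, `AT` → Arabidopsis by default). Trees read as
unrooted are midpoint-rooted (outgroup rooting was considered but the
sources of trees rarely carry a reliable outgroup); multifurcations are
resolved into a deterministic caterpillar with children ordered by
minimal leaf label. Resolution can merge same-mapping nodes into nested
duplications but can never create a new root-mapped speciation node, so
it can only lower the count — consistent with reporting it as a lower
bound.

Counting follows LCA reconciliation: each node maps to the lowest
species-tree node containing all species below it; a node whose mapping
equals a child's mapping is a duplication. For a species subset, the gene
tree is pruned to that subset first, and N_anc is the number of
*speciation* nodes mapping to the root of the restricted species tree.
This is the parsimony-minimal, loss-blind count — a family that lost all
copies of an ancestral lineage in one species undercounts, hence "at
least N units". A tree whose surviving leaves all come from one species
contributes zero units. The implementation is checked exhaustively
against an independent set-arithmetic oracle on all ~47 000 distinct
species-labeled rooted tree shapes with ≤ 8 leaves.

The birth rate of surviving copies is
`100 · (N_extant − N_anc) / N_anc / T` genes per 100 MY per ancestral
gene. T defaults to 150 MY, the upper end of the 140–150 MYA
monocot–dicot divergence window, which reproduces the published B-lectin
rates; it is configurable within that window. Rates are reported to one
decimal. N_anc = 0 is an error (rate undefined for a family absent from
the ancestor), not a zero.

## Retrogene detection

Candidates are single-exon lectins with a protein-level match to a
multi-exon lectin at ≥ 70% query coverage and e-value ≤ 1e-8; the
best-e-value qualifying subject is designated the parent (ties broken by
subject id for order-independence). Coverage uses a protein-length
sidecar because BLAST tabular output lacks query lengths.

Hallmark scans operate on strand-oriented flanks (for minus-strand genes
the flanks are reverse-complemented and swapped, so poly(A) is always
sought downstream on the coding strand):

- **TSD**: longest exact direct repeat of 4–20 bp between the last 100 bp
  of the upstream flank and the first 100 bp of the downstream flank;
  ties by total distance to the insertion boundaries, then by proximity
  to the upstream boundary. A mismatch allowance is available but
  defaults to exact.
- **poly(A)**: the substring of length ≥ 8 with adenine fraction ≥ 0.8
  carrying the most adenines (ties: higher purity, then earliest start).
  Maximizing adenine count rather than raw length prevents a pure run
  from losing to a longer dilution of the same adenines.

Both scanners are verified against exhaustive substring enumeration.
Numeric defaults are stated choices — the hallmarks were originally
curated by eye — and are configurable. A caveat the defaults imply: two
random 100-bp windows almost surely share some exact 4-mer, so a
minimum-length-4 TSD on its own is weak evidence; calls are therefore
tiered (`homology_only`, `+polyA`, `+TSD`, `+both`) rather than filtered,
and homology-only calls are retained because hallmarks erode by
substitution and indel over time. Raising `tsd_min_len` is the stringency
knob. Retro-then-tandem expansions are reported by intersecting calls
with tandem clusters.

## TE overlap

Each gene is classified against all elements within its 50-kb windows,
taking the most specific relationship: gene fully inside an element >
element fully inside an intron > element overlapping exons > element in
the flank windows > none. The precedence order is a design choice
(most-specific-first); equal-priority ties go to the left-most element so
calls are annotation-order-independent.

## Expression analysis

"Student's t-test" is read as the classical equal-variance two-sample
two-sided test on the replicate signals (Welch behind a flag). The fold
change is `(mean_stress + c) / (mean_control + c)` with pseudocount
c = 1.0 on the normalized scale, preventing division by zero. A gene is
`up` when fold ≥ 2 and p < 0.05, `down` when fold ≤ 0.5 and p < 0.05
(both bounds inclusive). No multiple-testing correction is applied by
default — the rule is reported per contrast as-is — with
Benjamini-Hochberg behind a flag. Tag-count platforms are normalized to
tags-per-million before the same rule; a contrast without ≥ 2 replicates
per side gets a fold-only call flagged `untested` rather than a
fabricated p-value.

Family stress summaries are computed on the regulated gene sets
themselves, so every reported union satisfies
|A ∪ B| = |A| + |B| − |A ∩ B| identically. Tissue specificity — stated
qualitatively in the field as preferential expression in one or two
tissues — is operationalized as: mean signal > θ = 5.0 in 1–2 tissues
*and* the top two tissues carrying ≥ 90% of the gene's total signal.
A cluster or block pair is expression-divergent when any two members with
data disagree in status under any contrast; members without expression
data are excluded and units with fewer than two covered members are
reported as `no_data` rather than counted in the denominator.

Known limitation: at n = 3 replicates with 20% multiplicative replicate
noise, the joint power of the 2-fold gate and the t-test caps the recall
of fold-2.5 effects near 0.85 even at high signal — the t-test alone
passes ~93% and the fold gate ~91% of such genes. The acceptance script
measures this recall (`de_recall_planted_fold_2p5`) rather than assuming
it; recovering smaller effects at this design requires more replicates,
not different thresholds.

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis assumes,
with a ground-truth manifest tying every emitted gene to its family,
mechanism, parent, planted hallmarks, TE relationship and expression
labels.

**Family evolution** is a pure-birth process: each of N_anc ancestral
genes speciates into one base copy per lineage, and each lineage adds a
Poisson(r·T/100) number of new copies per ancestral gene, attached to a
uniformly chosen existing copy. Expected extant count is
N_anc·(1 + r·T/100), which the surviving-copy rate estimator inverts
exactly in expectation. No loss is simulated by default, so the true
root-era lineage count equals N_anc and the ancestral-unit counter has an
exact truth; with losses the counter's value is a lower bound by design.
Default rates (13.3/10.9/4.4 per lineage) and ancestral sizes (5/4/2 for
the three simulated families) mirror the published B-lectin lineage rates
and root counts. Each duplication is tagged tandem/segmental/
retro/dispersed from a configurable mix (0.45/0.30/0.05/0.20 by default,
echoing the reported mechanism shares); retrogenes draw their parent from
non-retro copies so every retro parent is spliced (multi-exon).

**Placement** inserts tandem copies within ≤ 2 filler genes of their
parent (inside both distance caps by construction); segmental events copy
a window of two neighbouring fillers on each side of the donor to another
chromosome, recording the true block intervals and the filler anchor
pairs; retro and dispersed copies land uniformly — but *away from
same-family genes*, with an exclusion radius of 18 gene slots, because a
"dispersed" copy that happened to land next to a relative would satisfy
the tandem criterion and make the mechanism truth labels self-
contradictory. Filler density auto-scales to the largest family so the
exclusion zones always fit; the emulated genomes are therefore sparse in
lectins relative to all genes, as real plant genomes are (hundreds of
lectins among tens of thousands of genes). Genes are ~1–2.6 kb with
1.5–4 kb intergenic gaps, multi-exon genes carry 400-bp introns, and
chromosomes get 60-kb margins so 50-kb flank windows never clip.

**Sequences** are uniform random nucleotides; realism is limited to the
planted retro hallmarks (an identical direct repeat flanking the
insertion, a poly(A) run appended downstream, optional per-base erosion).
**Homology tables** are fabricated from true paralogy rather than
alignment: true child→parent pairs and segmental anchor pairs get
coverage ~ U(0.75, 1) and e-value 10^−U(10, 60); decoy rows alternate
failing the coverage and the e-value filter, so the 70%/1e-8 filter
separates truth from decoys by construction. **TE annotations** plant one
element per well-separated target gene realizing each overlap class, plus
far elements beyond every window. **Expression** draws log-normal
baselines (log-mean 3, log-sd 1 — signal medians in the tens, matching
processed microarray scales), scales DE genes by a fold from {2, 4, 8}
(up or down), applies multiplicative Gaussian replicate noise at CV 0.2
with n = 3, and zeroes tissue-specific genes outside 1–2 of 6 tissues.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: sequence evolution (no
substitution model, so homology detection is never stressed by
divergence), gene loss and pseudogenization dynamics, annotation errors,
probe-level microarray effects, unbalanced replicate designs, and
correlated expression between neighbouring genes. All randomness flows
from a single seed; identical seeds give byte-identical datasets.

## Problem sizes

The test suite and the acceptance script run the full study conditions at
desk scale: three species, three families (ancestral sizes 5/4/2) at the
published B-lectin lineage rates for mechanism and retrogene recovery
(~500 lectin genes per run); N_anc = 50 with r = 10 for birth-rate
recovery; 500 genes × 5 contrasts for expression recovery; exhaustive
enumeration of all ≤ 8-leaf species-labeled gene trees (47 063 shapes)
for the reconciliation oracle; 100 random 100-gene placements for the
clustering oracle. A complete run of the acceptance script takes under a
minute on one CPU.
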