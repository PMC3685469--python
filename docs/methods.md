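# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Motif census

A motif C-x(i)-C-x(j)-C-x(k)-C is matched by a regular-expression lookahead
so that overlapping occurrences are all reported; positions are 1-based.
The four fixed positions match only cysteine; spacer positions match any
residue, including the ambiguity code X (X never matches a fixed position).
Characters outside the 20 IUPAC amino acids plus X are an input error that
names the offending record. A protein with several occurrences of one
pattern counts once toward that pattern's protein count, matching the
"number of proteins containing the motif" semantics; the per-genome
proportion divides by all proteins in the genome file. Duplicate protein
ids within one genome are rejected.

The general pattern is the ferredoxin [4Fe-4S] spacing (2, 2, 3). The four
variant spacings shipped as defaults — (2,2,2), (2,3,3), (3,2,3), (2,2,4) —
are deliberate placeholders: the set of biologically attested alternative
spacings is not settled, so the variants are fully configurable and the
defaults should be treated as examples, not as a curated catalogue.

Marker-complex flagging (HdrABC, QmoABC) defaults to the lenient reading: a
taxon is flagged when any genome in it has a passing hit to any subunit of
either complex. A strict mode (`strict=True`) instead requires some single
genome to carry every subunit of at least one complex.

## Pathway presence calling

Hits arrive in the 12-column tabular layout (qseqid sseqid pident length
mismatch gapopen qstart qend sstart send evalue bitscore); subject ids of
the form `genome|protein` carry the genome assignment. Filtering keeps
hits with E-value ≤ 10⁻¹⁰ **and** identity ≥ 25%, both bounds inclusive
("E better than 10⁻¹⁰" is read as ≤; both are overridable). Filtering is
idempotent and order-preserving.

A pathway is an ordered list of gene *slots*; interchangeable genes
(ubiD/ubiX, HemF/HemN, HemY/HemG, UbiE/MenG) share a slot, so completeness
= satisfied slots / total slots never double-counts a slash pair.
Completeness fractions are compared to the 0.70 threshold exactly (no
rounding): 3/4 = 0.75 is present, 5/8 = 0.625 is not. The one exception is
haem d1: where a genome passes the alternative-haem threshold *and* has a
passing hit to cd1 nitrite reductase (the only haem-d1 enzyme), the call is
reported absent with `d1_reassigned=True`, since those hits are better
explained by d1 biosynthesis. Per-taxon aggregation is the proportion of a
taxon's genomes called present; taxa without genomes are dropped with a
warning rather than silently.

Gene-name matching is exact and case-sensitive — `ubiE` (ubiquinone) and
`UbiE` (menaquinone methyltransferase slot) are distinct queries.

## Gene-family stringency grid

Pairwise identity is computed from a Needleman–Wunsch global alignment
(BLOSUM62, affine gaps −11 open / −1 extend, via Biopython's
PairwiseAligner). The identity denominator is the number of alignment
columns after trimming terminal-gap columns from both ends; an alternative
shorter-sequence denominator is available (`denominator="shorter"`).
Because co-optimal global alignments need not be unique, the two sequences
are put in canonical order before aligning, which makes the function
exactly symmetric by construction.

The "roughly 30% identical" criterion is enforced as a hard inclusive
cutoff applied to **all** member pairs: a family survives only if every
pair is ≥ 30% identical (single-member families pass trivially). The
all-pairs cost is O(n²) alignments per family, so families above a
configurable `max_family_size` raise an error instead of being silently
subsampled. Group presence counts distinct higher taxa, not genomes: a
group is hit when at least one member genome belongs to it. The stringency
grid cell (a, b) counts families present in ≥ a archaebacterial and ≥ b
eubacterial groups; the grid is asserted monotone non-decreasing along both
axes on every construction, and per-cell family-id lists are retained for
annotation reports.

## Taxon sampling

Marker distances are 1 − identity/100 from the same global-alignment
identity. Each domain is clustered independently (guaranteeing an exactly
balanced sample), with average linkage by default (single and complete are
options); the dendrogram is cut into k clusters and each cluster
contributes its **medoid** — the member minimizing summed within-cluster
distance, ties broken by lexicographically smallest genome id. Genomes are
sorted before clustering, so the selection is independent of input order.
The linkage and the medoid rule are this package's own deterministic
choices; hierarchical-clustering-based selection admits many variants and
none is canonical.

## Trees and node frequencies

Distances: p = differing sites / sites where neither row is gapped
(pairwise deletion); d = −ln(1 − p), capped at d_max (default 10) as p → 1;
a pair with no comparable sites is an error naming the pair.

Neighbor joining follows the standard Q-criterion agglomeration with two
determinism guarantees: ties in Q are resolved by the smallest (row,
column) index pair, and negative limb estimates are clamped to zero. Three
taxa return the unique star resolution. On additive matrices NJ is exact:
the generating topology is recovered and all path distances are reproduced
to floating-point accuracy. NJ was chosen for determinism and speed; the
support statistic is method-agnostic, and externally built Newick trees are
accepted wherever trees are consumed.

Trees are unrooted throughout (rooted input is treated as unrooted on
read). A bipartition is canonicalized as the leaf subset *not* containing
the lexicographically smallest taxon id, making the two sides of an edge
hash identically. Node frequency is exact bipartition identity over an
identical leaf set — partial-taxon compatibility matching is out of scope.
The annotated Newick writer places the frequency, 4 decimal places, as the
internal-node label, and round-trips through the package's reader.

## The synthetic generator

The generator emulates the *shape* of the real comparative-genomics inputs
with known truth. Defaults follow the study-scale constants where the
analysis states them — 11 archaebacterial and 30 eubacterial groups, 48
universal genes — and desk-scale choices elsewhere.

- **Taxonomy/species tree.** Genomes are grouped; groups join randomly
  within each domain; the two domains connect through a single inter-domain
  edge (`interdomain_branch`, default 1.0 expected substitutions/site).
  Within-domain branch lengths are uniform on (0.05, 0.15): long enough
  that 2000-site genes carry recoverable signal — the regime where every
  gene recovers the deep split, matching the empirical pattern the support
  analysis measures — and short enough to stay far from saturation.
- **Discordance.** With probability p a gene receives exactly one NNI at a
  uniformly chosen internal edge, the inter-domain edge excluded by default
  (`exclude_interdomain`). The destroyed bipartition is recorded. This
  makes each eligible node's expected gene-tree frequency analytic,
  1 − p / n_eligible, at the price of realism: real discordance (transfer,
  incomplete lineage sorting, reconstruction error) is not limited to one
  rearrangement per gene.
- **Sequences.** Site-independent Poisson-style process: root residues
  uniform over 20 amino acids with P(C) = `background_c_freq` (default
  0.014, an empirical proteome cysteine frequency); per branch of length t
  each site substitutes with probability 1 − exp(−t), uniformly over the
  other 19 residues. No exchangeability matrix, rate heterogeneity or
  indels — controllability, not realism, is the goal.
- **Proteomes.** Background proteins drawn residue-wise; with probability
  `motif_rate` a protein receives exactly one planted motif, overwriting a
  window (lengths stay fixed) with spacers drawn from the 19 non-cysteine
  residues so no nested match can arise. With `background_c_freq = 0` the
  scanner's detections equal the plantings exactly; otherwise plantings are
  a subset of detections.
- **Families.** Per family, a presence probability applies to each group;
  one member genome per present group. Members sit ~5% diverged from a
  family ancestor (all pairs ≥ ~90% identical, far above the 30% filter);
  a configurable fraction of multi-member families carries one member
  randomized at 90% of positions, driving at least one pair far below the
  filter. The intended retained set is recorded. This family model is a
  stand-in with controlled properties, not a reconstruction of any real
  clustering procedure.
- **Hit tables.** For each genome × pathway the truth completeness (given,
  or drawn uniformly over the slot grid) is realized exactly: passing hits
  (E ∈ [10⁻⁴⁰, 10⁻¹⁵], identity ∈ [30, 95]) for exactly that many slots,
  plus decoys each failing exactly one filter, plus seeded cd1 and
  marker-complex placements.
- **Determinism.** One seed; each stage draws from its own SeedSequence
  child (stage order: taxonomy, genes, proteomes, families, hits), so
  stages are reproducible independently and full runs are byte-identical.

What passing tests on this generator do **not** show: robustness to real
alignment error, indels, compositional bias, rate variation,
coalescent-style discordance, paralogy in hit tables, or families whose
identity structure straddles the 30% cutoff. The generator's margins are
deliberately wide so that round-trip tests isolate bookkeeping correctness
from statistical noise.

## Problem sizes

The shipped end-to-end analyses run at 40 taxa (20 per domain), 48 genes of
2000 sites, 10,000 proteins for the census round trip, 1000 families for
the grid recount and 100 random additive matrices for the NJ oracle —
sizes chosen so the whole suite and the acceptance script each complete in
well under a minute on one CPU while keeping binomial checks adequately
powered.

## Known limitations

- The variant motif spacings are placeholders (see above).
- Identity is alignment-based; families of repetitive or multi-domain
  proteins can score differently under other identity conventions.
- NJ on Poisson distances is a deliberately simple tree method; published
  deep phylogenies typically use ML with empirical matrices. The support
  statistic accepts external trees for exactly this reason.
- The 70% completeness rule treats all slots equally; no weighting by
  enzymatic essentiality is attempted.
- Sulfolobales-type benzothiophene quinone analogues have no defined
  pathway here and simply score as absent for all defined pathways.
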