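# Methods

`genefam` re-implements, at desk scale, the standard analysis pipeline used to
characterize a plant gene family in an allopolyploid genome — here the MAP
kinase kinase kinase (MAPKKK) family of bread wheat, whose three subfamilies
(MEKK, ZIK, Raf) are diagnosed by short degenerate signature motifs in the
kinase activation segment. This note records the models, conventions and
numerical choices behind each stage, what the synthetic-data generators do and
do not emulate, and the limitations that follow.

## The packaged family table

The 155-member family inventory (gene ids, subfamily assignments, protein
length, EST support, pI, Mw, predicted subcellular compartments, genomic
location) ships as `data/family_table.tsv`. The published table's numeric
columns were run together in the available text; the transcription was
disambiguated with a constraint parser (length 149–1335 aa, EST 0–119, pI
4.55–9.33 with 1–2 printed decimals, Mw 16.5–146.1 kDa with 1 decimal, and a
mass-per-residue plausibility ratio used only to break ties) and cross-checked
against every published aggregate: subfamily counts 29/11/115, sub-genome
counts 58/45/52, per-group counts 13/31/32/16/32/15/16, chromosome extremes
(3A = 15, 7B = 1), the zero-EST gene set, and the three highest EST counts
(119/95/55). One row (TaRaf3) prints its pI without decimals; it is stored as
the integer printed. Subcellular labels are kept as the full multi-compartment
lists; no single-compartment reduction is attempted because the counting
convention behind published per-compartment totals is not recoverable.

## Locus notation and chromosomal distributions

Loci are written either chromosome-anchored (`5D:146319049-146323269`) or
scaffold-only (`scaffold_2BL_6949321:447-1269`), where the scaffold name
encodes the chromosome arm the scaffold was assigned to. Scaffold-only genes
count toward their encoded chromosome, matching how published per-chromosome
totals treat them. Coordinates are 1-based inclusive as printed; BED export
converts to 0-based half-open and is round-trip tested. A string with no
recognizable chromosome token parses to an explicit *unplaced* locus rather
than an error, so distributions can report placed and unplaced genes
separately.

## Signature-motif grammar

Patterns are positional: a fixed residue, an alternative set `(A/B/...)`, or
the wildcard `X` (any residue). A sequence letter `X` (unknown residue) fails
every fixed position and alternative set and is matched only by pattern
wildcards — conservative classification. The shipped signatures are

| subfamily | pattern            | length | rank |
|-----------|--------------------|--------|------|
| ZIK       | `GTPEFMAPE(L/V)Y`  | 11     | 0    |
| MEKK      | `G(T/S)PX(W/Y/F)MAPEV` | 10 | 1    |
| Raf       | `GTXX(W/Y)MAPE`    | 9      | 2    |

The Raf signature is the most degenerate, and it is *nested* inside many
MEKK/ZIK instantiations (e.g. `GTPAWMAPEV` contains a Raf match). Classification
therefore scans all offsets for all motifs and resolves multi-subfamily matches
by specificity precedence (ZIK before MEKK before Raf), flagging the call as
ambiguous instead of silently discarding the information. At the whole-string
level the three signatures are mutually exclusive (their instantiations have
distinct lengths and incompatible fixed positions), and the rank-based
classifier provably recovers the generating subfamily for every exhaustive
expansion — both facts are asserted in the test suite. Multiple occurrences of
a motif report the leftmost match.

## Profile screen

The genome-scale BLASTP + profile-HMM candidate screen is replaced by an
ungapped position-specific scoring matrix: per-column log2 odds
`log2(((c_r + pc·b_r)/(n + pc))/b_r)` with Laplace-style background-weighted
pseudocount `pc = 1.0` (small seed sets) and uniform background by default.
Columns with > 50 % gaps are dropped. Candidates are scored with a sliding
window of model length (short candidates scored over their full length and
flagged), and additionally filtered by best global-alignment identity against
the seed set at 50 % — identity computed over aligned non-gap columns, the
same convention the duplication caller uses. There are no E-values; score
thresholds are calibrated on an empirical decoy null (e.g. the 99th percentile
of best-window scores over random sequences), which the planted-domain
recovery test exercises (sensitivity ≥ 0.95, decoy pass rate ≤ 0.01).

## Alignment, duplication and homoeolog calling

Global alignment is Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner` (BLOSUM62, gap open 10, extend 0.5 — common practice
defaults, config-exposed; the first reported optimum is taken, which is
deterministic). Scores are verified against an exhaustive three-state dynamic
program on short peptides. Identity is computed over aligned non-gap-pair
columns; coverage over the longer sequence's length.

Duplication pairs satisfy: (a) coverage > 80 % of the longer gene,
(b) identity > 80 %, and (c) tightly linked same-chromosome copies collapse to
one event. "Tightly linked" is operationalized as gene starts within a
`tandem_window` of 100 kb (config-exposed; the source analyses leave the
window unstated), with transitive clustering and the highest-identity pair
retained as the representative event. Proteins, not CDS, are aligned, because
the family inventory itself is defined on protein sequence.

Homoeolog groups are connected components of qualifying pairs restricted to
same homoeologous group and different sub-genomes: components spanning A, B
and D are triads, two sub-genomes are pairs; a component with two genes from
one sub-genome is retained but flagged for review.

## Protein properties

Molecular weight is the sum of average residue masses plus one water
(`X` contributes the mean residue mass and is flagged). The isoelectric point
solves `Z(pH) = 0` with Henderson–Hasselbalch terms for the N-terminus, K, R,
H (positive) and C-terminus, D, E, C, Y (negative). `Z` is strictly decreasing
in pH, so the bisection root on [0, 14] is unique; iteration stops at
`|Z| < 1e-4` and results are reported to 2 decimals. Two pKa sets ship:
`bjellqvist` (default; includes Bjellqvist's residue-specific terminal pKas,
and matches ProtParam's charge model to 1e-6) and `emboss`. Published
per-protein pI values can reflect either set, so third-party tables are only
approximately reproducible by construction; the packaged family table's pI
column is transcribed, not recomputed.

## Phylogeny

Distances are p-distances (proportion of differing residues over
pairwise-comparable columns; gap-containing columns dropped per pair, or
globally with `gap_policy="complete"`), with an optional Poisson correction.
Trees are built with Saitou–Nei neighbor joining: standard Q-matrix, ties
broken toward the lowest index pair, negative branch lengths clamped to zero
and counted (the convention of mainstream phylogeny GUIs). Bootstrap resamples
alignment columns with replacement under a recorded seed; support for each
internal split of the full-data tree is the percentage of replicate trees
containing it. NJ is validated against additivity (path-length matrices
reproduce additive inputs to 1e-9), a least-squares topology-enumeration
oracle on quartets, and scikit-bio's independent implementation. The module
consumes a ready alignment; building MSAs is out of scope. The default
replicate count is 100 at desk scale; 1000 is available by flag.

## Gene structure

Exon intervals are grouped by `Parent` from GFF3 (via gffutils); introns are
inter-exon gaps. Abutting exons produce zero-length introns that are counted
but flagged — annotation artifacts should stay visible. Intron phase is the
cumulative coding length 5′ of the intron modulo 3, walking CDS segments in
transcription order (reverse genomic order on the minus strand).

## Promoter scanning

The proximal promoter is the 2 kb upstream of the gene start (truncated at
contig edges with a flag; minus-strand genes use the reverse complement of the
downstream flank). Elements are IUPAC consensi scanned on both strands — a
minus-strand hit is an occurrence of the element's reverse complement, with
offsets always in region coordinates. All overlapping matches are reported;
counting conventions (instances vs element types per promoter) belong to the
user. The shipped element table (ABRE, DRE/CRT, GARE, ERE, LTR, MBS, TC-rich,
W-box, core elements) is a small curated example, not a database; published
per-category element counts depend on a proprietary database and are not
reproduced.

## Expression analysis

All transforms operate on FPKM (genes × samples) with `log10(FPKM + 1)` as
the display/testing scale. "Expressed" defaults to FPKM ≥ 1 (config-exposed;
the underlying studies leave it unstated). Tissue-specific = expressed in
exactly one organ. Stress calls per timepoint compare treatment vs control:
fold change on means with a pseudo-FPKM of 0.1 against division by zero,
cutoff 2; with replicates, Welch's t-test on `log10(FPKM + 1)` with
Benjamini–Hochberg correction across the gene set, both p and q gated at
0.05. This substitutes a simple replicate-level test for the original
assembly-pipeline statistics, so published per-gene DE lists are not
reproduction targets. Genes below the expressed threshold in control but
expressed and induced under treatment are called stress-specific. The salt
time course is called separately at each timepoint; no time pooling.
Hierarchical clustering is average linkage on Euclidean distances of
log-transformed rows, with rows pre-sorted by gene id so equal-distance
merges are deterministic.

qPCR quantification is the comparative-Ct method: ΔCt = Ct_target − Ct_ref
per well, ΔΔCt = mean ΔCt(treatment) − mean ΔCt(control) over replicates,
relative expression `2^−ΔΔCt`, replicate SDs propagated in quadrature.
Swapping the condition labels inverts the fold exactly.

## Network projection and enrichment

Family genes map to model-organism orthologs (many-to-one allowed); each
interaction edge incident to a mapped ortholog projects to one
(family gene, partner) pair, de-duplicated. The headline statistic is the
mean projected pair count per mapped gene, reported to one decimal. GO
enrichment is the upper-tail hypergeometric test per term with BH correction
(default significance q < 0.01), validated against exact
binomial-coefficient enumeration on small universes. No interaction database
is bundled; the module consumes any edge list.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a seeded spec and produce truth tables
sufficient to score every caller without re-reading the data.

* **Proteins** — family members share a kinase-like core block with one
  signature instantiation planted at a known offset; decoys are residue-i.i.d.
  sequences resampled until motif-free. Real kinase domains have far more
  positional structure; passing recovery tests shows the grammar and scanner
  work, not that the signatures are uniquely diagnostic in real proteomes.
* **Genome layout** — 11 homoeolog triads (the published triad count), 24
  two-subgenome pairs, 2 tandem arrays of 3 copies, 8 singletons on a
  21-chromosome A/B/D layout. Within-group members derive from a shared
  ancestor mutated to an identity drawn from 85–98 % using BLOSUM62-frequent
  exchanges; unrelated units are independent random sequences (expected
  identity ≪ 40 %). Because the identity gap between related and unrelated
  units is wide, exact recovery is the designed outcome; the test
  demonstrates correctness of the calling logic, not real-data robustness at
  the 80 % boundary.
* **Expression** — five organs and a control/salt time course (0–48 h, 3
  replicates). Noise is the continuous Gamma component of a negative-binomial
  model applied to FPKM directly: variance = dispersion × mean², dispersion
  0.1, and the dispersion → 0 limit returns the mean exactly. This
  deliberately omits the count layer of sequencing noise. Planted structure:
  per-organ specific genes 1/6/1/6/3, 16 silent genes, 60 up-regulated genes
  under stress (the study describes most family genes as stress-induced), 4
  down-regulated and 4 stress-specific genes, effects at log2FC = 3 applied
  after 0 h.
* **qPCR** — reference wells at Ct ≈ 20, targets at Ct ≈ 26, replicate SD
  0.15 cycles; treatment target wells shifted by −log2(fold). Round-trip
  recovery is within replicate noise (observed max |log2 error| ≈ 0.3).
* **Network** — 18 mapped genes with 509 distinct projected pairs (the
  published projection size), distributed over per-gene partner sets.

## Problem sizes and determinism

Default test and acceptance problem sizes (95 layout genes of 250 aa,
155-gene expression panels, 100–200-sequence screens, 100 bootstrap
replicates) keep the full suite at well under a minute of alignment work
while leaving every threshold meaningfully exercised. All randomness flows
through `numpy.random.default_rng` seeded from the spec or CLI seed; repeat
runs are bit-identical.

## Known limitations

* The pI/Mw, screen and DE statistics are documented substitutions for web
  tools and assembly pipelines whose exact parameters are unpublished;
  per-gene numeric agreement with third-party outputs is not an objective.
* The duplication caller's tandem window and the expressed-FPKM threshold are
  conventions, not published values; both are config-exposed.
* Homoeolog grouping assumes the locus assignments are correct; misplaced
  scaffolds would silently move genes between groups.
* The motif grammar has no position weighting; borderline motif variants
  score identically to canonical ones or not at all.
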