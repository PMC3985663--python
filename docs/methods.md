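# Methods

## The RIFT-calling model

A retrotransposon-initiated fusion transcript (RIFT) is called from an
exon-array probe intensity matrix in four steps.

1. **Threshold.** For each sample, the high-expression threshold is
   `mean + sd_multiplier × SD` over *all* probes of that sample, with the
   sample standard deviation (n−1 denominator) and `sd_multiplier = 1` by
   default. The scope is per-sample rather than pooled across samples: the
   published rule couples the mean+1SD definition to an approximate
   absolute value (~7 on log2-RMA arrays), which only makes sense if each
   array contributes its own mean and spread. Comparison is strictly
   greater-than: a probe exactly at the threshold is not high.
2. **High probes.** A boolean flag per probe, `intensity > threshold`.
3. **Runs.** Within each gene, probes are taken in genomic order
   (consecutive = adjacent in the gene's probe list, irrespective of exon
   boundaries) and all *maximal* runs of consecutive high probes with
   length ≥ `min_run` (default 5) are collected. Probes without a gene
   assignment are ignored; a probe assigned to several genes would be
   evaluated independently per gene.
4. **Initiating-L1 join.** A candidate L1 integrant must be (a)
   full-length with span > `min_l1_length_bp` (5000), (b) of an active
   subfamily — RepeatMasker names are normalized case-insensitively by
   prefix (`L1Md_T*`→T_F, `L1Md_Gf*`→G_F, `L1Md_A*`→A,
   `L1Md_F*`/`L1_Mus*`→F; table overridable), (c) antisense to the run's
   gene, and (d) within `gene_distance_kb` (30) of the gene span **or**
   within `probe_distance_kb` (100) of any run probe. Distances are
   nearest-edge gaps, zero on overlap. The disjunction follows the
   "and/or" phrasing of the rule set; an `and` mode is available. Among
   survivors the element minimizing the probe distance wins; exact ties
   break on lexicographically smaller element id. Calling is strain-aware:
   an element absent from a sample's strain is never a candidate for that
   sample.

**Truth evaluation.** RIFT identity is the (gene, L1) pair — the same key
used for catalog comparison. Precision and recall against a planted truth
set are computed over these identity pairs; sample-resolved recall is
reported alongside. The identity level is deliberate: under Gaussian noise
at a mean+1SD threshold, a random ≥5-probe run occurs in roughly 1 in 10³
gene-samples, so an occasional call lands in a RIFT-hosting gene in a
sample outside the truth labels. Such a call names a genuinely planted
fusion transcript; counting it as a false positive would make "perfect
precision" a property of the noise draw rather than of the caller.

**Monotonicity.** Tightening `min_run` or the distance bounds shrinks the
call set monotonically. Raising `sd_multiplier` is monotone in the set of
called (gene, sample) pairs but *not* in the raw call count: a stricter
threshold can split one long maximal run into two qualifying runs. The
property tests assert the pair-set form.

## Coordinates

Genomic intervals are 0-based half-open throughout (BED convention); GFF3
I/O converts from 1-based inclusive on disk. Positions inside an L1 are
1-based on the element's *sense* strand, so antisense features (TSS,
donors) are still cited in sense coordinates. For a plus-strand integrant
`coord = pos − start + 1`; for a minus-strand integrant `coord = end −
pos`. `riftscan.coords` holds the converters; the round trip is exact on
both strands. A 5′-truncated integrant is treated as a prefix of the
reference coordinate system.

## Transcript features

- **Clone classes.** The block containing the clone's 5′ end is matched to
  an L1 (a clone overlapping two elements goes to the one containing the
  5′ end; nested ties to the smaller id). Antisense + ≥2 blocks with at
  least one block partly outside the element ⇒ spliced AS RIFT; antisense
  single block crossing the element's 5′ end into flank ⇒ unspliced AS
  RIFT; sense-oriented poly(A)+ block inside the element ⇒ premature
  sense transcript; everything else ⇒ OTHER. Every clone receives exactly
  one label.
- **Splice donors.** The junction is anchored at the L1 sense coordinate
  of the *last exonic base* of the L1 block. On the antisense transcript
  the exonic 4-mer is the reverse complement of sense positions
  [j, j+3] and the intronic 5-mer of [j−5, j−1]; the anchor was chosen so
  the canonical donor strings (`GATGgtgag` at 1838, `TCAGgtgtg` at 1892)
  reproduce verbatim. A call is valid when the intron starts with `gt`;
  non-canonical junctions are returned with `valid=False`, never dropped.
- **ATG scan.** The sense window is reverse-complemented and scanned for
  ATG; frames are 0/1/2 relative to the antisense transcript start, and
  each hit also reports the sense coordinate of the A.
- **Percentages** are rounded half away from zero to integers (44/65→68,
  13/65→20, 363/940→39), matching how count tables are conventionally
  printed.

## Synonymous recoding

The published design objective (maximally change codon usage, preserve the
protein and the A/T content) does not come with an algorithm, so the
recoder is this package's own construction:

- per codon, the synonymous alternatives at maximal Hamming distance are
  enumerated exhaustively (≤6 synonyms per codon; Met/Trp stay fixed);
  per-codon maximality is therefore optimal by construction;
- `neutral_AT` starts from the lexicographically smallest maximal-distance
  synonym and repairs globally: while |ΔAT| exceeds `at_tolerance`
  (default 0.01 as a fraction of sequence length), the single swap —
  always within a codon's maximal-distance set — that brings ΔAT closest
  to zero is applied, ties broken by position then lexicographically. The
  repair is a greedy heuristic; on ≤10-codon inputs it is checked against
  brute-force enumeration of the full product space. Infeasibility (the
  maximal-distance sets cannot reach the tolerance band) is reported via
  `at_feasible=False`, never silently violated;
- `min_AT` picks the G/C-richest maximal-distance synonym per codon, which
  is the exact product-space minimum.

The whole procedure is deterministic; the `seed` argument exists only for
interface symmetry. Motif disruption counts overlapping IUPAC matches on
one or both strands and reports `count_original − count_recoded` as-is
(negative values mean the recoding created sites).

## The synthetic-data generator

The generator emulates the assay's inputs with planted ground truth.

- **Layout.** One chromosome (multi-chromosome inputs are accepted by the
  caller); 200 genes of 8 × 200 bp exons separated by 8 kb introns, genes
  110 kb apart. The spacing guarantees that an integrant eligible for one
  gene is beyond both distance bounds of every other gene, so spurious
  cross-gene joins cannot occur by construction.
- **L1 population.** 60 integrants. Composition is applied as exact
  rounded counts with seed-shuffled assignment (not per-element coin
  flips), so every seed yields the same composition: 60% full-length
  (6.5–7 kb), of which 20 are caller-eligible (intronic, antisense,
  active subfamily drawn as 50% T_F / 20% G_F / 20% A / 10% F); the
  remaining full-length elements each fail exactly one filter (sense
  orientation, inactive subfamily `Lx5`, or placed ≥300 kb from any
  gene); short elements are 1–4 kb. Half of the eligible elements are
  polymorphic: present in a random proper subset of the five strains.
- **Intensities.** Background is Gaussian on the log2 scale,
  Normal(6, 1) — chosen for analytic checkability; RMA-processed data is
  roughly symmetric but the true distribution is unstated — which places
  the mean+1SD threshold at ≈7. Probes (4 per exon, evenly spaced) in the
  exons downstream of a planted integrant gain `signal_shift` = 6 log2
  units (6 background SDs) in the samples matching the RIFT's tissue and
  carrier strains. One sample per (strain, tissue) pair: 5 strains × 3
  tissues.
- **Truth.** Each planted RIFT draws a tissue (70% testis / 15% brain /
  15% kidney), an antisense TSS uniform in the tissue's window of L1
  sense coordinates (testis 2201–2244, kidney 2210–2306, brain
  2210–2478), and — for the 78% spliced — a donor at 1838 (weight 0.68),
  1892 (0.20) or a random "other" coordinate in 1700–2100 (0.12).
- **Clones.** Per tissue, the observed RACE cohort sizes (19 testis, 35
  kidney, 54 brain) are drawn from the planted RIFTs with jittered 5′
  ends; spliced clones end their L1 block exactly at the donor and
  continue into the first downstream exon; unspliced clones read through
  the element's 5′ end plus 500 bp of flank. Four sense-strand poly(A)+
  decoys are added.
- **Reference element.** `make_l1_reference` builds a synthetic stand-in
  for a real reference element: random sequence of 7000 nt with the two
  canonical donor motifs (and an antisense TATAA ending at sense 2698)
  planted at their published coordinates, and approximate landmarks
  (5′ UTR 1–1800, ORF1 1801–2916, ORF2 2921–6790, 3′ UTR 6791–7000). Only
  the planted features are coordinate-faithful; the background sequence is
  not a real element.

**What passing tests do and do not show.** The generator reproduces the
statistical structure the rule set assumes — Gaussian log2 background,
block-shaped signal confined to downstream exons, clean annotations. Real
arrays have probe-specific affinities, correlated noise, cross-
hybridization (notably from repetitive elements), partially wrong gene
models and 5′-truncated or rearranged integrants; perfect recovery here
bounds algorithmic correctness, not field performance. All generators are
deterministic given (config, seed); each stage uses an independent seeded
stream so, e.g., the background matrix is identical whether or not RIFTs
are planted.

## Problem sizes and runtime choices

Defaults were sized so the full suite runs in well under a minute: the
planted-recovery condition uses the 200-gene / 20-RIFT genome above; the
null false-call experiment uses 10,000 unsignalled 5-probe genes (expected
run rate 0.159⁵ ≈ 1.0 × 10⁻⁴, tested within 3 binomial SEs); oracle
equivalence uses 1000 random run instances (≤50 probes) and 500 random set
families; the recoder guarantees are exercised on 1000 random ORFs of
30–300 codons; pipeline determinism is checked byte-for-byte on a 60-gene
genome.

## Known limitations

- No array normalization (inputs are already-normalized log2
  intensities), no multiple-testing correction (the rule set applies
  none), no quantification beyond the binary rule set.
- The caller assumes probe→gene assignment is given; it does not
  re-annotate probes.
- Splice-donor extraction requires a reference sequence and assumes the
  genomic integrant matches it; integrant-specific variants are not
  modelled.
- The recoder's global A/T repair is greedy (per-codon choice is exact);
  no avoidance of restriction or splice sites.
- Venn comparisons count identity keys only; no statistical test of
  overlap is attempted.
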