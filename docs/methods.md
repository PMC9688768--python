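# Methods

## The analysis in brief

The pipeline curates somatic mutation calls over the 22-gene UGT
superfamily and summarizes them into landscape tables. Its substance is
not a statistical model fitted to data but a chain of deterministic
re-annotation and aggregation steps whose correctness is testable
against ground truth: coordinate remapping over exon-sharing loci,
rule-based functional annotation, and counting conventions that
reproduce published summary tables exactly.

## Gene models and coordinates

Transcripts are explicit exon lists with strand, genomic CDS bounds and
the spliced CDS sequence. Conventions:

- Genomic coordinates are 1-based inclusive (MAF convention); any
  half-open arithmetic is internal only.
- c.1 is the A of the initiator ATG; the CDS includes the terminal stop
  codon. 3'UTR offsets are `*N`, 1-based from the first base after the
  stop. 5'UTR SNVs render as `c.-N`.
- Splice sites are exactly the canonical dinucleotides: donor GT = the
  first two intronic bases past an exon in transcript sense, acceptor
  AG = the last two before the next exon. Larger consensus windows and
  intronic HGVS offsets (`c.N+M`) are out of scope: the disruption rule
  of interest concerns only the dinucleotide.
- Splice offsets count distance from the exon boundary (donor offset 1 =
  G of GT; acceptor offset 1 = G of AG).
- Variants spanning a boundary take the most severe overlapping region,
  CDS > splice > UTR > intron. This tie-break is our decision; the
  source material does not state one.
- Insertions are anchored at a single genomic base (Start = End) and
  inserted after that base in transcript sense.

Consequence calling translates the affected codon(s): SNVs in the CDS
are Silent / Missense / Nonsense / Nonstop (stop-codon loss) /
Translation_Start_Site (any hit in codon 1); CDS indels are frameshift
when length mod 3 ≠ 0, otherwise in-frame. The frameshift protein is
obtained by translating the shifted sequence — extended into the 3'UTR —
until the first stop, and the `fsTer k` distance counts the new stop's
codon index with the first altered residue as 1 (standard HGVS, giving
the `Trp173GlyfsTer8` style). Multi-nucleotide substitutions are
quarantined, not modelled. For the nonstop case the p. string is
rendered `p.Ter{n}{Aaa}` without the `ext*` suffix — the extension
length is not needed downstream.

## Curation

Cohorts are assembled from TCGA barcodes (4th field, first two
characters → sample type). Exclusions, in precedence order: recurrent
tumors always; metastatic tumors except melanoma, where they form the
`SKCM-metastatic` sub-cohort; an explicit barcode blocklist (the
published misclassified-sample exclusions are clinical judgments, not
computable rules, so they are config data); hypermutators.

The hypermutator criterion is configurable because the source analysis
never states its cutoff, only that 53 tumors averaging 16,569
mutations were removed while the retained top cohort averages
1204/tumor. Two strategies ship: an absolute per-sample threshold
(default 5000, which must exceed ~2000 to keep the retained melanoma
tail) and per-cohort Q3 + k·IQR (default k = 3, quartiles by linear
interpolation). A single absolute threshold cannot serve cohorts whose
medians differ by two orders of magnitude — a 300-mutation tumor is an
extreme outlier in a 15-median cohort and unremarkable in a 1204-median
one — so multi-cohort recovery uses the per-cohort strategy.

Re-annotation over the family registry handles four documented quirks,
as data-driven rules (registry entries, not code):

1. unique-exon mutations listed as a sibling member's intron →
   relabelled to the owning gene, class and c./p. recomputed;
2. shared-block mutations credited to a single member → assigned the
   category label ("1A E2-5", "2A1/2A2 E2-6") with the full member
   fan-out, and counted **once** in every downstream table (the fan-out
   list exists for per-enzyme queries only, never for counting);
3. records annotated on a configured variant transcript (the extended
   UGT2A1 form) → remapped to the canonical transcript's coordinates;
4. records inside decoy intervals (DNAJB3 embedded in the UGT1A locus)
   → dropped and logged.

Shared-block coordinates are computed on one canonical member transcript
per family (configured in the registry). Records whose stated cDNA
position contradicts their genomic position, or whose reference allele
contradicts the transcript sequence, are quarantined as conflicts and
excluded from counts — mirroring the handful of such records found in
the source data.

Intron and splice records are attributed to a family's shared block when
they fall within 10 bp of it, and to a member gene when within 10 bp of
its unique exon; this flank padding covers the splice dinucleotides and
near-exon intronic positions the pipeline places and corrects, without
claiming deep intronic territory.

## Functional annotation

- **Kozak**: window −9..+4 around the ATG (position +1 = A; no position
  0), with −10 and +5..+13 reported as adjacent context. Optimal motif:
  A/G at −3 and G at +4. Rules: start-codon hits; loss of the −3 A/G or
  the +4 G (`optimal_disrupted`); +5 U→other (potential enhancement,
  because a U at +5 negates the +4 G) and +5 →U (potential weakening);
  everything else in-window is weak, adjacent positions weak-or-none.
  The rule set is total over the window.
- **Splice**: any substitution inside the canonical GT/AG dinucleotide
  disrupts the site.
- **miRNA sites**: the catalog is an input TSV (gene, miRNA, site and
  seed intervals as `*N` offsets); no target prediction or pairing
  thermodynamics. Seeds sit at the 3' end of their site, so any
  non-seed overlap is classed `five_prime_of_site` — the boundary of
  the "5' sequence of the site" is our decision.
- **Conservation**: a column of the aligned protein FASTA is conserved
  iff all members show the identical residue with no gap (100% identity;
  the source's usage concerns specific invariant residues, and no
  similarity classes are stated). Residue numbers per member are
  recovered by counting non-gap positions, so convergence across members
  is reported in each gene's own protein coordinates.

## Landscape conventions

- mutations/tumor = floor(total/n); validated against a printed row
  where rounding would differ (155233/411 → 377, not 378).
- fraction of tumors with UGT mutations = truncation to 3 decimals;
  validated likewise (235/512 → 0.458, not 0.459). Two published rows
  (CESC, DLBC) print fractions inconsistent with their own printed
  counts under any convention; the package reproduces the counts and
  documents the exceptions. The expression-stratification fraction
  (83/267 → 0.311) instead matches rounding, and is rounded.
- Recurrence counts tumor-occurrences (one per distinct sample per
  identical chrom/pos/ref/alt/gene key); cross-dataset matching
  requires allele identity, not just position.
- Hotspots: a qualifying window is ≤ `window_bp` consecutive cDNA bases
  holding ≥ `min_count` events; overlapping qualifying windows (sharing
  at least one event) merge into one maximal cluster whose span is the
  distance between its outermost events. Defaults window 31, min 6 —
  chosen to capture the published examples (6–12 events over 11–31 bp);
  both are flags because the published account gives examples, not a
  definition, and the windowed scan is our formalization.

## Statistics

Spearman: average ranks for ties; r as the Pearson coefficient of the
ranks; two-sided p from the t-approximation with n−2 df (exact
permutation agreement within 0.05 is tested at n ≤ 8). The optional
log2 transform excludes zero-valued pairs with a logged notice — the
rank statistic is transform-invariant, so the transform's only effect is
this exclusion rule. On the published per-cohort table the convention
adopted is: melanoma enters as its two sub-cohorts (34 rows) and the
zero-burden cohort (TGCT) is excluded, giving n = 33 and r = 0.9398,
which matches the published figure (0.939, truncated) — the merged
variant gives 0.934 and was rejected. Chi-squared: plain Pearson
statistic, no continuity correction, expected counts from margins; a
zero expected cell is an error advising a category merge.

## Synthetic data

The generator emulates, on the toy registry, the phenomena the pipeline
must survive; its defaults are the study conditions:

- four cohorts of 250 tumors with log-normal burdens (σ = 0.5) at
  medians 15, 106, 475 and 1204 — the published per-tumor range across
  cancer types; the 1204-median cohort is 75% metastatic (melanoma-like)
  and two cohorts contain 2% recurrent samples;
- hypermutators at fraction 0.005 with a 20× burden multiplier,
  matching the order-of-magnitude gap between excluded hypermutators
  and retained cohort means;
- UGT mutations at 0.00128 per background mutation (the observed
  3427/2,686,092), classes drawn from the observed pan-cancer census
  with a small floor so all 13 classes occur (the observed census has
  zero in-frame insertions);
- 55% of missense records SIFT-deleterious (observed 1099/1998);
- recurrence boost 0.08 (probability of reusing an existing key) and
  one configured hotspot (7 events in a 13 bp cDNA window);
- mis-annotation rates default to 1.0 for the three relabelling quirks —
  faithful to the source files, where the quirks are systematic, not
  sporadic — plus ~0.01 decoy records per tumor.

Every placement is validated against transcript structure, all
randomness flows from one generator seeded by a single integer (fixed
seed ⇒ byte-identical output), and the truth ledger covers every sample
and record exactly once.

What the generator does **not** emulate: trinucleotide mutational
signatures, germline background, read-level evidence, purity/ploidy,
and realistic inter-gene mutation-rate variation. Passing recovery
tests therefore demonstrates the correctness of the coordinate
arithmetic, correction rules and aggregation logic — not robustness to
caller artifacts or alignment error in real MAFs.

## Problem sizes

The toy registry scales exon sizes down (CDS 258–534 nt per transcript,
real topology preserved) so exhaustive coordinate round-trips cover all
~8000 CDS bases in well under a second. The default synthetic run is
1000 tumors (~0.5M records, a few seconds); tests use smaller cohorts
of 30–400 tumors. The consequence-calling oracle comparison uses 1000+
random variants per run.

## Known limitations

- No VCF input, no protected-MAF handling, no network fetch; the real
  MC3/DepMap files are out of the test path by design.
- No full HGVS parser: consistency checking extracts the leading
  coordinate of `c.`/`*N` strings only.
- No splice-strength or miRNA-pairing models; no driver-gene background
  statistics; no survival analysis (deliberately out of scope).
- SIFT calls are consumed as input, never computed.
- The published 66/342/164 conserved-residue counts require the real
  protein alignments, which are external inputs; the conservation
  machinery is validated on the packaged toy alignment instead.
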