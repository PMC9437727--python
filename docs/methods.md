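# Methods

## Scope and data model

`miredit` analyses dual-sgRNA CRISPR/Cas9 editing of miRNA loci in a
polyploid genome.  A locus (`PremiRNALocus`) is an ~800-nt amplicon holding
a stem-loop precursor with annotated mature miR-5p/miR-3p spans and two
SpCas9 guide sites; up to four allele sequences differ from allele 1 by
substitutions only (natural SNPs).  Coordinates are 0-based half-open
throughout; the blunt Cas9 cut sits between protospacer positions 17 and 18
(3 bp 5' of the NGG PAM).

## Synthetic-data generator

All inputs are generated by seeded pure functions that return ground truth
alongside the artifact.  What the generator emulates, and what it does not:

* **Loci.**  A precursor (~114 nt) is assembled from a 5' arm (12-nt pad +
  21-nt mature miR + 20-nt extension), an 8-nt terminal loop, and a 3' arm
  that is the reverse complement of the 5' arm with 8 substitutions outside
  the duplex and 2 isolated mismatches inside it (kept ≥ 4 nt apart).  These
  defaults were chosen so that wild-type precursors behave like genuine
  plant pre-miRNAs under the internal energy model — MFEI ≈ 1.0–1.3, never
  classified impaired across 24 generator seeds — while retaining the
  empirically observed severity gradient: deletions of ≥ 4 nt frequently
  (≈ 35%) merge duplex loops past the 5-nt limit or depress MFEI below
  0.85, whereas ≤ 1-nt edits almost never do (≈ 0.4%).  Guides flank the
  mature miR (sense cut 1 nt inside its 5' end, antisense cut 2 nt inside
  its 3' end); PAM bases are written into allele 1 before the 3' arm is
  derived, so guides always match allele 1 exactly.  Natural SNPs are
  Bernoulli(snp_rate) per position per non-reference allele (default 0.01,
  bounded at 0.05).
* **Edits.**  Classes {none, short deletion 1–6 nt, 1-nt T/G insertion,
  inter-guide excision, large deletion 7–60 nt} with configurable
  probabilities; positions jitter uniformly within ±4 nt of a cut.  Recorded
  spans are left-normalized (the aligner's canonical placement), and a drawn
  large deletion that spans both cuts is labelled an inter-guide excision —
  the two descriptions denote the same molecule.
* **Clones and traces.**  Mosaic lines are lists of (outcome, proportion);
  clones are drawn with replacement.  The Sanger surrogate is the
  column-stochastic 4×L matrix of mixture-weighted base indicators over a
  window, plus symmetric uniform noise, renormalized.  No .ab1
  chromatogram emulation, no basecalling error model.
* **sRNA reads.**  50-nt single-end reads: mature insert (70% canonical,
  otherwise templated 5'/3' shifts of ±1 nt), optional non-templated tail
  (default probability 0.1; lengths 1–3 with probabilities 0.7/0.2/0.1; the
  first tail base is forced to break templating), 3' adapter, phred
  qualities ~ N(30, 3) clipped to [2, 41].  Impaired precursors yield reads
  at a configurable leak rate, default 0.  Not modelled: sequencing
  substitution errors inside the insert, ligation bias, PCR duplicates —
  so discovery metrics here bound what mapping-exactness can achieve, not
  what a real library would show.
* **qPCR.**  Cq = intercept + slope·log10(quantity) + N(0, sd); duplicate
  wells at two dilutions; ≥ 4-point ten-fold standard series per assay.

## Genotyping

Clones are globally aligned to every allele with affine gaps (match +2,
mismatch −3, gap open −6, extend −1; these weights make one long gap cheaper
than scattered gaps, which is what excision alleles require).  An
edit-distance prescreen (edlib) selects candidate alleles before the full
affine alignment; ties break to the lowest allele index.  Difference
operations are left-normalized; applying them to the best allele must
reconstruct the clone (asserted on every call).  Substitutions present at
the same coordinate with the same base in non-transgenic control clones
(aligned against allele 1) are masked as natural polymorphism; indels are
never masked.  Remaining indels are classified: deletions ≤ 6 nt short,
longer deletions containing both cut positions excisions, otherwise large;
insertions carry their base.  A clone may carry several calls; a line's
mutated fraction counts clones with ≥ 1 call.

The knock-out score solves non-negative least squares for the mixture of
candidate one-hot trace profiles that best explains an observed trace
matrix.  The default candidate set (all unedited alleles; deletions 1–15 nt
at offsets −4..+4 around each cut; A/C/G/T insertions at each cut; the
inter-guide excision) is deliberately over-complete and therefore
collinear; the active-set NNLS solve is well-defined regardless and returns
a sparse solution.  Profiles identical over the window are merged, and
proportions are aggregated by indel signature (type, net size) — placements
of a same-size deletion 1–2 nt apart differ in at most a couple of trace
columns and are not individually identifiable at realistic noise, while the
size spectrum is.  The editing rate is 1 − (proportion on groups containing
an unedited allele).  When material carrying natural SNPs is deconvolved
against candidates built on the reference allele only, part of the unedited
signal is attributed to edits; this known upward bias is reproduced and
tested.  A strict column-rank check is available (`check_rank=True`) for
curated candidate sets.

## Folding and processing classification

The internal engine is a Zuker dynamic program over a decomposable
Turner-type nearest-neighbor model at 37 °C: Watson-Crick + G:U stacking,
hairpin/bulge/interior initiation tables (interior loops capped at 30
unpaired nt, Ninio asymmetry 0.6 kcal/unit capped at 3.0, 1-nt bulges keep
the closing stack), and an affine multiloop (3.4 + 0.4 kcal/branch,
unpaired bases free).  Dangling ends, coaxial stacking, terminal-AU
penalties and special small-loop tables are omitted; this keeps the energy
of any structure equal to the sum of its loop terms, so three independent
routes agree exactly: the dynamic program, a loop-decomposition re-scorer
for arbitrary dot-brackets, and exhaustive enumeration for sequences ≤ 14
nt (the test oracle).  Traceback preference is fixed (pairing first,
smallest interior offsets first), making results deterministic.  ViennaRNA
(python bindings or the RNAfold binary) is exposed as an external
validation backend with its own engine tag; internal and external
structures are never mixed, and no byte-agreement with RNAfold is claimed —
the classifier contract is what matters.

MFEI = AMFE / GC% with AMFE = |MFE|/L×100 and GC on the 0–100 scale, so the
conventional 0.85 threshold applies directly.  The miR\* span is inferred
from the pairing partners of miR-5p bases extended by the canonical 2-nt 3'
overhang; an annotated miR-3p span takes precedence.  Duplex features: a
miR position is a mismatch when unpaired or paired outside the star span
(G:U counts as paired); internal loops are contiguous unpaired runs between
consecutive duplex pairs, with the headline size summing both strands (the
per-strand maximum is reported alongside, since the field's phrasing is
ambiguous about the convention).  A precursor is impaired iff MFEI < 0.85,
or the largest duplex loop exceeds 5 nt, or it is excised/degenerate; both
inequalities are strict, and the classifier is monotone in both inputs.

## Variant discovery

Preprocessing locates the 3' adapter by prefix match (≥ 6-nt anchor),
truncates the insert at the first base with phred ≤ 20 (whole-read
discard is available by configuration), keeps 18–30-nt inserts, and
collapses identical survivors.  Mapping is exact substring, sense strand,
no mismatches.  A mapped read overlapping a precursor's mature span is a
templated variant (canonical at offsets 0/0); an unmapped read whose core
maps after stripping ≤ 3 terminal nt from one end is non-templated, the
end with the longest matched core winning (tie → 3').  Variants mapping to
several precursors are counted for each source but flagged ambiguous;
totals ≤ 2 reads are flagged low-abundance.  cpm uses the sample's clean
read count as denominator.  The exclusion filter reports a variant for a
test group only when present in ≥ 1 test sample and absent from every
control sample; the pipeline additionally requires the variant's source to
be the line's own locus, since reads from an unedited reciprocal locus are
uninformative about the edit.

Discovery performance is measured count-weighted (the fraction of clean
read mass assigned to / recovered from truth variants): quality truncation
legitimately produces shortened inserts that are real reads but absent
from the truth table, so sequence-set precision would penalize correct
behaviour of the trimmer.

## Target scoring

Expectation = Σ per-position penalties of the miRNA aligned 5'→3' against
the reverse of the target site: Watson-Crick 0, G:U 0.5, mismatch 1, gap 2;
positions 2–13 weighted ×2; one bulge of ≤ 2 nt allowed per site (best
placement chosen).  Hits with expectation ≤ 3 (the stringent cutoff) are
kept, best hit per transcript.  Independent of the score, ≥ 3 consecutive
mispaired positions intersecting miRNA positions 12–14 — the central region
whose pairing is required for cleavage — mark the hit non-functional.  The
weights live in module constants; no accessibility/energy term is modelled.

## Quantification

Standard curves are ordinary least squares of Cq on log10 quantity (≥ 3
points over ≥ 2 logs); efficiency = 10^(−1/slope) − 1.  Quantities are
inverted per well, averaged on the quantity scale across duplicate wells
and dilutions (duplicates > 0.5 Cq apart are flagged), normalized to the
endogenous-control quantity of the same sample, and expressed relative to
the arithmetic mean over non-transgenic samples.  Undetected Cq values must
be absent from the table, never zero; samples missing the control assay are
skipped with an error record.

## Pipeline and problem sizes

The orchestrator derives one integer seed per stage from the top-level seed
(SHA-256, < 2^31), so identical configs give byte-identical TSVs.  The
default study: 2 loci × 4 alleles (SNP rate 0.01), 8 mosaic lines with 3
outcomes each, 10 clones/line + 12 NT clones per locus, sRNA depth 10^4
reads/sample (3 NT samples + 1 per line), qPCR noise 0.1 Cq.  Abundance
truth ties miRNA yield to the processable fraction of a line's outcomes,
and target-transcript truth rises as miRNA falls (repression relief),
which the quantification stage then re-estimates from simulated plates.

The benchmark script (`scripts/acceptance.py`) uses: 200 sequences ≤ 14 nt
for the folding oracle; 1000 clones per edit class for genotyping recovery
and 1000 unedited clones for the SNP false-call count; a 6-point mixture
grid at 2% trace noise for deconvolution recovery; 10^5 reads/sample over
4 samples (tailing 0.1) for discovery precision/recall; and 8 lines at
depth 1000 for the abundance correlations.  These sizes give stable
estimates while keeping a full run around a minute on one CPU.

## Known limitations

* The energy parameter set is reduced (no dangles/coaxial/terminal-AU), so
  absolute MFE values differ from RNAfold's by a few kcal/mol on real
  precursors; threshold-adjacent MFEI decisions on real data should use the
  external backend.
* Exact-substring mapping cannot see variants spanning sequencing errors;
  the simulator does not generate such errors, so real-data recall will be
  lower than the synthetic benchmark.
* The trace surrogate is an idealized base-proportion matrix; chromatogram
  artefacts (dye blobs, mobility shifts) are out of scope.
* Mosaic proportions are uniform over outcomes; clonal selection during
  regeneration is not modelled.
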