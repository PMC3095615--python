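# Methods

## The discovery flow

`mirseek` implements the classical annotation flow for plant microRNAs from a
small-RNA sequencing library and a draft genome:

1. **Preprocess.** Reads are optionally 3'-adapter trimmed (leftmost
   suffix–prefix match of ≥ `adapter_min_overlap` bases), purged of tags
   contained in a user-supplied structural-RNA database (rRNA/tRNA/snRNA/
   snoRNA, exact substring on either strand), length-filtered to 18–30 nt and
   collapsed to unique tags with read counts. The size/redundancy profile
   reports, per length, the number of distinct tags (non-redundant), total
   reads (redundant) and their ratio.
2. **Known-family profiling.** Tags are matched against a mature-miRNA
   reference under ungapped anchoring: each tag end may extend or recede at
   most 2 nt relative to the reference (the canonical-length ± 2 rule), with
   at most `max_mismatch` core mismatches (default 0 — the most conservative
   reading of homology-based assignment; configurable up to 2). A tag matching
   several families is credited to all of them and flagged ambiguous, so
   near-identical families (miR165/miR166) are never silently arbitrated.
   Conservation status is reference metadata, not a computed quantity.
3. **Genome mapping and repeat filter.** Exact, full-length mapping on both
   strands; tags hitting more than `max_loci` (50) genomic loci are set aside
   as likely repeat-associated siRNAs.
4. **Precursor excision and folding.** Around each surviving hit, two
   asymmetric windows per far-flank length F ∈ {100, 170, 250} are excised —
   `[start−F, end+60]` and `[start−60, end+F]` — so the mature arm may sit
   near either precursor end; the 60-nt near pad allows a lower stem of up to
   ~60 nt on the mature side. Windows are folded and duplex-validated; the
   passing window with the lowest trimmed-hairpin energy is kept.
5. **Class A/B/C annotation.** Candidates whose predicted star arm was itself
   sequenced (± 2 nt end variation) are Class A; otherwise ≥ 5 mature reads
   gives Class B, fewer gives Class C (reported only on request). A count of
   exactly 5 is Class B ("fewer than five reads" defines C; its complement
   defines B). Candidates matching a known family are removed from the novel
   table. Loci sharing a mature sequence share an id stem with `_1`, `_2`
   locus suffixes.
6. **Target prediction.** Every transcript window of miRNA length is scored
   in the antiparallel register: mismatch 1.0, G:U wobble 0.5, single-nt
   bulge 1.0, all doubled at miRNA positions 2–13; sites scoring ≤ 4.0 are
   reported. These are the canonical plant rules; all four constants are
   configurable because published tools differ in their exact
   parameterisation.

## The folding model

The folding engine is a Nussinov-style dynamic program over pseudoknot-free
structures maximising an additive score: pair scores A:U = 2, G:C = 3,
G:U = 1, plus a stacking bonus of 1 for each pair directly stacked on
another; hairpin loops keep ≥ 3 unpaired bases. Reported "energy" is the
negated score — arbitrary units, not kcal/mol. Absolute energies are
therefore comparable only within a run and a scoring configuration; no
result in this package depends on absolute ΔG values. A thermodynamic
backend can be substituted by anything producing the same `FoldResult`
contract. Determinism: traceback prefers pairing over leaving a base
unpaired, the 5'-most partner, and the stacked continuation, in that order.

Duplex validation works on the fold's pairing map:

- Pairs inside the mature span fail immediately (`arm-in-loop`: the mature
  arm may not straddle the terminal loop).
- Partners of mature positions are restricted to the majority side and to
  the densest antiparallel diagonal (|i + partner(i) − centre| ≤ 6). A
  maximum-scoring fold readily adds incidental single pairs — e.g. the
  mature 3' overhang grabbing a loop base — and the diagonal cluster is what
  separates the duplex helix from such noise.
- The star span is the partner interval of the clustered duplex pairs
  (excluding partners picked up by the mature's two 3'-terminal bases, which
  by Dicer geometry protrude from the duplex) extended 2 nt at the star 3'
  end, imposing the 2-nt 3' overhang on both arms. This single rule covers
  mature arms on either precursor arm.
- A single stem-loop is required: at most one terminal loop between the
  inner edges of the two arms.
- Pass criteria: ≥ 16 matched pairs (inclusive — "exceeding 16" is read as
  the customary ≥ 16 discovery default; configurable) and mature/star length
  difference ≤ 4 nt.

The reported hairpin is the *trimmed stem-loop*: the duplex helix extended
outward through enclosing helices of ≥ 3 stacked pairs separated by ≤ 2 nt
per side. Trimming matters because a maximum-scoring fold decorates random
flanking sequence with short incidental helices; without it the reported
precursor length and energy would grow with the excised window instead of
describing the hairpin. For the same reason `best_precursor` ranks windows
by the trimmed-hairpin energy, not the whole-window energy.

## The synthetic data generator

`synthetic_data` emulates the statistical structure the analysis assumes,
with recorded ground truth:

- **Genome**: uniform-random scaffolds at GC 0.36 (a typical cucurbit value),
  100 kb over 4 scaffolds by default.
- **Planted MIR loci**: precursor = lower stem (25–60 bp perfect
  reverse-complement) · mature arm · loop · star arm · lower stem, with the
  mature arm randomly on the 5' or 3' arm and the locus on either strand.
  Mature length is drawn from 20–24 nt (mode 21); the star satisfies the
  2-nt 3'-overhang pairing rule with 2 interior positions knocked out to
  non-pairing bases, so matched pairs stay ≥ 16 while the duplex is
  imperfect. The loop (15 nt) is drawn from {A, C} so it cannot base-pair
  internally. Precursor lengths land in ~105–180 nt, inside the 100–300
  contract. Each draw is folded and duplex-validated before planting
  (rejection sampling), so the recorded truth always satisfies the
  generator's contract that every planted precursor re-folds into a valid
  stem-loop with the planted star arm.
- **Repeat family**: one 90-nt unit copied at exactly `repeat_copies` (60)
  loci; five 24-nt tags from fixed unit offsets simulate repeat-associated
  siRNAs that multi-map far past the 50-locus filter.
- **Reads**: planted mature/star sequences contribute exactly their recorded
  counts (mature 5–40, star 1–8 by default); background reads are drawn
  uniformly from genomic positions on either strand with the 24-nt-dominated
  length distribution typical of plant libraries (51% at 24 nt, ~10% each at
  21–23 nt).

What the generator does *not* emulate: sequencing errors, adapter-ligation
and length biases of real library preparation, transcription-level count
overdispersion, genuine heterochromatic siRNA clusters, and paralogous MIR
families. Passing the synthetic round-trip therefore demonstrates that the
pipeline's gates and geometry rules are implemented correctly, not that the
same recovery rates would hold on a real library.

Dinucleotide-preserving shuffling (for the duplex-validation null) resamples
a random Eulerian path of the dinucleotide transition multigraph, keeping
both termini and all dinucleotide counts fixed.

## Problem sizes and numerical choices

The bundled evaluation (`mirseek.evaluation`, also run by
`scripts/acceptance.py`) uses ten replicate studies of 30 kb genomes with 10
planted loci, a 60-copy repeat family and 100 background reads each — sizes
chosen so a replicate folds a few hundred windows and the whole study
completes in a couple of minutes while every gate (repeat filter, duplex
criteria, star matching, classing) is exercised. Folding is O(n³) per
window (numba-compiled); windows are ≤ ~330 nt.

Tie-breaks and degenerate inputs: collapsed tags sort by (count desc, seq
asc); report rows by (scaffold, start); palindromic tags count a locus once;
windows clipped at scaffold bounds are kept if they still contain the tag;
reads trimmed to zero length are dropped and logged. Score comparisons in
the fold traceback use a 1e-6 tolerance on an integer-valued score scale.

## Known limitations

- The folding score is a pairing heuristic: energies are not thermodynamic,
  and a maximum-scoring structure can differ from an MFE structure,
  particularly in AU-rich regions.
- Exact-match mapping only; a real 454 library's indels would need a
  mismatch-tolerant mapper in front of the pipeline.
- The bundled reference tables carry their original values as recorded,
  including free energies from an external folding engine, which this
  package does not attempt to reproduce.
- Star matching uses sequence identity (± 2 nt ends) rather than genomic
  coordinates, so a star sequence occurring elsewhere in the library would
  be credited; at realistic library sizes this is negligible.
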