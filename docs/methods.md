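# Methods

`hervkmap` re-implements the bioinformatic phase of an LTR-targeted
enrichment sequencing protocol for mapping HERV-K (HML-2) proviral and
solo-LTR integration sites, and ships a simulator of the wet-lab phase so
the whole pipeline can be exercised and scored against ground truth
without any external data.

## The analysis model

Enrichment libraries are built from randomly fragmented genomic DNA,
ligated to a suppression-PCR linker, and amplified with primers anchored
in the terminal regions of the HERV-K LTR, so that informative molecules
span an LTR/host junction. The analysis phase recovers integration sites
from such reads in five steps:

1. **Read preparation.** Sliding-window quality trimming (window 4, mean
   Q15, minimum mate length 36), PCR-duplicate removal by exact sequence
   identity of the pair, and overlap merging of mates (minimum overlap
   10, mismatch ratio <= 0.1; the qualifying overlap with the lowest
   mismatch ratio wins, longer overlap on exact ties). Deduplication runs
   before alignment, so sequence identity is the only available
   duplicate criterion. Both merged reads and unmerged mates continue.
2. **Chimeric-read detection.** A read is an LTR-host chimera when a
   20-bp *bait* — a terminal 20-mer of an LTR consensus — occurs in it
   at >= 90% ungapped identity in either orientation. The scan evaluates
   every bait at every offset; the maximal-identity hit wins, with ties
   broken toward the smaller offset and bait declaration order. The host
   side of the read (the *flank*) is kept, normalised so the LTR abuts
   its left edge; the linker is stripped from its far end (best
   suffix/prefix overlap >= 6 nt at <= 10% mismatches) and flanks
   shorter than 10 nt are abandoned. Flanks with a local ungapped match
   to any catalogued HERV-K sequence at >= 90% identity over >= 20 nt
   are removed: these are LTR-gag / LTR-env amplicons from proviral
   interiors, not host sequence.
3. **Unique mapping.** Flanks are aligned ungapped (mismatch budget 6% of
   flank length) over both strands by exact k-mer seeding (k = 13 by
   default) with pigeonhole-complete seed placement, or imported from any
   external aligner's SAM. Only flanks with exactly one best-scoring
   placement are kept; a tying second placement discards the flank.
   This is the strictest reproducible reading of "uniquely mapped" and
   is what makes repeat-embedded loci drop out.
4. **Locus calling.** Each alignment contributes its *junction*
   coordinate — the flank base adjacent to the LTR (left genome edge of
   a forward placement, right edge of a reverse one). Junctions within
   10 nt of a catalogued locus increment that locus (nearest edge wins;
   exact ties go deterministically to the lower-coordinate locus and are
   counted). Unassigned junctions are clustered (single linkage, 50-nt
   gap, >= 2 reads); clusters more than 2 kb from every catalogued locus
   are novel candidates, anything between the counting window and 2 kb
   is ambiguous. A candidate whose 5' and 3' junction clusters overlap
   within 10 bases delimits a target-site duplication and is called
   novel-non-reference (the TSD is reported as a 1-based inclusive
   interval, matching how such footprints are printed); a candidate
   abutting an annotated-but-uncatalogued LTR element is called
   novel-reference, and the two edge clusters of one element are merged
   into a single call spanning it. Abundance is counts per million
   uniquely mapped flanks (CPM), with an optional CPM >= 50 detection
   filter; loci at exactly 50 pass.
5. **Polymorphism calling.** Replicate counts are summed per individual
   and tested with an exact conditional binomial test: given
   t = ya + yb, ya ~ Binomial(t, Na/(Na+Nb)) under the null of equal
   relative abundance, and the two-sided p-value sums all outcomes no
   more probable than the observed one. A locus is polymorphic between
   two individuals iff the fold change of mean CPM exceeds 20 *and*
   p < 1e-10 (both strict). Mean CPM uses a pseudocount of 0.5 per
   replicate count, which keeps fold changes finite structurally —
   in real enrichment data absent loci attract a few stray reads, so
   finiteness there is empirical. No multiple-testing correction is
   applied: the method uses fixed thresholds, not an FDR procedure.

### The exact test as a replacement for a dispersion-based test

The published analysis used a count-based differential-expression
package for the contrast. Its settings (dispersion, normalisation) are
not part of the public record, so this package substitutes a fully
specified statistic: the conditional binomial test above, which is the
dispersion-to-zero limit of the exact negative-binomial test such
packages implement. At the extreme p < 1e-10 gate the two agree on
presence/absence contrasts, which is the intended use case.
Numerically, totals t <= 300 are evaluated in exact integer arithmetic
(weights C(t,k) Na^k Nb^(t-k) against the common denominator
(Na+Nb)^t), so the test is enumeration-exact where enumeration is
feasible; larger totals switch to log-space evaluation with a 1e-12
relative tie tolerance, where tie handling is irrelevant because such
cases are astronomically far from the decision threshold.

## The simulator

The simulator emulates the wet-lab phase on a synthetic genome and
provides complete ground truth (per-read tags, genotypes, realized
coordinates).

* **Genome.** Uniform-random background contigs (default 4 x 120 kb;
  desk-scale stand-in for a reference assembly). Optional groups of
  three identical 2-kb cassettes model repeat elements; loci planted
  inside a cassette are expected to be lost at unique mapping.
* **Elements.** Synthetic LTR consensus (968 bp) with LTR5A and LTR5B
  derived at ~4% and ~8% divergence, mimicking the subtype ladder
  (LTR5_Hs youngest, LTR5B oldest); a 2-kb internal segment stands in
  for the proviral interior (only its junctions matter at desk scale).
  Each insertion accumulates substitutions at
  `ltr_mutation_rate_per_mya` x age (default 0.0023/site/Mya, the
  literature-scale LTR substitution rate); the two LTRs of a provirus
  diverge independently. Insertions duplicate `tsd_len` bases of the
  target site (default 6).
* **Genotypes.** A configurable fraction of loci is polymorphic;
  carriers are drawn per individual from the allele frequency with a
  redraw guaranteeing at least one discordant pair; replicates share
  genotypes. Reference-assembly insertions appear in the emitted
  reference regardless of genotype; non-reference ones never do.
* **Libraries.** Molecules are `[LTR carry (55 nt, ending at the LTR
  edge)] + [host or internal flank] + [linker (25 nt)]`, with fragment
  lengths drawn from N(330, 60) and size-selected so the molecule falls
  in 250-450 bp; reads are PE150 with a flat per-base error rate and a
  configurable PCR-duplicate fraction (default 0.15; duplicated
  molecules are emitted twice). Primer-region mismatches m (25-nt
  primer) weight a junction's amplification by 1/(1 + exp(k (m - m0)))
  with k = 2, m0 = 3, which produces the observed detection bias
  against old, mutated elements. Proviruses also emit LTR-gag and
  LTR-env molecules because both LTR copies anneal each primer group.
  An off-target fraction (default 20%) of molecules is drawn from the
  background genome to exercise the bait and alignment filters.
* **Scale.** Desk-scale defaults are 1e5 read pairs per sample and a
  ~35-locus panel on ~0.5 Mb of genome; real libraries are three orders
  of magnitude larger in both respects, and the subsampling ladder used
  for saturation analysis is scaled down 100x accordingly
  (1e3 ... 1.5e5 reads).

**What the simulator does not model.** Quality-score structure (flat
Q37 with a flat error rate), indels and structural errors, gapped
alignment (the internal aligner is ungapped; indel-carrying flanks
appear only as unmapped loss — real-genome users take the SAM import
route), chimeric PCR artifacts, GC/length amplification bias beyond the
logistic primer model, truncated or rearranged elements, and nested
insertions. Passing tests therefore demonstrate the pipeline's logic
(junction arithmetic, windows, uniqueness, statistics) under controlled
conditions, not performance on real libraries.

## Packaged catalog fixture

The package ships a 1063-record reference catalog whose category
composition matches the reported locus list (85 reference proviruses,
946 reference solo LTRs, 5 + 27 non-reference loci; 69 polymorphic and
89 fixed annotations) with deterministic synthetic coordinates, since
the full supplementary coordinate list is not in the public record; the
35 novel loci are shipped with their published coordinates. Internal
coordinates are 0-based half-open; tabular listings are declared
1-based inclusive and converted on load. Contig names are normalised to
a lower-case `chr` prefix, scaffold names kept verbatim.

## Numerical and design choices

* **Library size for CPM** is the number of uniquely mapped flanks
  after all filters (recorded in every output header). The published
  CPM base is unstated; this choice makes CPM invariant to raw
  sequencing depth and aligner loss.
* **Bait matching is ungapped** because the published contract is a
  bait length and a percent identity, not an alignment scoring scheme;
  ungapped scanning is deterministic and oracle-checkable. Baits are
  generated per subtype consensus so diverged subtypes stay detectable.
  N never matches (windows are packed three bits per base, with N a
  fifth symbol).
* **The homology filter is exact** for its 90%/20-nt contract: any
  qualifying window either contains an exact run >= 7 (caught by 7-mer
  seeds) or is the unique (6,6,6) match-run layout (caught by a gapped
  6+6 seed at spacing 7); every anchor is verified by direct packed
  window comparison. Other parameterisations use a slower generic
  6-mer triple-seeding path with the same exactness argument.
* **Uniqueness ties:** a second placement at the same best score
  disqualifies the flank; no randomness, no MAPQ heuristics internally.
  SAM import uses MAPQ > 0 and primary-record status as an
  aligner-portable uniqueness proxy, which is a declared convention.
* **Detection vs counting window:** the 10-bp detection rule and the
  10-nt counting rule are treated as the same window parameter.
* **Novel-candidate support:** >= 2 reads by default (configurable to
  1). Known-locus detection accepts single reads, but novel calls in
  the original workflow were manually screened; a >= 2 default curbs
  false novels while remaining overridable.
* **Ambiguous zone:** clusters between the counting window and the 2-kb
  novelty distance are reported as ambiguous, never as novel.
* **Degenerate inputs:** empty catalogs, unknown contigs (logged once,
  empty result), zero library sizes (error), t = 0 contrasts (p = 1),
  zero-variance correlation vectors (NA) are all defined behaviours.
* **Determinism:** every stochastic step takes an explicit seed;
  per-insertion randomness is keyed by (seed, locus id) so element
  sequences are stable across haplotypes and individuals; gzip output
  is written with a zeroed mtime so reruns are byte-identical.
* **Chi-square construction:** the replicate-difference test is run on
  the 2 x k detected/undetected contingency table against the shared
  locus universe (Pearson, no continuity correction). Whether the
  original analysis used this or a goodness-of-fit to equal proportions
  is unstated; the contingency reading is the default here.
* **Plots are not emitted**; all outputs are tabular (TSV/JSON) and
  plotting is left to the user.

## Known limitations

* The internal aligner is ungapped and targets desk-scale genomes
  (<= a few Mb); real-genome runs should import SAM from a production
  aligner.
* CPM-filtered detection counts are not monotone under subsampling (the
  CPM threshold interacts with library size); only the unfiltered
  detected-locus curve carries the monotonicity guarantee.
* The exact test treats replicates as exchangeable Poisson draws
  (summing counts); it does not model extra-Poisson dispersion between
  replicates. At the extreme thresholds used for presence/absence
  calling this is immaterial, but moderate quantitative differences
  should not be interpreted against it.
* The age-vs-CPM bias depends on the logistic primer model; its slope
  is a mechanism choice, so only the qualitative trend (younger
  elements amplify better) is meaningful.
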