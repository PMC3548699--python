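# Methods

`supersage` implements a digital gene-expression workflow for
SuperSAGE-style tag data: 26-bp transcript tags anchored at an NlaIII
restriction site (CATG) are counted per library, contrasted between
libraries with an exact count test, mapped back to transcript models, and
the matched gene loci are anchored on chromosomes with cluster and
family-redundancy summaries. A synthetic-data generator with full ground
truth makes every stage testable end to end.

## Tag model and counting

A tag is the 26-base sequence starting at a CATG site; complete NlaIII
digestion releases the tag at the 3'-most site of a transcript (the
*canonical* tag), incomplete digestion can release tags at upstream sites.
A site closer than 26 bases to the transcript's 3' end yields no tag: the
protocol cannot produce a truncated anchored 26-mer, so such sites are
skipped rather than padded.

Counting is per library over distinct tag sequences (*unitags*). Input is
case-insensitive; records of the wrong length, without the CATG anchor, or
containing ambiguity codes are routed to a rejects report rather than
silently dropped, so retained + singlet + rejected counts always equal the
input stream length. Tags observed exactly once (*singlets*) are excluded
as likely sequencing noise. Normalised frequencies are tags per million
(tpm), `count / library_total * 1e6`, with the **post-exclusion** total as
denominator — the retained tag set is the analysis universe, so its total
is the natural library size. (Whether historical SAGE software normalised
by pre- or post-exclusion totals is ambiguous; with singlet mass around 1%
the choice moves tpm values by under 1%.)

## Two-library count test

Significance of a count difference uses the Audic–Claverie conditional
test. Given `x` counts of a tag in library A (total `N_A`), under the null
of equal underlying frequency the count `y` in library B (total `N_B`)
follows

    p(y | x) = (N_B/N_A)^y (x+y)! / ( x! y! (1 + N_B/N_A)^(x+y+1) )

which is exactly the negative binomial NB(r = x+1, p = N_A/(N_A+N_B)).
The implementation evaluates tails with `scipy.stats.nbinom` in log space;
the two-sided p-value is `min(1, 2 * min(lower tail, upper tail))` with
both tails including the observed count, so p is always in (0, 1]. An
exact-rational direct-summation oracle (`fractions.Fraction`, no rounding)
agrees with the implementation to ~1e-14 relative error over the full
support `x + y <= 50`.

Two properties of this test are worth stating explicitly:

* **It is conditional, not symmetric.** `p(y|x)` conditions on the first
  library's count; swapping the roles of the libraries changes the tails
  (verified by exact summation, e.g. p(3 | 17) = 0.0026 but p(17 | 3) =
  0.0015 at equal totals of 1e5). Contrasts therefore have a defined
  direction — the stress library is always A — and outputs are reported in
  that orientation.
* **It models sampling noise only.** The test assumes multinomial
  (Poisson-like) sampling from a fixed transcript pool, appropriate for a
  design with one library per condition and no biological replicates.
  Under that null its empirical size at p <= 0.05 is 0.04–0.05.

No multiple-testing correction is applied by default: calls are at raw
p <= 0.05, matching the single-tag screening character of the analysis.
The alpha level is a parameter, and `run_contrast` accepts an optional
correction (`bonferroni` or Benjamini–Hochberg) that changes the
classification while leaving the reported p-values raw.

Fold change is the SAGE convention: the ratio R of normalised frequencies
(A over B) with zero frequencies replaced by 1 tpm before the ratio,
reported directly when R >= 1 and as -1/R otherwise. |FC| >= 1 always;
negative values denote repression. A unitag is UR when p <= alpha and
FC > 1, DR when p <= alpha and FC < -1, and ns otherwise (|FC| = 1 has no
direction and is ns regardless of p). The unitag universe of a contrast is
the union of the two libraries' retained sets; a tag absent from one side
enters with count 0.

## Tag-to-transcript matching

Matching replaces a BLASTn tag-hit step with direct anchored search: a tag
matches a transcript at every position where the transcript carries a
26-base window starting with CATG whose positions 5–26 differ from the tag
in at most one base, plus strand only. For a fixed-length 26-mer with an
exact 4-base anchor and <= 1 mismatch this search is complete and
deterministic, and any such hit would trivially pass an e-value cutoff of
1e-4, so no separate e-value filter exists. The implementation indexes all
anchored windows exactly and probes the tag plus its 66 one-substitution
variants (3 alternatives x 22 non-anchor positions), which is provably
equivalent to a full Hamming scan and is verified against one in the
tests.

Matched 26-base intervals are classified against the transcript's
annotated spans: `CDS`, `UTR3`, `CDS_UTR3_junction` when the interval
overlaps both (at least one base on each side of the boundary, half-open
interval arithmetic), `UTR5`, or `no_UTR_annotation` when the transcript
has no annotated 3'UTR. A match whose anchor is not the transcript's
3'-most usable CATG is flagged as a partial-digestion candidate. *Sister
tags* — putative SNP variants — are unordered unitag pairs at Hamming
distance exactly 1 (the difference outside the anchor) that share at least
one matched transcript; candidate pairs are found by position-masked
bucketing, which is exact. Multi-transcript and multi-locus hits are all
kept (reports carry a hit-multiplicity column); transcript hits are
collapsed to gene loci to expose alternative-isoform multiplicity.

All coordinates are 0-based half-open in memory and 1-based inclusive in
every file written (GFF3, reports, Circos).

## Genome anchoring

Loci are anchored using their gene-model GFF3 coordinates. The arm
position class is a pure function of the locus midpoint: *pericentromeric*
within +-5% of chromosome length around the configured centromere
(default: mid-chromosome), otherwise *subterminal* within the outer 15% of
its arm measured from the telomere, otherwise *intercalary*. Both
fractions and the centromere position are parameters; real centromere
positions would be supplied per chromosome.

Clusters are maximal chains of anchored loci with inter-locus gap
<= `max_gap` (default 1 Mb at the library level; the pipeline config uses
50 kb, scaled to the 500 kb synthetic chromosomes) and at least `min_size`
members (default 2). *Synteny* here means family-level redundancy, not
alignment-based collinearity: for each gene family, loci on one chromosome
are merged into a family interval, and every unordered pair of chromosomes
holding the family yields one link. Circos export writes the plain-text
karyotype (`chr - id label start end color`), links and tile dialects, and
the module's own readers round-trip them losslessly.

## Synthetic data generator

The generator emulates a four-library drought-stress root experiment: a
tolerant and a sensitive accession, each stressed and control (TS/TC,
SS/SC). Defaults are the study conditions used throughout the tests:

| parameter | default | rationale |
|---|---|---|
| chromosomes | 20 x 500 kb | soybean chromosome count, desk-scale length |
| loci | 200 | enough for stable contrast statistics at desk scale |
| family labels | P5CS 6, P5CR 2, TPS 17, TPP 1, BADH 4, CMO 2, MIPS 3, IMP 10 | relative family sizes of the osmoprotectant-biosynthesis loci analysed in soybean |
| isoforms per locus | 1–4 (P = .6/.25/.10/.05) | alternative transcripts sharing the 3'UTR |
| CDS / 3'UTR length | 900 / 200 bp | typical plant mRNA proportions |
| library depth | 600,000 | ~one quarter of the 2.55 M post-singlet tags of a real four-library HT-SuperSAGE set |
| de_fraction | 0.28 | observed DE fraction of a stress-vs-control contrast in real root libraries |
| true fold changes | 2, 4, 8 | spans marginal to strong regulation |
| dispersion | 0 (Poisson) | single library per condition: counts are multinomial samples, no replicate-level variance; NB dispersion is an exposed knob |
| sister rate / mass | 3% of loci / 30% of locus mass | occasional heterozygous SNP splitting tag mass |
| partial digestion rate | 2% of emission events | rare incomplete digestion |
| singlet rate | 1% of library mass | count-1 noise tags |

Gene structure is deliberately minimal: single-exon genes whose transcript
is CDS followed by 3'UTR (no 5'UTR), so CDS and 3'UTR tile each transcript
exactly. Isoforms are progressive 5' truncations sharing the 3' end —
hence the shared 3'UTR and identical canonical tag. Structural corner
cases are planted at configurable rates: transcripts whose only usable
CATG lies in the CDS, transcripts without an annotated 3'UTR, and
untaggable transcripts with no CATG at all. Multi-member families are
spread over >= 2 chromosomes (true redundancy for synteny recovery), and a
configurable fraction of loci (default 60%) is placed with its midpoint in
the outer 15% of an arm to emulate subterminal clustering; if an arm's
outer windows fill up the locus falls back to an unconstrained position
rather than failing the run.

**Spike-in design.** Differentially expressed loci are selected in pairs
forced to equal baseline abundance (each pair's two shares are set to
their geometric mean), given the same fold change f, one regulated up (the
stress-library mean multiplied by f) and one down (the control-library
mean multiplied by f). Accession-specific regimes (TS-only / SS-only)
alternate over the low-abundance half of the pairs with aligned fold-change
cycling, and the high-abundance half gets the "both accessions" regime,
which loads all four libraries identically. Per-library means are then
rescaled to the target depth. The point of this arrangement is
*composition balance*: every library carries identical spiked mass, so
after normalisation an unspiked tag has a true frequency ratio of exactly
1 in every contrast — without it, renormalisation would turn truth-ns tags
into genuinely shifted ones and corrupt any false-discovery accounting.
Truth classes per contrast are derived from the realised per-library
multiplier ratios, so cross-accession contrasts (TS vs SS, TC vs SC) also
carry honest truth labels. The cost is a mild artificiality (spiked loci
come in equal-abundance pairs) that real data would not show.

What the generator does **not** emulate: read-level sequencing (counts are
emitted directly, no FASTQ), base-call error beyond the sister/singlet
mechanisms, multi-exon gene structure (so genome-level tag mapping across
introns is out of scope), biological replicate variance (dispersion
defaults to 0), GC or length biases, and between-accession genome
divergence. Passing tests therefore demonstrate correctness of the
algorithms under the stated sampling model, not robustness to artifacts
real libraries may contain.

## Validation experiments

Two calibration/recovery experiments ship with the package
(`supersage.benchmark`) and are re-run by `scripts/acceptance.py`:

* **Type-I error**: two libraries with identical lognormal mean profiles
  (1e4 tags, 1e6 depth), Poisson counts, singlet rule applied; the
  fraction of tags with p <= 0.05 is ~0.04.
* **Spike-in recovery**: the dedicated benchmark configuration
  (`spike_recovery_config`: 1e6-tag libraries, spike fraction 0.5) run for
  three seeds; the two stress-vs-control contrasts are scored against
  truth over unitags with baseline >= 50 tpm. Spikes with true |FC| >= 4
  are detected with the correct direction at sensitivity ~1.0, and the
  empirical FDR of UR/DR calls is ~0.06–0.07. The spike fraction is higher
  than the default dataset's 0.28 by design: an uncorrected raw-p 0.05
  screen over a mostly-null universe has FDR near
  `size x (1-pi) / (pi x power)`, so measuring FDR with useful precision
  requires a spike-dense benchmark; the observed DE fraction in real data
  is itself a mixture of truth and false positives and does not pin the
  truth fraction.

Problem sizes throughout (200 loci, 0.6–1 M tags per library, 3 benchmark
seeds) were chosen as the smallest giving stable statistics for these
experiments; a full five-stage pipeline run takes a few seconds.

## Numerical and design choices

* Tails of the count test are computed via `nbinom.logcdf`/`logsf`
  (regularised incomplete beta under the hood), never by naive summation,
  so deep tails (p ~ 1e-300) remain accurate.
* Zero replacement in the fold change acts on normalised frequencies (1
  tpm), not raw counts.
* Tag matching treats the anchor as inviolable: a mismatch in positions
  1–4 is not a match, whatever the total mismatch count.
* "Last CATG" ties across isoforms sharing a 3'UTR are reported per
  isoform, not deduplicated.
* The pipeline's outputs contain no timestamps; two runs with the same
  config and seed are byte-identical, and the run manifest records package
  and dependency versions, the seed and a config hash.
* Degenerate inputs fail loudly with named causes: empty libraries cannot
  be normalised, loci without coordinates cannot be anchored, stages
  refuse to overwrite existing outputs without `--force`, and infeasible
  locus packing names the constraint that failed.

## Known limitations

The count test's calibration statement applies under Poisson sampling; if
the generator's NB dispersion is raised, the test (which has no dispersion
parameter) becomes anticonservative at high counts — that is a property of
the method being modelled, not a defect of the implementation. Locus
collapsing relies on the generator's locus labels; on real annotation it
would inherit whatever locus assignment the GFF3 carries. Synteny links
are family-level redundancy and make no claim about sequence homology of
the linked intervals.
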