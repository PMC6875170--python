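# Methods

`tescope` measures two things about a genome's transposable-element (TE)
complement: how recently and how often each family has transposed
(insertion cataloguing and divergence statistics), and whether natural
selection shapes the codon usage of TE genes (the codon-usage battery).
Because the interesting guarantees are statistical, every stage is built
and validated against a synthetic-genome generator that plants insertions
with known coordinates, ages and codon composition.

## The synthetic genome generator

The generator emulates the repeat landscape of a compact protist genome:
low-copy LTR retrotransposon families (copia-like, chromoviral and
non-chromoviral gypsy-like) and DNA transposon families with inverted
terminal repeats (ITRs), planted into an i.i.d. background at a
configurable GC content (default 0.50, matching the non-coding GC observed
in such genomes).

**Family consensus.** An LTR family consensus is `LTR + 5'UTR + ORF +
3'UTR + LTR` with the two LTR copies identical; an ITR family carries
reverse-complement terminal repeats and may hold spliceosomal introns
(GT..AG), inserted between codons so exon frames stay trivial.  ORFs start
with ATG, contain no internal stop and end with a stop codon.  The default
three-family configuration uses a 243 bp-LTR chromovirus with a 5 bp TSD,
a 373 bp-LTR gypsy-like family with a 4 bp TSD and a 28 bp-ITR transposon
with an 8 bp TSD and one intron — element sizes of roughly 1.6–2.4 kb,
inside the 2–11 kb range such families span in real genomes, but kept at
the small end so a full pipeline run takes seconds.

**Codon model.** ORF codons are drawn per amino acid (amino acids uniform
over the 20) from a distribution solved to hit two targets jointly: the
expected frequency of optimal codons (Fop) is met exactly by giving each
amino acid's optimal codon probability `q = target_fop * 20 / n_opt`, and
the expected synonymous-third-position GC (GC3s) is met by tilting the
non-optimal codons with a softmax weight on third-base GC whose
temperature is solved by bracketed root finding.  Infeasible target pairs
(e.g. high Fop with low GC3s under a GC-ending optimal set) raise an error
listing the attainable range rather than silently missing the target.  The
shipped optimal set is synthetic (one GC-ending codon per degenerate amino
acid); real analyses must supply the host's empirically determined optimal
codons — the package never infers them.

**Insertion mechanics.** A full-length element (FLE) integrates as
`TSD + element + TSD`, the TSD copied from the insertion site and
identical on both flanks; solo LTRs (the product of intra-element
recombination) are a single LTR with the same flanking duplication;
truncated copies are FLEs with an internal chunk or one terminus plus a
margin deleted.  Divergence is applied per copy before planting: each
site substitutes independently with probability `age` (expected
substitutions/site, uniform replacement; an optional GC-bias parameter
emulates GC-ward mutation pressure, and optional geometric indels — mean
3 bp at 5% of the substitution rate — plus a dinucleotide-slippage mode
cover indel-driven divergence).  The two LTRs of an FLE therefore diverge
from each other with expected per-site difference
`2a(1-a) + (2/3)a²` at age `a` — the quantity the intra-element identity
statistic estimates.  Flanking TSD copies are written once and not
mutated, so truth TSDs remain identical; this models recent insertions,
for which the TSD pairing rule was designed, and keeps the catalog's
exact-match TSD rule meaningful.

**What the generator does not model** (and what passing tests therefore do
not show): nested insertions, recombination between families, host genes
and transcriptome structure, phylogenetically correlated divergence (each
copy diverges independently from the consensus), TSD decay in old
insertions, and sequencing/assembly error.  Expression counts are
negative-binomial per family (Poisson in the infinite-dispersion limit,
optional zero inflation); they model mapped-read totals only.

## Insertion cataloguing

The scanner finds copies of a probe (an LTR, an ITR, or the internal
region) by 12-mer seeding on both strands, clustering seeds by diagonal,
and aligning each candidate window with exact local Smith–Waterman at
pinned scores (match +1, mismatch −1, gap −2).  Identity is matches over
aligned columns, gap columns counted as mismatches.  A window may contain
several copies, so alignment is iterated with the reported segment masked
until the score falls below the floor of a minimally acceptable hit.
Internal-region probes use a lower coverage floor (25% of probe length)
than terminal probes (80%) so truncated copies still report internal hits
while random seed matches cannot extend far enough to qualify.

Hits are clustered into loci (gap ≤ 150 bp; an FLE's terminal hits are
bridged by its internal hit).  Within a locus, two same-strand LTR hits —
or a +/− ITR hit pair, ITRs being strand-symmetric — spaced within
[0.5×, 1.5×] of the consensus internal length form an element; candidate
pairs are ranked by target-site-duplication (TSD) presence, then by
spacing closest to consensus.  The call is FLE when less than 50 bp of
internal sequence is missing, truncated otherwise.  A lone LTR with no
adjacent internal sequence is a solo LTR.  TSD detection requires an exact
flanking duplication (longest k in the family's length range) but
tolerates ±5 bp of alignment-endpoint slop; an element at full-length
spacing without a detectable TSD keeps its FLE call with a `no_tsd` note,
since terminal mutations can shift alignment ends.  A deletion can
separate a surviving terminus from the internal remnant by more than the
cluster gap; two adjacent fragments of the same family are rejoined into
one truncated record when an identical duplication flanks their combined
span — the same evidence used to pair termini in the first place.  Hits
abutting a contig edge are excluded from copy-number counts and listed
separately.

Family delimitation follows the 80-80-80 rule: two repeats are the same
family when they align at ≥80% identity over ≥80% of the shorter sequence
with ≥80 aligned bp; aligned length under 80 bp yields an undecidable
verdict, never a split.  Pairs failing the full-length rule but sharing
≥98% identity over the terminal 160 bp of their 3′ ends are one family
flagged as subfamilies (the signature of recombinant/chimeric subfamily
structure).

## Divergence and diversity

Intra-element LTR identity is the percent identity between an element's
own 5′ and 3′ LTRs (global alignment at the same pinned scores); gap
columns count as mismatches unless `exclude_indel_columns`, the dual
reporting used when slippage indels dominate the differences.  Nei's π is
the average pairwise per-site difference over a cohort alignment,
uncorrected for multiple hits (raw π, appropriate at the small divergences
involved): complete deletion removes columns gapped in any row (one shared
L); pairwise deletion uses each pair's own gap-free columns.  Both modes
ship because the choice is a genuine free parameter; complete deletion is
the default.  Cohorts are All / FLE / Solo, with one LTR per FLE — the 5′
LTR by strand, falling back to the 3′ — and every solo LTR; cohorts with
fewer than two sequences are omitted.  Tip-age classification reads a
Newick tree and calls a tip ancient when its terminal branch length is
≥ 0.05 substitutions/site (boundary inclusive); tips without a branch
length are reported unclassified, never assumed zero.

## Codon-usage statistics

Wright's effective number of codons is computed from per-amino-acid codon
homozygosity `F = (n·Σp² − 1)/(n − 1)` for amino acids observed at least
twice, averaged within degeneracy classes, with
`Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆`, capped to [20, 61].  When the
three-fold class (Ile) is unobserved, `F̄₃ := (F̄₂ + F̄₄)/2`; any other
missing class requires ≥18 observed codons and is then dropped from the
sum.  Both rules log their firing.  Six-fold amino acids are their own
class, never split 2+4.  GC3s is the G/C fraction at third positions of
degenerate-amino-acid codons (Met, Trp, stops excluded).  Fop divides
optimal codons by **all** sense codons; the variant restricted to amino
acids possessing an optimal codon exists behind a flag and logs its use.
Codons containing N are dropped (logged); stop codons are never counted;
codons straddling a region boundary (e.g. the overlap of a gag–pol
frameshift) are labelled masked and excluded.  The repetitive-region mask
removes tandem runs of motif length 1–6 spanning ≥24 bp at ≥90% purity —
the exclusion applied to CDS regions before expression counting, because
low-complexity tracts attract reads from unrelated transcripts.

## The selection battery

Three lines of evidence are separated: mutation pressure (GC3s regressed
on non-coding GC, overall and per group, with leave-one-out sensitivity
because a single outlying family can carry a group's fit), translational
efficiency (Fop regressed on copy number and on expression reads), and
translational accuracy (per-family Fisher exact test of optimal/non-optimal
codon counts in functional-domain versus non-domain regions).  R² is the
squared Pearson correlation of an ordinary least-squares fit; groups of
two are reported ordinally, smaller groups skipped with a reason.
Expression regressions are emitted on both raw and log10(reads+1) scales —
counts span orders of magnitude, so the default report uses log10, but the
raw scale is retained because family-level efficiency signals can be
scale-dependent.  The Fisher p-value is computed by full enumeration of
the hypergeometric support in exact rational arithmetic, two-sided by the
minimum-likelihood rule; a small p with domain Fop *lower* than non-domain
Fop is significant heterogeneity but is not evidence of accuracy
selection, so direction is reported separately and
`accuracy_consistent` requires both direction and significance.  No
multiple-testing correction is applied; the report carries the number of
regressions run.

A bundled reference table (`tescope.datasets.load_sros_te_families`)
carries the published per-family statistics of the 19 fully characterised
*S. rosetta* TE families so the regression battery can be exercised on
real numbers; for DNA transposon families whose 5′ and 3′ ITR counts
disagree, the copy-number column holds a single point value inside the
published range.  The table's printed group means contain small internal
inconsistencies (the transposon-column means as printed disagree with the
means of their own cells); the package always recomputes means from the
per-family values.

## Numerical and testing choices

All randomness flows through one seeded NumPy generator; identical seed
and configuration give byte-identical genomes, truth files and pipeline
outputs (asserted in tests).  Alignment scores are pinned so scanner
results are reproducible and directly comparable to the independent
Smith–Waterman oracle the tests carry.  Oracle checks run π against a
brute-force double loop (exact), the Fisher p against an independent float
enumeration (|Δp| ≤ 1e−12) and scipy, and OLS R² against a direct-sum
Pearson computation (1e−12).  Simulation-based checks use a ~175 kb
three-family genome (34 insertions, ages ≤ 0.02 substitutions/site) for
insertion recovery, and 2,000 null replicates of 300+300 codons for the
domain test's type-I calibration — sizes chosen so the whole suite runs in
about a minute while leaving the statistical assertions well-powered.

Known limitations: the catalog is not designed for nested or overlapping
insertions (overlaps are resolved greedily by identity and flagged); the
cohort aligner anchors unequal-length rows to the longest sequence and
discards insertions relative to it, which is adequate at percent-level
divergence but is not a full multiple aligner; solo-LTR calls for ITR
families are not a biological category and such fragments are reported as
truncated; and the generator's feasibility region for joint Fop/GC3s
targets depends on the optimal-codon set supplied.
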