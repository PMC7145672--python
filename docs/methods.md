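# Methods

## Element model and classification

An LTR retrotransposon is modelled as `TSD + LTR + core + LTR + TSD`: the
core carries the three enzymatic domains (integrase IN, reverse
transcriptase RT, RNase H RH) whose strand-normalised order assigns the
superfamily — IN–RT–RH is Copia, RT–RH–IN is Gypsy.  A candidate core is
accepted only when, after discarding homology hits at e-value ≥ 1 × 10⁻²⁰,
exactly one hit remains per domain; candidates with a missing or
duplicated domain are rejected with a reason code rather than repaired,
and mixed-strand domain sets are kept but left unclassified.  Validated
cores propagate to other genomes through tabular homology hits filtered at
query coverage ≥ 0.80 and e-value < 1 × 10⁻²⁵; surviving hits that overlap
by at least 1 bp on the same scaffold and strand are merged (strand-aware,
to avoid chimeric plus/minus cores; merging is idempotent and
order-independent).

Families follow the 80/80/80 criterion — ≥ 80% identity over ≥ 80% of the
shorter sequence with ≥ 80 aligned bp; both the fraction and the absolute
floor must hold.  The published clusterings of this kind have used
mean-shift engines; here the same predicate drives deterministic
single-linkage connected components, which makes family membership a pure
function of the pair graph.  The representative is the longest member,
ties resolved to the lexicographically smallest id, and families are
numbered per genome by superfamily and representative position.

## LTR resolution

LTR sequences from complete elements are searched genome-wide (identity
≥ 0.80 over ≥ 0.90 of the query; hits with gaps strictly under 100 bp are
merged).  Each resulting locus is tested for a similar self-copy
(identity ≥ 0.80 covering ≥ 0.90 of the LTR) within 30 kb of flank on
either side: found → *paired*, with the partner recorded mutually.
Unpaired loci are screened for a TSD: an identical k-mer (k = 7 down to 4,
leftmost in the 5′ flank on ties — a deterministic convention) present in
the 20 bp flanking both sides.  TSD found → *solo*; none → *nonsolo*;
loci failing a self-homology screen (shorter than 50 bp or
near-homopolymeric) → *discarded*.  Discarded loci are reported separately
from the three-class total.  Class ratios are computed by exact rational
division and rounded half-even to two decimals; a zero paired count is an
error, not a zero ratio.

Note that scanning 20-mers for any shared 4-mer has a substantial chance
hit rate on random sequence (about two thirds of random flank pairs share
one); the classification inherits this property of the published rule, and
the simulator therefore scrubs chance k-mers from the flanks of planted
nonsolo elements so their labels are unambiguous ground truth.

## Dating

Two LTRs of one element are globally aligned (internal Needleman–Wunsch,
match +1 / mismatch −1 / gap −2, anti-diagonal vectorised; an adapter
accepts externally aligned pairs).  Gap columns are excluded; transitions
P and transversions Q over the remaining sites give the
Kimura-2-parameter distance d = −½ ln((1−2P−Q)·√(1−2Q)).  Pairs with a
non-positive log argument are flagged saturated and excluded with a
reason.  Age conversion is t = d/(2r) with r bracketed by 4 × 10⁻⁹ and
5 × 10⁻⁹ substitutions/site/year; the interval uses the widest bracket
(oldest at the slow rate, youngest at the fast rate).  This is the formula
that reproduces every printed conversion of the motivating survey
(0.06 → 7.5 Ma at 4 × 10⁻⁹, 0.075 ← 7.5 Ma at 5 × 10⁻⁹, …).  "New"
elements require exactly P = Q = 0, not a tolerance.  Age histograms use
left-closed 0.01-distance bins (an edge value belongs to the right-hand
bin, guarded against float error by a 10⁻⁹ nudge) and groups under 100
elements are flagged low-confidence.

## Relatedness network and deletion evidence

Each unpaired LTR is queried against the full LTR collection (self
excluded); a hit qualifies at identity ≥ 0.90 over ≥ 0.90 of the query,
the best hit maximises the number of matching columns (ties → higher
identity, then lexicographically smaller subject), and only mutual pairs
become edges.  The edge set is a matching by construction; genome-pair
edge counts form a symmetric matrix with within-genome edges on the
diagonal.

Deletion calls (VCF, SVTYPE=DEL) shorter than 100 kb are assigned to a
complete element when each covers ≥ 80% of the other; if several
overlapping elements qualify, the highest minimum reciprocal fraction
wins.  Per-sample support comes from AO/RO allele-observation counts;
records carrying only genotypes or likelihoods are refused rather than
guessed.  Support ≥ 0.80 is homozygous, ≥ 0.20 hemizygous (closed bounds,
reading "at least" literally), below that the assignment is dropped.
Insertion-versus-deletion polarity is not resolved.

## Windows, pericentromeres, and activity models

Scaffolds ≥ 100 kb are tiled in non-overlapping windows of up to 1 Mb
(1 Mb by default; sub-1 Mb scaffolds form a single window; the trailing
partial window is kept).  Features land in the window containing their
start coordinate.  Genic fraction is the unioned, clipped gene coverage.
Windows strictly below the genome-median genic fraction are pericentromere
candidates; the maximal consecutive run per scaffold is reported, and the
final selection is left to configuration since a bare median threshold
necessarily flags about half the windows.  Correlations are Spearman rank
tests.  Gene-content binning uses six left-closed 10% bins over [0, 60%);
windows at or above 60% are excluded.

Activity typing regresses bin counts on time-toward-the-present in three
age segments — old (0.06, 0.20], middle (0.02, 0.06], recent [0, 0.02] —
and reads the model from the slope signs: both middle and recent
non-negative → model a (sustained growth); middle decline with a recent
rebound → model c (final burst); otherwise model b (arrest/decline).  The
0.06 changepoint is where published genus-wide histograms stop agreeing
across species; the 0.02 recent boundary is this package's formalisation
of "recent burst" and both are configuration-exposed.  Two total-LTR
metrics are exported side by side rather than choosing between them: the
stack total (paired + solo + nonsolo) and the insertion-equivalent total
(paired + 2·(solo + nonsolo), counting each excision product as one lost
insertion).

## The synthetic-data generator

`simgenome` emulates the input universe: random-background scaffolds
(default 4 scaffolds totalling 5 Mb, GC 0.38), 400 genes of 1–6 kb, and
300 elements from 12 families (Copia and Gypsy alternating across the ten
standard lineages).  Element cores average 2,590 bp; LTRs are 0.2–2 kb;
TSDs are uniform random 4–7-mers, identical on both sides.  Ages are drawn
from the cohort set {0, 0.02, 0.06, 0.12} K2P units; each LTR copy evolves
age/2 from the element ancestor under the exact K2P substitution matrix
(transition fraction 0.5, no indels), so the process composes correctly
and the pairwise distance is unbiased for the planted age.  45% of
elements are excised to solo LTRs (TSDs kept) and 20% truncated to
nonsolo LTRs (no TSDs), echoing the class proportions of genus-scale
surveys.  Deletion calls cover half of the complete elements with support
fractions from {0.1, 0.25, 0.5, 0.9, 1.0} over 10 samples, 20 reads per
locus.  All draws flow from one seeded generator; fixed seed ⇒
byte-identical outputs.

Two placement rules keep the planted truth well defined: same-family
elements are kept ≥ 32 kb apart, because a solo LTR within 30 kb of a
same-family paired LTR would be *legitimately* paired under the published
flank rule; and every family retains at least one complete element
(statuses are swapped, preserving global proportions), because solo and
nonsolo copies are only discoverable through homology with a paired
family member.  An optional spatial mode concentrates elements and
deletion activity into a gene-poor middle third per scaffold to emulate
pericentromeres.

What the simulator does *not* emulate — indel evolution, nested
insertions (a flag exists but defaults off), mutation-spectrum biases,
segmental duplication, assembly gaps — bounds what passing tests show:
recovery rates here measure the logic of the pipeline, not its robustness
to the full noise structure of real assemblies.

## Problem sizes and numerical choices

Recovery checks run on a 5 Mb genome with 300 elements and on 200
LTR-pair replicates per age cohort at 500 bp per LTR — sizes at which all
sampling errors are comfortably below the asserted tolerances (per-cohort
mean dating error < 0.01; ≥ 95% status recovery).  Copy search uses a
sorted 2-bit 13-mer index with seed-and-verify: seed diagonals cluster
within 0.4 query lengths and candidates are verified by infix alignment
(edlib), which at the 0.80 identity floor tolerates the ≤ 0.15 planted
divergence with wide seed margins.  Alignment identity is matches over
alignment columns; query coverage is aligned query bases over query
length.  Degenerate inputs (empty query sets, scaffold-edge flanks,
constant correlation fields, empty histograms) are either defined
explicitly above or raise immediately with a named cause.
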