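# Methods

This note documents the models implemented in `rmsim`, the defaults and why
they were chosen, the numerical conventions, and what the synthetic-data
generator does and does not emulate.

## Digestion model

Each contig is treated as an independent linear molecule. Cut sites are
located by overlap-tolerant scanning: an anchored lookahead regex tests
every offset, so overlapping instances (e.g. HhaI's GCGC inside GCGCGC) are
all found. Character classes are built from concrete bases only, so an `N`
in the genome never matches any motif position — a site containing `N` is
conservatively not a cut site. Non-palindromic motifs are additionally
scanned as their reverse complement; a bottom-strand match at offset s cuts
the top strand at s + (|m| − cut_offset).

Coordinates are 0-based half-open throughout; a cut at position p falls
between bases p−1 and p on the top strand. Only top-strand cut geometry is
modelled: the few-bp sticky-end overhang does not move fragment
coordinates, and appears only as optional adapter-overhang sequence in read
construction. Read-level output for quantification purposes is insensitive
to this simplification, and it keeps coordinates testable against a naive
oracle.

Candidate fragments are all ordered cut pairs (a, b) with b − a inside the
enumeration window and at most `max_internal` cut sites strictly between
them. Each carries the survival probability

    Pr(fragment) = 1 if c = 1 and i = 0, else c²(1−c)^i

with a single cut efficiency c shared by all enzymes (per-enzyme values are
accepted through the API but default equal). `max_internal` defaults to 5
because the i ≥ 6 terms are bounded by c²(1−c)⁶ and contribute negligibly
at any realistic c. The partial-digestion probability model is stated for
palindromic motifs; we apply the same formula to non-palindromic motifs as
a pragmatic extension, since both boundary cuts and internal non-cuts are
still per-site Bernoulli events under the top-strand geometry.

Contig-terminal pieces (from the contig end to the first/last cut) are
excluded by default: they lack one enzyme-generated adapter-boundary site,
which the model requires for a fragment to enter the library. With
`ddrad_strict`, fragments whose two ends carry only one and the same enzyme
are removed, mirroring double-digest adapter chemistry.

Type IIB (isolength) enzymes excise a fixed window
[s − upstream, s + |m| + downstream) around each recognition match (offsets
swapped for bottom-strand matches); every fragment has i = 0 and p = c².
Windows crossing contig bounds are dropped, and overlapping excisions are
all emitted independently, consistent with per-site independence.

## Size selection

Per-genome fragment weights p are scaled by the genome's proportional
abundance (abundance-table values are relative genome-copy numbers, not
read fractions) and summed by length into the digest distribution D(x).
The Gaussian envelope is anchored at a length where it touches D:
k = D(anchor)/φ(anchor; μ, σ), and the selected distribution is the
pointwise minimum S(x) = min(D(x), k φ(x)). The minimum is the reading of
"intersection" consistent with a physical size cut: the envelope can only
remove fragments, never inflate a length class beyond what digestion
produced (dominance S ≤ D is asserted in tests). Lengths are integers and
the density is evaluated at integer lengths without continuity correction.

The default anchor is round(μ − σ): with the μ = 150/σ = 50 default this
puts the anchor at 100 bp, the left shoulder of a typical narrow gel-based
selection. Whether the anchor should track μ − σ or stay fixed at 100 bp is
genuinely open, so it is an explicit parameter (`anchor_length`), with
"auto" falling back to the supported length nearest μ − σ when D is zero
there. A custom length-weight JSON (e.g. extracted from real alignments by
`extract_length_distribution`) replaces the Gaussian via the same anchored
pointwise minimum.

The read budget n is divided over the size-selected distribution
proportionally: fragment f of length x gets probability
q_f ∝ weight_f · S(x)/D(x). Literal equal-per-fragment division would erase
the abundance signal the quantification path is designed to recover, so
"divided evenly" is implemented as proportional allocation normalised to
total n. Two rounding modes exist: seeded multinomial sampling (default)
and deterministic largest-remainder apportionment (floor(n q) plus one unit
to the largest fractional remainders, ties to the lowest index), which
exists so tests can assert exact counts. Both conserve the budget exactly.

## Read construction and errors

Read 1 sequences the (oriented) insert 5'→3' into the read-1 adapter;
read 2 sequences the reverse complement into the read-2 adapter. Inserts
shorter than the read length produce adapter read-through; templates still
shorter than the read length are padded with `A` — deterministic and
visibly artificial. For double-digest fragments read 1 starts at the
forward-enzyme end (first motif on the command line); same-enzyme fragments
orient uniformly at random. Qualities are sampled read-by-read, uniformly,
from a donor FASTQ pool (one pool reused for both mates if only one file is
given; constant Q40 without a profile). Errors are substitutions only —
each base flips to one of the other three with probability 10^(−Q/10); `N`
and pad positions are untouched. No indel, chimera or PCR model is
included: PCR length bias in particular is a known influence on RMS
libraries but no quantitative model is adopted here.

Read names are `genome:contig:start:end:orientation:serial/1|2` — a
versioned provenance dialect that lets the quantification path recreate
source fragments without alignment. `:` is therefore reserved and rejected
in genome/contig ids.

## Cut-efficiency estimation

For a fully digested inner fragment [a, b) and the observed fragment
extending it by exactly one cut site ([a′, b) or [a, b′)), expected counts
are proportional to c² and c²(1−c), so the ratio r = inner/outer satisfies
c = (r − 1)/r. Defaults, where the procedure leaves choices open:

- aggregation of pair ratios into r̂ uses the **median** (mean available),
  robust to low-count outer fragments;
- inner fragments must have count ≥ 5 (parameter) to stabilise ratios;
- the estimation window is 100–450 bp (parameter) — lengths least
  constrained by size selection;
- only ratios r > 1 are informative under the model; pairs with
  unobserved outers are treated as absent (evidence of complete digestion),
  not as r = ∞ observations. No pairs at all returns c = 1 exactly; pairs
  existing but none with r > 1 returns an explicit `inestimable` status
  rather than a number.

Estimation runs on the recreated-fragment table *before* the internal-cut
filter (the encompassing i = 1 fragments are precisely what it needs), or
on the simulator's own fragment-count table.

## FLTR quantification

Fragment recreation keeps a read pair when (provenance mode) its interval's
endpoints coincide exactly with expected cut positions, or (SAM mode) both
mates are mapped to the same reference in forward/reverse orientation with
MAPQ > 0, and in both modes drops fragments spanning an expected internal
cut site, since partial digests affect depth unpredictably.

Depth is **mean depth per distinct expected fragment**:
d(t, L) = (total reads on taxon t's length-L fragments) / (number of t's
enumerable i = 0 fragments of length L), counting zero-read expected
fragments in the denominator. This is the reading under which d is
proportional to abundance when fragment multiplicities differ between taxa;
a per-length-total denominator would conflate multiplicity with abundance.

The ratio matrix averages d(i, L)/d(j, L) over lengths where both taxa have
expected fragments and d(j, L) > 0, unweighted across lengths
(a depth-weighted option exists but is not the default). Column scaling is
division by the reference row entry R[k, j], where k is the taxon with the
most defined relationships (ties: first in input order): this makes every
entry a ratio-to-reference, and makes exact recovery provable — if
d(t, L) = a_t·s(L) then every defined scaled entry in row i equals a_i/a_k,
so the row mean is exact regardless of s and of per-taxon length supports,
provided each taxon co-occurs with some reference-connected column. Taxa
whose columns cannot be scaled and that share no length with any scalable
column are reported as **unquantified** rather than imputed; chaining
ratios along co-occurrence paths is available behind `impute_paths=True`
(off by default, since multiplied ratios compound noise).

Mean- and median-depth baselines are computed over the same expected
fragment populations and normalised to sum 1; they are the comparison
points FLTR is designed to beat when length bias interacts with per-taxon
fragment-length profiles.

## Synthetic data

The fixture generator emulates community references at desk scale: i.i.d.
bases at a target GC (no repeats, no gene structure, no shared homology
between genomes), uniform or log-normal(μ = 0, σ = 1) abundances, and
Gaussian per-position quality profiles clamped to [0, 41]. Planted-site
genomes insert exact motif instances at fixed spacing and scrub accidental
occurrences of the same motifs (both strands), so expected fragment lengths
are known in closed form. Because synthetic genomes share no sequence,
multi-mapping — a major real-data effect the MAPQ-0 filter exists for —
never occurs in pure simulation; passing tests therefore validate the
probabilistic machinery and the estimators, not robustness to conserved
regions between closely related strains, reference/sample mismatch, or
PCR/GC bias, none of which the generator produces.

Test and benchmark problem sizes are chosen to exercise the estimators'
asymptotics while staying desk-scale: the end-to-end check uses 10 genomes
of 100 kb at log-normal abundances with EcoRI/MseI, c = 0.9, μ = 150/σ = 50
and 2×10⁵ read pairs; digestion oracles run on 50 random genomes ≤ 5 kb;
error calibration uses 10⁶ bases per quality value.

## Numerical conventions and degenerate inputs

- One master seed drives every stream; child streams are spawned through
  `numpy.random.SeedSequence`, so outputs are byte-reproducible.
- Largest-remainder ties break to the lowest fragment index (stable sort).
- Genome ambiguity codes (R, Y, …) are folded to `N` with a warning;
  non-IUPAC characters are a hard error naming the record.
- Empty digest distributions, anchors with zero weight, and communities
  whose size selection removes every fragment raise errors rather than
  returning empty output.
- Abundances are normalised on load; zero or negative values are rejected.
- FLTR needs ≥ 2 taxa; a ratio matrix with one taxon is an error, and an
  all-disconnected matrix returns everything unquantified except the
  reference.

## Known limitations

Methylation sensitivity, nicking, star activity and circular chromosomes
are not modelled in digestion; no PCR duplicate/GC model; no indel errors;
no taxonomic classification (inputs are assumed assigned to references);
SAM-mode recreation trusts the aligner's mate pairing and applies only the
orientation and MAPQ-0 filters used in the quantification model.
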