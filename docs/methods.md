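# Methods

This note documents the models and procedures implemented in centroscan,
the parameters that matter, the design choices made where the underlying
methods are underspecified, and what the synthetic test bed does and does
not establish.

## Coordinate and data conventions

All internal coordinates are 0-based half-open; conversion to and from
1-based closed GFF3 happens only at the I/O boundary, so no stage ever
reasons about mixed conventions. N bases are legal in input but never
match in any scan. Contact matrices use genome-global bin indexing with
per-chromosome offsets, so cis and trans blocks are addressed uniformly.
Configuration is one key-value (YAML) file; CLI flags override file values
and every run logs the fully resolved parameter set, because most calls
here are threshold-sensitive.

## Telomere detection and rescue

A tandem run is a maximal chain of unit-length frames (6 bp for the
CCCTAA/TTAGGG unit), each within a per-unit mismatch budget, with no
insertions or deletions between frames. Defaults: scan window 1,000 bp
from each terminus, minimum 5 copies, mismatch budget ⌊u/6⌋ = 1 per unit.
These are deliberately permissive: the detection outcome on both real-scale
and synthetic chromosomes is insensitive to the window over a wide range,
and all three knobs are exposed. The 3' end is scanned in the
reverse-complement frame, which makes detection exactly strand-consistent.

Read extraction requires 10 tandem copies (60 bp) by default — enough to
make chance hits in random sequence negligible — and reverse-complements
reverse-form reads so the library shares one orientation. Patching matches
the terminal `anchor_len` (500 bp) of the deficient end against each
library read by exact seed (21 bp) plus full-anchor identity
(default ≥ 0.95), requires the read's distal portion to end in a telomere
array, and splices on the longest qualifying extension (ties: higher
anchor identity, then smallest read id, for determinism). This anchored
extension is a deliberate simplification of a read-level rescue workflow:
it does not re-assemble the extracted reads, so it rebuilds an end exactly
only when some single read spans from the anchor to the true terminus —
which the tests verify on error-free synthetic reads.

## k-mer consensus accuracy

Both K_total and K_only count *distinct* canonical k-mers (the canonical
form is the lexicographic minimum of a window and its reverse complement;
windows containing N are skipped). Distinct counting is the only reading
under which k-mer totals in the tens of millions arise from a ~47 Mb
assembly, and it is what the error model assumes. A read k-mer present at
any multiplicity rescues an assembly k-mer; no minimum-multiplicity filter
is applied (the threshold exists as a parameter). k defaults to 17.

The error model E = 1 − (1 − K_only/K_total)^(1/k) treats each unsupported
k-mer as evidence of an error under the approximation that each base error
corrupts k overlapping k-mers. Note that with the published inputs
(4,471 / 34,238,721, k = 17) the formula yields QV 51.1454 and accuracy
99.9992%; the implementation reports exactly what the formula gives.

The genome-size estimate divides total k-mer instances by the homozygous
peak depth. At desk scale the multiplicity histogram is lumpy because
coverage is correlated over read-length scales, so the peak is taken as
the argmax of a 5-wide smoothed histogram (multiplicities ≥ 2) refined by
the centroid of the peak's own mass (0.6–1.5 × the argmax). The estimate
is declared undefined when singleton k-mers outnumber all higher
multiplicities combined, which is the signature of unit-coverage input.
Heterozygosity modelling (two-peak fitting) is out of scope.

## Coverage anomalies and mapping rates

Bins are tiled and non-overlapping (10 kb default); the final partial bin
is normalized by its true width, so binning conserves aligned base pairs
exactly. The default anomaly rule is the absolute one used at publication
scale (depth < 80 against a genome-wide mean of 248); a fraction mode
(default 0.32 ≈ 80/248) is provided because the absolute constant is
depth-specific and synthetic runs are shallower. Flagging is monotone in
the threshold by construction. MQ0 flagging marks bins where at least half
of the overlapping reads (and at least one read) map with quality 0 — the
signature of a collapsed repeat. Mapping-rate percentages are rounded
half-up to two decimals.

## rDNA copy number

Unit matching is ungapped seed-and-extend (31 bp exact seeds, stepped
scan, per-diagonal trimming to the maximal-scoring segment at ≥ 90%
identity, ≥ 100 bp), with overlapping hits merged per read before lengths
are summed, so a tandem array contributes its footprint exactly once.
copies = round(L_total / (C × U)); nearest-integer rounding reproduces the
published worked example (102,247,170 / (248 × 5,701) = 72.32 → 72). C
defaults to the coverage stage's genome mean so depth has a single source
of truth. The terminal check reports the fraction of each terminal window
covered by unit hits and flags ends above 50% — the signature of an
rDNA-blocked telomere. The estimate is depth-invariant: doubling simulated
depth doubles L_total and C together.

## Centromere prediction

The expected cis contact at bin distance d is the mean observed count on
that diagonal within the chromosome, so cis OE is self-normalizing: the
per-diagonal mean is exactly 1 wherever defined (the tests require 1e−9).
Expectations below 1e−9 yield OE 0 rather than a division. The trans
expectation is the global trans mean. Each bin receives a trans-intensity
score (mean OE over trans partners) and a long-range cis score (mean OE
over cis partners at ≥ `d_min` bins, default 50 — on chromosomes shorter
than `d_min` bins this track is undefined and the fusion falls back to the
trans track alone).

Per chromosome, the combined score is the rank average of the two tracks,
smoothed by a 3-bin moving mean. The peak bin seeds the call (ties break
toward the chromosome middle, then the lower index); the region grows
while the median-centred score stays above `peak_fraction` (0.5) of the
peak's excess over the median. Growth is measured against the median
rather than zero because rank scores have a ~0.5 background level; a
threshold taken on the raw scale would flood the chromosome. A peak that
does not rise above the median is a no-call, not an error. The call is
retained when at least 2 of the 4 sequence features agree over the
candidate region, each as a strict inequality against the chromosome mean:
GC below, gene density below, repeat density above, transcription below.
Calls whose midpoint falls in the outermost 5% of the chromosome are
annotated low-confidence — OE prediction is known to be unreliable for
edge centromeres, and the synthetic tests exercise exactly that failure
mode.

Arm classification uses the Levan normalization s + l = 10 and is driven
by the d = l − s intervals alone ([0, 2.5] metacentric, (2.5, 5]
submetacentric, (5, 7.5] subtelocentric, (7.5, 10) acrocentric); r = l/s
is reported alongside. d alone is used because the published karyotype
rows are all consistent under d but not under a strict joint (d, r) rule
at the r = 3.0 boundary. Classification is mirror-invariant.

## Centromeric LTR annotation

Monomer hits come from the same seed-and-extend core (21 bp seeds,
identity ≥ 0.80), trimmed per diagonal so truncated copies are reported
with proportionate consensus coverage; hits at ≥ 80% coverage are
"complete", [40%, 80%) "shorter", overlapping hits reduce to the best
score. These cutoffs are documented stand-ins — the complete/shorter
distinction has no published thresholds — and are configurable.

Pairing is greedy left-to-right among same-strand hits with separation in
[1 kb, 15 kb] and LTR-LTR identity ≥ 0.85, compared base-aligned through
shared consensus coordinates (so trimmed hits compare correctly). Paired
elements are checked for: identical flanking duplications of 4–6 bp (TSR);
a PBS motif within 20 bp downstream of the 5' LTR (reported not-found
unless a motif is supplied, since no motif is published for these
elements); a ≥ 10 bp purine run within 30 bp upstream of the 3' LTR (PPT);
and the four internal domains in GAG→INT→RT→RH order. Domains are matched
as nucleotide marker sequences, not protein profiles — sufficient for
structural verification at desk scale, and a documented limitation for
diverged real elements. Every hit lands in exactly one element (paired
consumes two, solo one), and element counts are strand-symmetric.

## Synthetic data generator

The generator emulates the structure the analyses assume, at desk scale:
3 chromosomes of 500/400/300 kb (the real assembly's 13 chromosomes of
2.6–5.3 Mb, scaled so every stage runs in seconds), 56% GC background,
30-unit CCCTAA/TTAGGG telomere caps, one 30 kb centromere per chromosome
at 40% GC carrying paired (internal ≈ 3 kb, 5 bp TSR, PBS, PPT, ordered
domain markers) and solo 427 bp LTR monomers, a terminal tandem array of a
5,701 bp rDNA unit (10 copies) on the smallest chromosome, genes tiling
the arms at ~50% density and absent from centromeres, RNA depth near zero
over centromeres, 30× long reads (8 ± 1.5 kb, 0.1% substitutions) with a
0.3× coverage dip and an MQ0 region planted, and contact matrices with
cis decay 100/(d+1), unit trans background, 5× centromere-centromere
enrichment and 10% multiplicative log-normal noise. Solo LTRs are planted
on the minus strand with sub-kilobase spacing so the greedy pairing rule
is exercised against a truth in which solos can never legally chain.

One root seed drives per-component derived generators, so adding a
component never perturbs the others and all outputs are byte-reproducible.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: realistic long-read error profiles
(homopolymer indels), diploid/dikaryotic haplotype structure, Hi-C
read-pair mechanics (matrices are drawn directly from the expectation
model), rDNA intergenic-spacer haplotype variation (units are exact tandem
duplicates by default, with an optional per-unit substitution rate), and
sequence divergence between LTR copies beyond i.i.d. substitutions.

## Numerical choices and degenerate inputs

Nearest-integer rounding for rDNA copies; round-half-up for percentages;
OE division only where the expectation exceeds 1e−9; deterministic
tie-breaks everywhere a maximum is taken (documented per stage above).
Degenerate inputs are handled explicitly: empty k-mer sets and all-zero
contact matrices are fatal; an end that already has a telomere refuses
patching; an empty read library yields an unchanged genome with a
"no patch" report; zero matched rDNA length yields zero copies; a
uniform contact matrix yields no centromere call.

## Problem sizes

The default test suite and the acceptance script run the full synthetic
stack at the scales above (1.2 Mb genome, ~4,500 reads, 120 Hi-C bins,
10-seed sweeps for the stochastic properties), completing in about a
minute on one CPU. These sizes are the package's chosen study conditions
for the synthetic properties; the published-figure checks are pure
arithmetic on the published inputs and run in milliseconds.
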