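# Methods

## Model and scope

The package analyses the 5-HT2C receptor editing cassette: five editable
adenosines (A, B, E, C, D) inside a 21-nt exonic core, reconstructed here
from the unedited allele-specific hybridisation probe
`TAGCAATACGTAATCCTATTG` with 1-based site offsets A:6, B:8, E:12, C:13,
D:18 and reading frame starting at offset 6 (in-frame codons
ATA·CGT·AAT·CCT·ATT). Sites A/B occupy codon positions 1/3 of the first
codon, E/C positions 1/2 of the third, D position 1 of the fifth; edited
bases are read as G and translated by the standard genetic code, giving
the 32-isoform / 24-protein combinatorics. The five published
edited-isoform probes validate the reconstruction at every site position;
probes differ from the core only at their termini (one probe carries an
unexplained extra terminal base), so only the five site offsets are
treated as authoritative.

Two published typographical inconsistencies in the isoform table were
resolved from internal evidence: the D-only ("INV") row's pattern is
rendered `AnA-nnn-AAn-nnn-Gnn` (the printed pattern duplicated the
unedited row, contradicting both its protein and the requirement that the
32 patterns be distinct), and the second "VDV" row is taken as the
A,B,E,D-edited set, as both its pattern and protein demand (the printed
"ABEC" label would encode VGI, a set already listed).

## Demultiplexing

A read is assigned by matching, on the read or its reverse complement,
the adaptor-A prefix (≤ 1 mismatch) followed by the closest group barcode
(≤ 1 mismatch; the two published barcodes differ at 6 of 10 positions, so
single-mismatch assignment is unambiguous) followed by the forward primer
(≤ 2 mismatches — primer location after the barcode is required, since a
read without the cassette cannot be called). Matched reads are reoriented
to sense and stripped of adaptor, barcode, primers and, when present, the
3′ adaptor-B/reverse-primer tail. "Unassigned" is a status, never an
error, and every input read is accounted for in the run manifest.

## Quality screen

The published screen is reimplemented as an accept/reject filter with its
two stated thresholds: mean per-base error probability ≤ 0.025 and error
probability ≤ 0.02 for each of the `end_window = 2` bases at either end
(Phred p = 10^(−Q/10)). The original tool also performed windowed
trimming whose parameters were not published; reads here are already
primer-trimmed, so the filter applies the published criteria only. When
both criteria fail, the average criterion is reported as the reason. The
filter is monotone: lowering any quality score never converts a rejection
into a pass.

## Site calling

Each trimmed read is aligned with an affine-gap glocal aligner
(reference global, read end-gaps free; match +2, mismatch −1, gap open
−4, gap extend −1, via Biopython's pairwise aligner). Three acceptance
rules apply:

* **span** — all five site offsets must land on read bases;
* **compactness** — the aligned reference must occupy a read window no
  longer than the cassette plus `max_span_slack = 10` bases; a scattered,
  heavily gapped placement is a spurious hit on flanking sequence;
* **identity** — ≥ 80 % of the 16 *non-site* reference positions must
  match. Identity deliberately excludes the five site positions: edited
  molecules legitimately mismatch the unedited reference there (a fully
  edited read is 5/21 divergent), so including them would bias against
  highly edited isoforms while telling nothing about read quality.

The base over each site gives unedited (A), edited (G) or ambiguous
(C/T/N/gap). A read with any ambiguous site is rejected whole (read-level
exclusion, the default denominator); a per-site tally that retains the
unambiguous sites of such reads is also available, since the original
report's per-site denominators are not exactly recoverable and lie
between the two conventions. On gap-free reads the aligner provably
reduces to direct indexing at the site offsets (property-tested).

## Statistics

Isoform counts keep all 32 rows (including structural zeros); all
percentage columns divide by the combined two-group grand total, the
convention the published table uses, and are rendered to two decimals
from counts at write time. Per-site group differences are reported as
Δ% = *ob/ob* − lean, the published sign convention (an increase in the
obese group is positive).

`fisher_exact_2x2` computes the two-sided p as the sum of hypergeometric
probabilities ≤ that of the observed table (probability-mass rule, with a
1e-7 relative tie tolerance), entirely in log space via log-gamma, so
totals of order 10⁴ are exact; it is verified in the tests against both
exhaustive enumeration over all margins ≤ 30 and an independent library
implementation at study scale. The odds ratio is the sample OR with a
Haldane 0.5 correction for zero cells; a degenerate margin yields p = 1
with a warning. Bonferroni families are the 5 editing sites (sequencing)
and the number of genes tested (qPCR).

qPCR records are averaged over technical replicates per (sample, gene),
transformed to relative expression 2^−ΔCt (ΔCt = Ct − reference-gene Ct),
summarised as group mean ± SEM, expressed as fold change versus the lean
group, and compared per gene with a two-tailed Welch t-test.

Sanger estimates use X = G/(A+G) on the two channel heights at each
aligned site, multiplied by the published calibration factors (A: 1.114,
B: 1.009; the remaining sites default to 1.0 because only A and B were
calibrated) and clamped to [0, 1], since a frequency cannot exceed 1 —
the unclamped product can, at high X. The calibration factors are treated
as opaque empirical constants. Trace orientation (forward vs
reverse-complement sequencing) is auto-detected by aligning the
called-base sequence both ways and keeping the better score; the
reverse-complement transform reverses positions and swaps the A↔T and
C↔G channels.

## Synthetic data

The generator emulates the wet-lab amplicon design: sense reads are
`adaptorA + barcode + forward primer + 90-nt flank + cassette + 86-nt
flank + rc(reverse primer) + rc(adaptorB)` (~300 bp, matching the
reported band size). The true flank sequences were never published and do
not affect any computation; fixed arbitrary non-homopolymeric filler is
used. Isoform composition is drawn either exactly from a per-group count
map (the packaged `table1_counts.yaml` transcribes the published counts:
lean 10 574, *ob/ob* 10 377, total 20 951) or by independent Bernoulli
draws per site. Orientation is randomised 1:1 by default. Errors are
uniform substitutions at a configurable per-base rate (no
homopolymer-indel model of 454 chemistry; indels enter only through the
alignment-robustness tests). Qualities are drawn i.i.d. from a discretised
normal, default Q ~ N(35, 2) clipped to [2, 41] — consistent with
screened 454 data and with the zero-error read model, so that an
error-free simulation passes the quality filter with probability
effectively 1 (a sub-threshold end base would require a ~9σ deviate); the
qualities are drawn independently of the injected errors and do not
encode their positions. Fixed seed ⇒ byte-identical FASTQ.

Chromatogram simulation places `peak_scale·(1−m)` on the A channel and
`peak_scale·m` on the G channel at each site (m = edited-template
fraction), the full scale on the template channel elsewhere, plus
optional Gaussian noise clamped at zero. qPCR simulation applies
per-sample Gaussian Ct noise (σ in cycles) around the true ΔCt and emits
identical technical triplicates, matching an analysis that averages
replicate wells first.

What the simulations do **not** model: 454 homopolymer indel errors,
read-length variation, quality–error coupling, chimeras, PCR bias between
isoforms, and cross-talk between chromatogram channels. Passing tests
therefore demonstrate correctness of the computational pipeline under the
stated error model, not robustness to every artefact of real
pyrosequencing or capillary data.

## Problem sizes and determinism

The test suite and the acceptance script regenerate all inputs at run
time: the count round-trip uses the full 20 951-read composition, read
accounting uses the full 29 721 reads, and parameter recovery uses
10 000 reads per group at 0.5 % base error — a few seconds each at
~170 µs per aligned read. All randomness flows from explicit seeds
(numpy Generator); reruns with the same config and seed produce
byte-identical tables.

## Known limitations

* The original per-site denominators (and hence the exact published
  percentages and p-values) cannot be regenerated from the published
  isoform counts (≤ 0.1 % discrepancies); reconstructed p-values for
  sites A and D agree with the published ones in order of magnitude, and
  the published significance pattern is reproduced exactly.
* The published report prints p-values only for sites A and D; the other
  sites' dashes are not interpretable (not-significant vs not-tested), so
  this package always reports all five.
* Editing sites are treated independently in `site_probs` mode; real
  editing exhibits site linkage (e.g. ADAR2-dependent D-site coupling),
  which the exact-counts mode captures but the Bernoulli mode does not.
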