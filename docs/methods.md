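# Methods

`nucshift` analyzes nucleosome organization from paired-end MNase-Seq in two
conditions (a control and a perturbation), and ships a synthetic-chromatin
generator with known ground truth so that every stage of the analysis can be
validated end to end without external data. This note records the models,
the parameters that matter, the numerical conventions, and the limits of
what the synthetic validation shows.

## Signal model

The atomic observation is an MNase-protected **fragment** `[start, end)` in
BED coordinates (0-based, half-open). Its **dyad** — the point estimate of
the nucleosome position — is the midpoint of the inclusive span,
`floor((start + end - 1) / 2)`. The floor makes even-length dyads
deterministic at the cost of sitting half a base left of the true center;
consequently exact mirror (reverse-complement) symmetry of dyad-based
signal holds for odd fragment lengths only. Fragments of 140–180 bp are
treated as canonical mononucleosomes (`filter_canonical`), with the
denominator for normalization deliberately kept at the pre-filter fragment
count so that densities remain comparable across filter settings.

Per-base occupancy is accumulated in **dyad** mode (unit mass at the dyad;
the default, since dyad signal gives the sharpest phasing) or
**footprint-coverage** mode (unit mass over the whole fragment). Raw counts
are scaled to **RPBM** (reads per base per million mapped fragments,
`raw * 1e6 / total_count`), which is invariant under duplication of the
data set. Smoothing convolves with a unit-mass Gaussian (default σ = 20 bp)
or triangular kernel with reflected edges, conserving total mass to within
1e-9 relative.

Profiles around anchors (TSS, DHS, CTCF/TF sites) are strand-aware: windows
of minus-strand anchors are mirrored so positive offsets always point
downstream. Anchors whose window would leave the chromosome are dropped and
counted, never zero-padded — padding would bias edge means. The 2D
occupancy matrix bins the same dyad counts by fragment length; its column
sums reproduce the length-filtered 1D profile exactly, which is asserted in
the tests.

## Nucleosome calling

Summits are local maxima of the smoothed RPBM dyad track at or above an
occupancy floor (default 2 RPBM), retained greedily by descending occupancy
subject to a minimum summit separation; ties go to the leftmost coordinate.
A run of exactly equal values higher than both flanks counts as a single
summit at its left end — such plateaus arise in noise-free signal when two
dyad clusters are symmetric about a midpoint. The footprint is fixed at
147 bp (summit ± 73), the canonical length of DNA in the core particle.
**Fuzziness** is the sample standard deviation of the supporting dyads
inside the footprint (undefined below two dyads).

The minimum summit separation deserves a note. The library function
defaults to 120 bp, appropriate when nucleosomes are at least a footprint
apart. The pipeline configuration, however, defaults to **40 bp**: in a
perturbed condition a +1 nucleosome shifted 75–125 bp toward its array
neighbor produces genuine summit pairs 15–115 bp apart, and a 120-bp
exclusion silently deletes one of them. With σ = 20 smoothing, any two dyad
clusters closer than 2σ = 40 bp merge into a single (possibly plateau)
maximum anyway, so 40 bp admits no spurious double calls while keeping
every resolvable pair. This was the single most consequential parameter for
shift recovery.

## Cross-condition shift analysis

Two calls from different conditions describe the same nucleosome when their
147-bp footprints overlap, i.e. summits at most 146 bp apart. Candidate
pairs are matched one-to-one greedily by ascending |shift| (ties: leftmost
control summit), which is order-stable. A pair's **variance** is its
absolute summit distance; **region variance** is the mean over pairs in a
region.

Roles (+1 = first call at/downstream of the TSS in gene orientation, −1 =
first strictly upstream, within a 1-kb search window) are assigned on the
control calls; the matched treatment call inherits the role. For shifts
beyond footprint overlap (147–200 bp), and for shifted nucleosomes whose
treatment call merged with an array neighbor, a secondary match finds the
nearest treatment summit within 200 bp that carries *unexplained
occupancy*: a candidate already paired to a control call of similar height
is excluded (its mass is accounted for), while a merged two-nucleosome call
or an unpaired call qualifies. The eligibility threshold is 30% of the
query call's occupancy. Without this rule the nearest-summit fallback
systematically captures the stable −1 call when a +1 shifts ~175 bp
downstream.

Oriented shifts (positive = downstream in gene orientation) are stratified
into the bins 0, 1–9, 10–50, 51–100, 101–150, 151–200 bp; |shift| > 200 bp
is excluded and counted separately. Spacing is summarized by the multiset
of adjacent summit distances; **uniformness** reports its mode (1-bp
histogram, smallest value on ties) and IQR (type-7 linear-interpolation
quartiles).

**Phasing** of a TSS profile is classified canonical when (i) the profile
minimum in [−250, +50] is below half the +1 peak height (the NDR), (ii) a
downstream +1 peak exists, and (iii) downstream peak heights are
non-increasing within 5% relative tolerance. Peaks are maxima above 20% of
the profile maximum separated by at least the lower end of the expected
spacing range; the period estimate is the mean successive downstream peak
distance.

## Positional-difference track

Per base, dyad counts are summed over a centered window (default 147 bp)
in both conditions and given a pseudocount of 1. The larger depth-scaled
windowed count is tested against the Poisson expectation derived from the
smaller side after library-size scaling, two-sided
(`p = 2·min(P(X ≤ obs), P(X ≥ obs))`, capped at 1). Fixing the test
direction to the larger side makes the track exactly antisymmetric under
swapping the two samples, which a one-directional test is not; the
magnitude at any base still equals the exact Poisson tail sum asserted by
the brute-force oracle in the tests. Sign convention: bases where the
treatment exceeds the control score negative (−log10 p), the reverse
positive, exact ties zero. No multiple-testing correction is applied; the
track is a browser-style display statistic.

## Sequence features

Dinucleotide composition around dyads distinguishes the flexible W|W class
{AA, AT, TA, TT} from the stiff S class, by default {GC, CG} with the full
{GG, GC, CG, CC} available. At oriented offset *o* the dinucleotide starts
at dyad+*o* (reverse-complemented for minus-strand sites); sites with
ambiguity codes at an offset leave that offset's denominator. Positional
k-mer matrices (default 6-mers in 10-bp windows over ±130 bp, 125 bp
available via configuration) count k-mer starts per window bin,
row-normalize to frequencies and z-score across bins. Genic annotation
labels a position promoter ([TSS − 1000, TSS + 100] in gene orientation,
promoter wins on overlap), gene body (rest of TSS–TES), or intergenic.

## Integration

Signal density over a region is the tag-dyad count scaled per million total
tags (`count * 1e6 / total`), log2-transformed with pseudocount 1 for group
summaries; a per-base variant divides by region length. Distributions are
compared with the two-sample two-sided Kolmogorov–Smirnov test — the
asymptotic Kolmogorov distribution for large samples, and an exhaustive
permutation enumeration (valid under ties) when both samples have at most
10 observations. Binding is defined by summit-in-region membership
(footprint overlap available via flag) at the **control** summit: the
question is whether the nucleosome, at its reference position, carries the
mark. Fold enrichment is relative to the stable (0-bp shift) group and
reported missing when the reference fraction is zero.

## Synthetic chromatin

The generator places non-overlapping genes with random strand on one
chromosome and lays down a phased truth array per gene: +1 dyad at
TSS + 100 bp (gene-oriented), −1 dyad 150 bp upstream of +1 (the NDR), and
further dyads every 190 bp on both sides (3 per side by default). Programmed
shifts move the treatment +1 (or −1) dyad by an exact delta up- or
downstream in gene orientation; all applied deltas are recorded in the
truth table. Fragments are sampled per truth dyad: center = dyad +
round(N(0, jitter)), length = round(N(147, 12)) clamped to [100, 250] bp
(the bounded support of a gel-purified mononucleosome library); fragments
that would leave the chromosome are dropped. The published fragment-length
dispersion is not quantified anywhere we could anchor to, so 147 ± 12 bp is
a simulation convention. Optionally the G+C fraction is elevated under
reference footprints to give the composition profiles a recoverable signal.

The standard study conditions — used by the validation suite and
`scripts/acceptance.py` — are 200 genes, 190-bp spacing, 150-bp NDR, 50
fragments per nucleosome per condition, 10-bp dyad jitter, and +1 shifts of
{30, 75, 125, 175} bp, half downstream and half upstream. These sizes keep
a full end-to-end run under ten seconds on one core while leaving each
shift-bin group 20–25 genes. The demo pipeline additionally emits a
synthetic DE table (shifted genes dysregulated with probability 0.5 vs 0.1)
and synthetic bound regions (+1 footprints bound with probability 0.6 vs
0.25), so the integration stage has programmed associations of known
direction.

What the generator does **not** emulate: sequencing error, PCR duplicates,
MNase sequence preference, overlapping genes, sub-nucleosomal or
di-nucleosomal particles, chromatin heterogeneity across cells, and
mapping artifacts. Passing the synthetic validation therefore demonstrates
the correctness of the computations and the recoverability of programmed
signal at realistic depth and noise — not robustness to every property of
real chromatin.

## Degenerate inputs and tie rules

Empty fragment files, zero-length regions, empty samples to the KS test,
anchors whose windows leave the chromosome, and calls with fewer than two
supporting dyads all either raise with context or propagate as explicit
missing values, as listed per function. Ties are always broken
deterministically: leftmost coordinate for equal-occupancy summits and
equal-|shift| pairs, lexicographic anchor name in heatmap ordering,
smallest value for tied spacing modes. All randomness flows from explicit
integer seeds; two runs of a pipeline configuration produce byte-identical
outputs, which the manifest (SHA-256 per file) makes checkable.
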