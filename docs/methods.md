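# Methods

## Sequence model and conventions

All sequences are DNA over `{A, C, G, T, N, -}`; RNA input is mapped
`U → T` at parse time. Coordinates are 0-based half-open everywhere in
the library (1-based only where a report column says so). Only the
standard genetic code is supported, with the stop set fixed at
{TAA, TAG, TGA}; every computation below assumes it. A codon containing
`N` or a gap is excluded from stop counting and from dN/dS site
counting — the "treat undetermined nucleotides as gaps" policy — and is
reported in a skipped-codon tally so codon bookkeeping always closes.

## ORF scanning

An ORF is a maximal run of non-stop codons bounded by in-frame stop
codons or by the ends of the scanned region. There is no ATG
requirement: the intended substrates are decaying viral-gene remnants,
where the biologically meaningful quantity is how much uninterrupted
coding frame survives, and runs truncated by the region boundary are
eligible for the same reason. The length threshold is strict
(`n_codons > min_codons`, default 50), and the terminal stop codon is
never included in `n_codons`; whether a published ORF length includes
the stop is rarely stated, so the choice is documented here and
configurable by adjusting the threshold.

Frame names encode correspondence with a reference gene whose first
codon starts at region coordinate K: a forward ORF starting at s is
ORF1/ORF2/ORF3 for (s − K) mod 3 = 0/1/2; a reverse-strand ORF whose
first codon's position 1 sits at forward coordinate e − 1 is
ORF−1/−2/−3 for (e − 1 − K) mod 3 = 0/1/2 (its first base pairs with a
reference codon position 1/2/3). When two or more reported ORFs share
a frame name on a strand they are suffixed a, b, c … in 5′→3′ order on
that strand; a lone fragment keeps the bare name. Frame correspondence
is supplied by the caller (an offset); this module never aligns.

## Pairwise dN/dS (Pamilo–Bianchi–Li)

Each codon position is classified by degeneracy: fourfold if all three
single-base changes are synonymous, nondegenerate if none are, twofold
otherwise; changes to stop codons count as nonsynonymous. This "count
of synonymous outcomes" rule places codons like ATA (third position:
two synonymous changes) in the twofold class. Site totals L0, L2, L4
are averaged over the two sequences, so L0 + L2 + L4 = 3 × (compared
codon columns) identically.

Differences are tallied as transitions (P) and transversions (Q) per
class. A column whose codons differ at one position contributes one
change, split half-and-half between the two codons' classes at that
position. Codons differing at 2–3 positions are resolved by unweighted
averaging over all minimal mutational pathways that avoid stop-codon
intermediates (if every pathway is blocked, all pathways are used —
this never occurs for 2-difference sense pairs and is a guarded corner
for 3-difference ones). Columns containing a gap, ambiguity, or a stop
codon in either sequence are excluded from that comparison only
(pairwise deletion).

Kimura two-parameter corrections are applied per class:
A = ½ln 1/(1−2P−Q) − ¼ln 1/(1−2Q) (transition distance) and
B = ½ln 1/(1−2Q) (transversion distance), then

    dS = (L2·A2 + L4·A4)/(L2 + L4) + B4
    dN = A0 + (L0·B0 + L2·B2)/(L0 + L2)

on the premise that twofold-site transitions are synonymous and
twofold-site transversions nonsynonymous. Undefined logarithms
(saturation) and comparisons with L2 + L4 = 0 yield NA, never
infinities, and NA propagates: dS NA ⇒ ratio NA ⇒ p NA. A class with
zero sites contributes zero to the weighted sums.

Standard errors come from resampling codon columns (not nucleotides,
preserving codon structure) with replacement, 1,000 times by default;
the SE is the standard deviation of the resampled estimates, with NA
resamples dropped per component and counted. dN = dS is tested with
z = (dN − dS)/√(se_dN² + se_dS²) against the standard normal
(two-tailed); families of comparisons use a Bonferroni per-test level
α/n (e.g. 108 branch tests at family α = 0.05 give 4.6×10⁻⁴).
Sliding-window scans (default 30 codons, step 1) repeat the full
estimate per window; windows with no observed synonymous difference
are flagged NA — the disconnected stretches of a windowed plot.

A cross-check in the test suite compares the estimator with an
independent implementation of the closely related Li (1993) method
(seqinr's `kaks` via Rscript) at 10% relative tolerance; the two
counting variants differ in pathway weighting details, so exact
agreement is not expected.

## Branch models

The codon substitution model is the usual 61-state reversible Markov
process: zero rate for multi-position changes, otherwise rate ∝ π_j
times κ for transitions and times ω for nonsynonymous changes, scaled
per branch so branch lengths are expected substitutions per codon.
Equilibrium codon frequencies are plugged in empirically from observed
codon counts with a 0.5 pseudocount (an F61-style estimate); treating
all 60 frequencies as free ML parameters adds little at these data
sizes and is numerically fragile, so the plug-in is used and named as
such. Likelihoods use Felsenstein pruning with per-node rescaling;
columns with gaps or ambiguity are marginalized over all compatible
states rather than deleted, which uses partial codons' information
(tools that delete such columns will differ slightly).

The *selection* (free-ratio) model gives every branch its own ω; the
*null* model pins ω = 1 on the tested branches and frees the rest.
Fitting is coordinate-wise: a global line search on κ each sweep, then
for each branch a bounded search on its length (and ω where free)
against fixed "upper/lower" conditional likelihoods of the rest of the
tree — each proposal there costs one 61×61 eigendecomposition and one
matrix product, which is what makes replicate studies affordable.
Convergence is declared when a sweep improves lnL by less than the
tolerance (default 10⁻⁶; calibration studies in the tests use 10⁻⁴).
Because the ω landscape can be multimodal, optimization restarts from
ω ∈ {0.4, 1, 3.14, 15} by default and the best likelihood is kept; a
warm start from the null fit's parameters is supported and guarantees
lnL(selection) ≥ lnL(null) for nested comparisons. The LRT statistic
2ΔlnL is referred to χ² with df = number of pinned ω parameters
(branch lengths are shared); negative statistics within a small
tolerance are clamped to zero, larger ones raise as optimizer failure.
Trees follow the user-supplied species topology — no topology search —
and a basal bifurcation is collapsed since the two root edges of an
unrooted tree are not separately identifiable under a reversible model.

## Analytic stop expectations

Under neutrality at rate r substitutions/site/year, a frame of C
codons accumulates r·3C·t substitutions in t years along a single
lineage (root→tip, the convention matching the substitution-load
arithmetic these analyses use — not tip-to-tip). If a fraction f of
substitutions creates a stop codon, E[stops] = r·3f·C·t, and the
Poisson approximation Pr(no stop) = exp(−E). Under equal substitution
rates and equal codon frequencies, f is an exact enumeration over the
code: 23 stop-producing changes out of 549 single-base changes from
sense codons, ≈4.19% ("4%") — one third of the 12% figure this
calculator corrects. The reciprocal form, one stop per
1/(r·3f·10⁶) codon·My, gives ~2,310 at r = 1.2×10⁻⁹ and f = 0.12.
Report rounding: two decimals for expected counts, three significant
figures for the codon·My rate.

One documented inconsistency: a published substitution load of 132.11
for a 1,113-nt gene over 54.1 My at 2.2×10⁻⁹/site/yr corresponds to
1,110 sites (the stop-stripped gene), not 1,113 (direct product
132.47). The calculator returns the direct product and leaves the
choice of site count to the caller rather than silently matching
either figure.

## Neutral Monte Carlo simulator

Each replicate evolves every site independently under an HKY process
with stationary base frequencies (empirical from the input by default;
equal-frequency and explicit modes provided) for a branch length of
rate × time expected substitutions per site. Sites are sampled from
the exact matrix-exponential transition probabilities at the full
branch length — not discretized mutation steps — which is both exact
and fast. The transition/transversion ratio (default 4) is interpreted
as the expected substitution ratio R, with
κ = R(π_A+π_G)(π_C+π_T)/(π_Aπ_G+π_Cπ_T); a flag treats the value as κ
directly, since simulators disagree on this convention. Input
sequences are stop-stripped first (codon deletion); stop codons
arising mid-history are not masked — only the final sequence is
scored, so reversions are possible and the mean stop count saturates
at large branch lengths instead of growing linearly. There are no
indels and no rate heterogeneity across sites (the classic
sequence-evolution-simulator model). Default 100,000 iterations; the
test suite runs 10,000 with widened Monte Carlo tolerances. Summaries
carry the full histogram and Monte Carlo standard errors for the mean
and for Pr(0), and are bit-reproducible from the seed.

For small branch lengths (≲0.05/site) the simulator agrees with a
sequence-specific first-order expectation: branch length × the summed
instantaneous rate of stop-producing single-base changes over the
current sequence (`first_order_expected_stops`). This is the
quantitative bridge between the simulator and the uniform 4% figure —
on a sequence containing each sense codon once, with equal rates, the
enumerated fraction is recovered exactly.

## Synthetic data: what it emulates and what it does not

`random_stop_free_sequence` draws codons i.i.d. (uniform over the 61
sense codons by default). `simulate_pair` evolves two descendants from
an ancestor under the codon model, parameterized by the tip-to-tip
synonymous divergence t_syn so true dS is known analytically; the
realized nonsynonymous divergence is ω-controlled but only
approximately ω·t_syn on the counting scale, so recovery tests compare
against simulation-measured truth. `simulate_tree_alignment` evolves
down a fixed tree with per-branch ω and keeps internal states.
`make_degraded_region` wraps a mutated template (injected stop codons
and single-base-deletion frameshifts) in stop cassettes — a 12-nt
sequence containing a stop in all six frames — plus flank blocks built
so that no flank frame runs more than ~20 codons stop-free; the
returned ground truth therefore lists *exactly* the template-
overlapping ORFs a correct scanner must report in the affected frames.

None of these fixtures imitate real nucleotide composition, codon
usage bias, CpG hypermutability, indel spectra, or transposon
insertions. Consequently a passing suite demonstrates that the
estimators and the simulator are correct and calibrated under their
stated models, not that any particular real locus's published numbers
are recovered: quantities like a Monte Carlo mean stop count are
composition-dependent (a uniform-codon surrogate has a smaller
stop-generation opportunity than an AT-biased viral gene), and
reproducing locus-specific values requires that locus's sequence as
input. The test suite asserts the composition-robust features instead:
grid orderings, Poisson consistency of mean/Pr(0) pairs, first-order
analytic agreement, estimator calibration (type-I error, LRT p-value
uniformity) and parameter recovery.

## Numerical choices

* Bounded log-scale line searches for branch lengths
  (10⁻⁷–20 subs/codon), ω (10⁻⁴–50) and κ (0.05–100); a proposal never
  replaces an incumbent with higher likelihood.
* Reversible generators are diagonalized via similarity to a symmetric
  matrix (√π scaling); transition matrices are clipped at zero and, for
  simulation, renormalized row-wise.
* Pruning partials are rescaled per node with accumulated log scalers.
* Degenerate K2P inputs (log arguments ≤ 0) yield NA; the bootstrap
  drops NA resamples and reports how many.
* Bootstrap, simulators and generators take explicit integer seeds;
  identical seed + config ⇒ bit-identical output.

## Problem sizes in the shipped studies

The test suite's replicate studies are sized for a desktop run:
Z-test calibration uses 500 neutral 300-codon pairs with 200 bootstrap
resamples; LRT null calibration uses 100 replicates of a 6-taxon,
200-codon alignment; ω-recovery uses 20 replicates at 500 codons;
Monte Carlo checks use 10⁴ iterations. Library defaults remain at the
full study settings (1,000 resamples, 10⁵ iterations).

## Known limitations

* Pairwise estimation implements the Pamilo–Bianchi–Li family only (no
  Nei–Gojobori or ML pairwise variants).
* Branch models only: no site or branch-site models, no Bayes
  empirical Bayes.
* The exact pathway weighting used by other PBL implementations varies;
  this one uses unweighted stop-free minimal pathways, and cross-tool
  agreement is expected only to within a few percent.
* The simulator has no indels, no rate heterogeneity, and no
  selection-adjusted stop accumulation.
* ORF scanning assumes a caller-supplied frame correspondence; it does
  not align the region to the reference gene.
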