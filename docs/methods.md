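# Methods

This note documents the models, defaults and numerical choices behind
`chromexpr`, and what the synthetic validation does and does not show.

## The analysis problem

Combined knockdown of the endothelial ETS transcription factors ERG and
FLI1 converts endothelial cells toward a mesenchymal state. The
computational task is to connect three data layers: (i) an 8-group
expression matrix (siControl / siERG / siFLI1 / siERG+siFLI1 at days 3
and 7, MAS5-like linear scale), (ii) ChIP peak sets for the two factors
and for histone marks, and (iii) binned coverage tracks for six
ChIP targets (ERG, FLI1, H3K4me3 and H3K27Ac under control and
double-knockdown conditions). The pipeline asks which chromatin
configurations the factors occupy, which expression programs respond,
whether the two align, and which genes look like direct activation
targets.

## Expression pipeline

**Group means and filters.** Replicates are averaged into the 8
(treatment, day) group means. A probe is kept when (1) its maximum
group mean is ≥ `min_signal` (default 300, inclusive) and (2) its
coefficient of variation across the 8 group means — sample (n−1)
standard deviation over mean — is ≥ `min_cv` (default 0.5, inclusive).
CV is deliberately computed on group means rather than per-replicate
values: the filters describe between-condition variability, not
replicate noise. All-zero probes have undefined CV and are dropped with
a warning.

**Probe collapse.** Genes with several probes keep the probe with the
largest sum of group means; exact ties resolve to the lexicographically
smaller probe id (logged), which makes the operation order-independent.

**Clustering.** Rows are Z-scored across the 8 groups (sample sd) and
clustered by agglomerative average linkage on correlation distance,
cut at `k_major` clusters; ids are renumbered by descending size. This
is a deliberate substitute for HOPACH-style hybrid clustering: the tree
construction differs, so memberships on real data are not expected to
match a HOPACH run — the planted-structure tests validate the
substitute on data whose clusters are real, not the original tool. A
`subsplit_cluster` helper re-cuts one cluster (e.g. splitting a "late
up" cluster by day of upregulation into 3-1/3-2-style subclusters).

**Regulation patterns.** Day-3 group means are re-normalized (Z within
the four day-3 groups only; zero-variance rows become all-zero) and
each knockdown's shift against siControl is discretized at
`delta = 0.5` Z into up/flat/down. The (siERG, siFLI1, combo) triple is
matched against eight templates in order I..VIII (first match wins):

| pattern | siERG | siFLI1 | combo | extra | reading |
|---|---|---|---|---|---|
| I | U | F | U | combo ≥ siERG | cooperative repression, ERG-led |
| II | F | U | U | | cooperative repression, FLI1-led |
| III | U | U | U | | redundant repression |
| IV | U | F | U | combo < siERG | FLI1 loss partially counteracts |
| V | U | F | F | | FLI1 loss fully counteracts |
| VI | D | U | any | | opposing: ERG promotes, FLI1 represses |
| VII | D | F | D | combo ≤ siERG | cooperative promotion, ERG-led |
| VIII | F | D | D | | cooperative promotion, FLI1-led |

The magnitude side-conditions are what make I and IV disjoint; ties
(combo exactly equal to siERG on the Z scale) fall to I/VII. Everything
else — including uniform repression of all three knockdowns — is
"other". The templates are an explicit encoding of verbal pattern
descriptions; `delta` trades sensitivity against stability and 0.5 Z is
a conventional middle ground.

## Peak analytics

Peak position for TSS and feature assignment is the interval midpoint
(a narrowPeak summit can be used instead where present). "Upstream" /
"downstream" are the 3-kb flanks 5′ of the TSS and 3′ of the TES in
gene orientation, with precedence upstream > genic > downstream >
distal intergenic. Nearest-TSS assignment searches within 1 Mb and
reports a signed distance (negative 5′ of the TSS in gene orientation);
equidistant TSSs resolve to the smaller coordinate. Venn overlap
requires ≥ 1 shared bp by default and is reported both as per-peak
counts (each direction) and as merged shared intervals, since the two
conventions genuinely differ. Replicate correlation re-bins tracks to
10-kb bins by summation and computes genome-wide Pearson r per mark.

## Chromatin-state segmentation

**Binarization.** Each mark's background rate λ is its genome-wide
mean count per bin (200 bp default). A bin is "on" when the Poisson
upper tail P(X ≥ c | λ) at its count is ≤ `p_threshold` (default
1e-4). This assumes the genome is mostly background for every mark —
true for real ChIP data and for the default synthetic genome (below),
but not for, e.g., input-free dense signal.

**Model.** A K-state HMM over the M = 6 binary tracks with independent
Bernoulli emissions per mark: P(x|k) = ∏_m B_km^x (1−B_km)^(1−x).
Chromosomes are independent sequences (transitions never cross
boundaries). Baum–Welch runs on scaled probabilities (log-likelihood
accumulated from scaling factors — algebraically the log-space
recursion); emissions are clipped to [1e-6, 1−1e-6]. Convergence:
Δ log-likelihood < `tol` (1e-4) or `max_iter` (300). The EM
log-likelihood is asserted non-decreasing every iteration, and row
stochasticity of π and A is enforced to 1e-10.

**Restarts and initialization.** EM on binarized chromatin data is
multimodal: a common local optimum fuses two signal states and splits
the quiescent state. The trainer therefore takes the best of
`n_restarts` (default 5) seeded initializations, alternating two
styles: perturbed genome-wide mark frequencies, and "prototype" rows
copied from randomly drawn observed bin profiles. Prototype draws give
rare but distinct signatures (a 3–4 % enhancer state) a basin of
attraction that frequency perturbation rarely finds. Transitions start
sticky-uniform (0.9 diagonal), π uniform.

**Decoding and merging.** Viterbi by default (posterior decoding
optional), in log space. States with genome occupancy < 0.5 % *and*
maximum emission probability < 0.05 can be merged into a single
quiescent class — the usual collapse of near-empty classes before a
segmentation is displayed — and classes are renumbered by
descending occupancy. Both thresholds are exposed; requiring both
conditions prevents merging a rare-but-real signal state.

## Integration

**Differential H3K27Ac.** Without replicates, the exact test of choice
is a two-sided binomial test per region: under no change, the region's
pooled count splits between conditions by the library-size ratio.
Regions default to the control H3K27Ac peak intervals (overlapping
peaks merged; bookended peaks kept separate so adjacent distinct
chromatin elements are tested separately). Calls require BH q < 0.05
*and* |log2FC| ≥ 1 (fold change on library-normalized counts, 0.5
pseudocount only when a side is zero). The fold-change gate is what
keeps large regions with trivially significant 1.2-fold shifts out of
the "decreased" set.

**Class–cluster association.** Gene lists per chromatin class collect
every gene with ≥ 1 class bin within ±25 kb of its TSS; a gene may
appear in many classes. Enrichment against expression clusters is the
one-sided Fisher exact test, computed as the hypergeometric upper tail
in log space (gammaln + log-sum-exp), accurate to ~1e-13 relative even
for p ≈ 1e-60; odds ratios use the Haldane 0.5 correction only for
zero cells. The universe defaults to all genes assigned to ≥ 1 class.
One-sided enrichment is used because the question is over-representation;
the acceptance suite validates the tail against exact integer
arithmetic exhaustively for every table with N ≤ 40 and on a 20,000-table
random sample up to N = 200 (exhausting N ≤ 200 outright is ~10⁷·7
tables and adds nothing but runtime), plus an independent library
cross-check.

**Direct-target screen.** Five flags per gene, all required: (a) ≥ 1
ERG peak *and* ≥ 1 FLI1 peak with midpoint within ±25 kb of the TSS
("either" mode relaxes to one factor); (b) such a TF peak overlaps
(≥ 1 bp) a control H3K27Ac peak; (c) that H3K27Ac peak intersects a
"decreased" differential region; (d) double-knockdown day-3 mean
< 30 % of siControl (strict); (e) double-knockdown mean strictly below
both single knockdowns. Genes missing from the expression matrix fail
(d) and (e) with a warning. Day 3 is the default timepoint (direct
responses); the day is a parameter.

## Motif enrichment

An exact k-mer enumerator, not a PWM optimizer: 8-bp windows counted
on both strands (each N-free window contributes 2 to its canonical
k-mer), background either per-sequence dinucleotide shuffles
(Altschul–Erikson Euler-walk shuffle, exactly preserving dinucleotide
counts) or uniform-random sequences of matching lengths, both seeded.
Results keep fold ≥ 2 and rank by the one-sided Fisher p of the k-mer's
occurrence counts. Motif frequency comparison between two region
classes scores the fraction of sequences with ≥ 1 match (either
strand) of an IUPAC consensus and a one-sided Fisher p toward the first
class; built-ins cover the ETS core (GGAW), AP-1 (TGASTCA) and the
GGAA repeat (GGAAGGAA).

## Synthetic data: what it emulates and what it does not

The generator plants a known truth behind every stage. Hidden chromatin
states follow a sticky Markov chain per chromosome; with uniform
occupancy the chain is exactly "stay with probability 0.95, else
uniform", and with target weights w it is the mixture chain
A = sI + (1−s)·1wᵀ whose stationary distribution is exactly w. The
default genome (2 chromosomes × 1 Mb, 200-bp bins) uses weights
(0.775, 0.10, 0.035, 0.09) over (quiescent, promoter, EC-enhancer,
generic-enhancer): a mostly quiescent genome in which ERG/FLI1-bound
enhancers are rare, so "an enhancer near the TSS" is informative rather
than ubiquitous, and the genome-wide-mean Poisson binarization is
meaningful. Emission rates (Poisson means per bin) give each mark a
high rate in the states that carry it (TFs 25, H3K4me3 25, H3K27Ac 40)
against a 0.1–0.5 background; the EC-enhancer's knockdown-condition
H3K27Ac rate is attenuated 4-fold (configurable; 1.0 gives null data
for calibration). A negative-binomial option (gamma-overdispersed
Poisson) exists for robustness experiments. TF and H3K27Ac peaks are
maximal single-state runs of the corresponding states, scored by mean
observed count; EC-enhancer runs are the true differential regions.

Expression is simulated on log2 scale — baseline ~ Uniform(8.6, 10.6)
log2 units for planted genes, per-block log2 effect vectors over the 8
groups, Gaussian replicate noise (default sd 0.15, 2 replicates per
group) — then exponentiated, because the ≥ 300 and CV filters act on
linear signal. Default blocks: four 30-gene pattern blocks (I, IV, V,
VI) and 12 candidate genes (≈ 82 % loss under the double knockdown,
more than either single), plus flat genes half of which sit below the
signal filter and half of which are high but invariant. Effect sizes
were chosen so that every block clears the CV filter, discretizes
unambiguously to its pattern at 0.5 Z, and — critically — only the
candidate block passes both expression criteria of the screen. That
makes the planted candidate set exactly the screen's correct answer:
candidates are additionally anchored with their TSS within 10 kb of an
EC-enhancer run of ≥ 5 bins so the three ChIP criteria hold by
construction, while all other genes are placed uniformly. Genes carry
1–3 probes (extra probes scaled 0.4–0.8×) to exercise probe collapse.

Because gene placement must know where enhancer runs are, the
`simulate(config)` orchestrator samples the state paths once and passes
them to genome, chromatin and expression generation explicitly; all
randomness flows from one seeded generator, and identical configs
produce byte-identical files.

**What passing tests show — and do not.** Exact recovery at
`noise_sd = 0` shows the pipeline implements its own definitions
correctly, not that it is robust to real microarray noise (the default
noise level exercises robustness only mildly). Poisson emissions with
well-separated rates make binarization nearly clean; real ChIP data
have overdispersion, mappability artifacts and copy-number structure
that the generator does not model. Peaks derived from state runs are
perfectly aligned with bins; real peak callers produce ragged
boundaries. The expression design plants block-constant profiles, so
an adjusted Rand index of 1.0 is attainable; real clusters are fuzzy.
Headline counts from the original sequencing-scale datasets (tens of
thousands of peaks, hundreds of screened candidates) are functions of
genome size and sequencing depth and are not reproduced at this scale.

## Problem sizes used in validation

The validation suite runs at desk scale by design: 10,000 bins for the
default end-to-end study, 20,000 bins for HMM parameter recovery,
~2,000 regions (74 Mb of synthetic genome) for null calibration of the
differential test, 100 random instances of up to 500 intervals for the
interval oracles, and exhaustive Fisher tables to N = 40 plus 20,000
random tables to N = 200. These sizes give the planted effects enough
data to be recovered with wide margins while keeping every run
reproducible on a single CPU.

## Known limitations

* The HMM assumes conditionally independent marks given the state;
  correlated antibody artifacts violate this.
* Differential H3K27Ac without replicates cannot separate biological
  from technical variability; the binomial test treats counts as the
  only noise source.
* The screen's "upstream region" width (±25 kb) and the TF-pair
  requirement are conventions, exposed as parameters.
* HOPACH-style clustering is substituted, as noted above.
* `read_binned_track` prorates boundary-crossing bedGraph intervals by
  overlap fraction; this conserves mass but smooths sub-bin structure.
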