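# Methods

`txdefine` models how a yeast cell delineates transcription units from
DNA sequence alone. It has three layers: sequence-feature classifiers
that score every base for transcription-initiation and
cleavage/polyadenylation (CPA) potential on both strands; an 8-state
strand-symmetric hidden Markov model (HMM) that integrates the four
score tracks into genome-wide transcript structure; and a synthetic-data
layer that generates every input needed to exercise and validate the
pipeline without external downloads.

## Initiation and termination classifiers

Candidate sites are described by binned sequence features around an
anchor base, read 5′→3′ of the putative transcript (minus-strand windows
are reverse-complemented, so the representation is strand-symmetric by
construction).

* **Initiation**: a 600-bp window from −500 to +100 relative to the TSS,
  six bins with interior boundaries −300/−150/−80/−50/0. The window
  extents and bin count are fixed; the two promoter-proximal boundaries
  delimit the sections used in the promoter-library design (−150:−80 and
  −80:−50), and the distal region is split evenly. Bin boundaries are
  configurable.
* **Termination**: a 150-base window from −75 to +75 relative to the CPA
  site, three 50-base bins.

Feature kinds per bin: maximum motif log-odds (PWM score of the best
match lying fully inside the bin, scanned on both strands — the
nucleosome-depleting elements these features capture act
orientation-independently), G/C fraction, longest poly(dA) and poly(dT)
run, the A:T ratio (restricted to the first 100 transcribed bases for
the initiation classifier, where nascent-transcript base content
matters), and optionally the mean of a user-supplied dinucleotide
property table as a proxy for DNA structural features. The default
vocabulary is the reduced feature set that dominates promoter and
terminator identity — general regulatory factor (GRF) motifs (Reb1,
Abf1, Rap1), Rsc3, the TATA box, G/C content and poly(dA:dT) for
initiation; the Hrp1 efficiency element (optimal site TATATA), G/C
content and poly(dA:dT) for termination — with a plug-in interface for
larger inventories. The shipped PFMs are consensus-derived illustrative
stand-ins with realistic widths and information content; curated
database matrices can be loaded from plain-text PFM or MEME minimal
files.

Training sets: positives anchored at annotated TSS/CPA bases; initiation
negatives tile the genome in overlapping 600-bp windows (half-window
stride, 300 bp) excluding any window overlapping a promoter window;
termination negatives tile transcript bodies at 75-bp stride excluding
the CPA window. The ensemble is leave-one-chromosome-out: for each held
chromosome, replicate Random Forests are trained on the remaining
chromosomes; the score is the mean of per-forest class probabilities,
and held-out prediction for a chromosome uses only the fold that
withheld it. The reference configuration is 8 folds × 4 replicates × 50
trees = 1600 trees; simulation-scale work uses smaller configurations.
Class imbalance is handled by a balanced bootstrap per forest (equal
numbers of positives and negatives sampled with replacement); this
affects calibration, not ranking. Forest hyperparameters beyond tree
counts are scikit-learn defaults, recorded in the model metadata. A
standardized L2-regularized logistic regression with the same predict
contract is provided as the linear alternative; on synthetic promoter
data it performs within 0.05 AUROC of the forest, reflecting the weak
interaction structure among promoter-defining features.

Feature reduction considers features in decreasing impurity importance
(averaged over folds) and retains one iff adding it improves AUROC on a
disjoint refinement set by at least `improvement_threshold` (default
0.002; "appreciable improvement" is not otherwise quantified).

Per-gene factor dependence is a leave-out call: features of the group
are neutralized to the negative-class median (avoiding retraining per
gene) and the promoter depends on the factor iff the score drops by at
least 0.1.

Genome scoring steps anchors by `stride` (default 5–10 bp, well under
the classifiers' intrinsic resolution of ~70 bp for initiation and
~50 bp for termination), carries scores forward between anchors, and
masks window-infeasible edge bases to the track minimum.

## Fine-mapping

Classifier peaks (maximal runs of score ≥ 0.5, merged when closer than
150 bp) localize sites only to tens of bases; the exact base is set by
local micro-motifs. The TSS is placed at the purine of the CA initiator
occurrence nearest the peak summit (falling back to any YR
pyrimidine–purine, then to the summit); the CPA site at the first A of
the (G/C)AA cleavage motif nearest the summit. Ties break 5′-most.

## The unified transcript model

States: {IG, TSS+, Gene+, CPA+, TSS−, Gene−, CPA−, Term}, scanning the
chromosome in one direction while describing transcription on both
strands (reverse-strand states appear in reversed order). Observations:
the four per-base classifier scores (initiation/termination × strand),
emitted as independent Gaussians per state and track. Of the 64
transition probabilities, 40 are structurally zero: the allowed set
comprises 8 self-loops, the two strand cycles
(IG→TSS+→Gene+→CPA+→IG and IG→CPA−→Gene−→TSS−→IG), the bidirectional
terminator path (Gene+/CPA+→Term→Gene−/CPA−), and
divergent/tandem/convergent shortcuts (TSS−→TSS+, CPA+→TSS+, TSS−→CPA−,
CPA+→CPA−). The set is closed under the strand-swap involution σ and is
configurable.

**Strand symmetry.** σ swaps +/− states (fixing IG and Term) and the
+/− observation tracks. Emission means and variances are tied per
σ-orbit. For transitions, the package ties the *joint flows*:
π(a)·T[a,b] = π(σ(b))·T[σ(b),σ(a)] with a σ-invariant stationary π —
i.e., the chain's law is invariant under reading the chromosome as its
reverse complement. (Tying the conditional probabilities themselves
would force equal dwell times on TSS and Gene states, which is
structurally wrong; flow tying preserves each state's dwell.)
`symmetrize` averages the flow matrix with its σ-reflection and applies
a Sinkhorn-style row/column rescaling — scaling row *a* and column σ(*a*)
by the same factor preserves the reflection tie exactly — until the
stationary weights are σ-invariant; the operation is idempotent. With
56 free nonzero parameters in total: 24 transitions + 16 tied means +
16 tied variances.

**Decoding** is scaled forward–backward (underflow impossible by
construction; per-base emission log-likelihoods are stabilized by their
row maximum before exponentiation), with the initial distribution equal
to the σ-invariant stationary distribution. Under these ties decoding
is *exactly* σ-symmetric: the posterior of the reverse-complemented
input is the position-reversed, σ-mapped posterior (verified to 1e−12;
a brute-force path-enumeration oracle checks the marginals to 1e−8).

**Estimation** takes a per-base state map plus the four tracks: means
and variances are within-state empirical moments (population variance,
floored at 1e−4 since the scores are bounded), transitions are
normalized adjacent-base counts restricted to the allowed set
(disallowed observed transitions are warned about and dropped), masked
bases (e.g. overlapping sense/antisense bodies, which the model cannot
represent) are excluded, and the result is symmetrized.

Three package-level choices make decoding of real score tracks robust;
all were adopted after observing fragmented or truncated transcript
calls end-to-end, and each has a mechanistic rationale:

1. **Site-state widths in the training map.** TSS/CPA states are
   widened around the exact sites to 70 bp (the initiation classifier's
   resolution) and 100 bp (spanning the bidirectional cleavage peak:
   the palindromic efficiency element fires the termination classifier
   on both strands with a ~90-bp offset). With narrow site states the
   peak shoulders contaminate the Gene/IG emission statistics, and the
   decoder misreads sense terminators as antisense transcript starts.
2. **Gene/IG emission tying.** The classifier scores carry no per-base
   information distinguishing transcript bodies from intergenic
   background; small spurious differences in the estimated moments
   otherwise accumulate over hundreds of bases and break calls.
   `tie_gene_to_intergenic` shares IG's emission parameters with both
   Gene states, leaving segmentation to the boundary evidence and the
   transition structure. This plays the corrective role that tuning the
   observation means against expression data plays when expression is
   available.
3. **Emission down-weighting.** The scoring windows span hundreds of
   bases, so neighbouring per-base scores are strongly autocorrelated;
   treating each base as an independent draw overstates the evidence.
   When decoding real tracks the emission log-likelihoods are scaled by
   1/50 (one effective independent observation per resolution length).
   `forward_backward`'s default remains the textbook per-base model.

**Mean tuning.** `tune_means` optimizes the 16 tied means by
Nelder–Mead (≤500 objective evaluations; derivative-free because the
objective is a decode) to maximize the Pearson correlation between the
per-base transcript probability, defined as 1 − P(IG), and
log-expression; variances and transitions stay fixed, the result is
re-symmetrized and never scores below the start.

**Transcript calling.** Per strand, maximal runs where the strand
transcript probability (strand states + Term) ≥ 0.5 become calls;
TSS/CPA regions come from the posterior argmax labels inside the call
(Term counts toward both strands' CPA). The pipeline wrapper discards
calls shorter than 250 bp or with mean strand probability below 0.85
(spontaneous promoter–terminator pairings in random background produce
genuine but weak calls; the confidence filter separates them from
implanted genes).

## Synthetic data

The generator emulates the study conditions: i.i.d. background at 38%
G/C (A=T=0.31, C=G=0.19), gene bodies of 500–900 bp with 650–1000 bp
intergenic gaps, ~40% of genes laid out as convergent pairs whose CPA
regions overlap by a few bases (the shared bidirectional terminator
configuration). Promoter grammar, 5′→3′ relative to the TSS: one GRF
site sampled from its PFM at −145, a poly(dA) tract of 10–20 bp at
−128, a TATA box at −70 with probability 0.7, and a TCAT initiator
cassette placing the CA's A exactly at the TSS; competing CA
dinucleotides within ±40 bp are scrubbed (A→T) so the initiator is
locally dominant over the classifier's ~70-bp resolution, as at real
promoters. Terminator grammar: an AT-rich (~75% A+T) 150-bp window
ending at the CPA site with 2–4 TATATA Hrp1 sites in the 60 bp upstream
of it. Annotations carry the exact sites, widened to the observed
biological spreads (26 bp TSS, 36 b CPA) for the annotation-level state
map.

What the simulator does **not** emulate: nucleosome positioning and
chromatin state, transcription-factor concentrations and condition
dependence, CUT/SUT-like unstable transcripts, splicing, overlapping
same-strand transcription, the full motif inventories of real
promoters, and real inter-site dependence structure. Passing tests
therefore show that the implementation is internally correct and that
the method recovers structure generated by its own assumed grammar —
not that it attains any particular accuracy on real genomes.

Expression simulation assigns each transcript a log-normal abundance
(μ=1, σ=1 on the log scale) and per-base multiplicative log-normal
noise (σ=0.2). Sort-seq simulation sorts log-normally fluorescing cells
into six log-spaced bins; the estimator is the bin-count-weighted mean
fluorescence, invariant to scaling all counts. The promoter-library
designer generates random candidate segments at varying G/C, embeds
PFM-sampled TFBSs, scores all cross-combinations with the initiation
classifier in a fixed neutral context, retains top segments by mean
score, and pairs every TFBS-bearing segment with a control disrupted at
the motif's three highest-information positions.

## Evaluation

AUROC uses the rank (Mann–Whitney) identity — exactly the pair-counting
estimator with ties at ½, equal to the trapezoidal ROC area. Per-base
precision applies its positional tolerance through binary dilation of
the truth mask (precision-only by default; a flag extends it to
recall). Transcript matching is greedy one-to-one in order of summed
end distance, a pair matching iff same strand and both |ΔTSS| and
|ΔCPA| ≤ the offset (200 bp default); exhaustive assignment verifies
the greedy matching in tests at small n. Strand cross-correlation scans
Pearson correlation at 1-bp offsets over a configurable ±500-bp window.
The random baseline simulates Bernoulli guessing against Bernoulli
truth; with guess probability equal to the transcribed fraction both
precision and recall converge to that fraction. Factor-dependence
validation uses a two-sided Wilcoxon rank-sum on |expression change|.

## Problem sizes and numerical notes

The test suite trains on simulated genomes of 2–4 chromosomes × 30–90
kb (up to 200 implanted genes), scores at 5-bp stride, and decodes
hundreds of kilobases; parameter recovery simulates 1 Mb from known
parameters. These sizes give stable statistics while keeping the full
suite under a minute of compute for the unit layer and a few minutes
end-to-end. Degenerate inputs are rejected with explicit errors
(unobserved states, zero-variance emissions, constant expression,
single-class folds, windows off chromosome ends); N bases never match
motifs and count toward no base fraction. All randomness flows through
seeded `numpy` generators; trained models and score tracks are
bit-reproducible given the seed.

## Known limitations

Single-interval transcripts only (no splicing); no states for
simultaneous sense/antisense transcription, so overlapping opposite-
strand transcripts are predicted at most one strand at a time; the
Gaussian emission model is a misspecification for bounded, bimodal
score distributions (mitigated by the tying and down-weighting above);
the shipped motif library is illustrative, and genome-scale accuracy on
real data depends on curated matrices and a real transcript map.
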