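# txdefine

Sequence-based modeling of eukaryotic transcript definition, built
around the signals a yeast cell can actually read from its DNA.

Identifying where transcription initiates and terminates — and hence
where transcripts are — is usually done with features a cell cannot
sense (ORFs, conservation). `txdefine` instead asks how far the
*cis*-elements recognized by nuclear factors go in defining transcript
units, and provides the machinery to test that question end to end:

* **Initiation and termination classifiers** — Random-Forest ensembles
  (with a logistic alternative) over binned sequence features around
  candidate TSS/CPA anchors: general regulatory factor motifs (Reb1,
  Abf1, Rap1), Rsc3, the TATA box, G/C content and poly(dA:dT) tracts
  for promoters; Hrp1 efficiency elements (TATATA) and base content for
  cleavage/polyadenylation sites. Initiation windows span −500..+100
  around the TSS in six bins; termination windows −75..+75 in three
  50-base bins. Leave-one-chromosome-out folds, importance-ordered
  feature reduction, per-base genome scoring on both strands, and
  leave-one-feature-out dependence calls.
* **A unified transcript model** — an 8-state hidden Markov model over
  the four classifier score tracks, with states
  {IG, TSS±, Gene±, CPA±, Term}, 24 allowed transitions (40 of 64 are
  structurally zero), and strand-symmetric parameter tying (56 free
  nonzero parameters: 24 transitions + 16 tied Gaussian means + 16 tied
  variances). Posterior marginals come from scaled forward–backward;
  decoding is exactly invariant under reverse complement of the input.
  Expression-correlation mean tuning and transcript calling included.
* **Fine-mapping** — exact TSS/CPA bases from score peaks via the CA/YR
  initiator and (G/C)AA cleavage micro-motifs.
* **Synthetic data** — random genomes at yeast base composition (38%
  G/C) with implanted promoter/terminator grammars and full ground
  truth, simulated expression tracks, combinatorial promoter-library
  design, sort-seq bin-count simulation and expression estimation, and
  pseudo-random 3-kb fragment design.
* **Evaluation** — pair-counting AUROC, tolerance-aware per-base
  precision/recall, transcript-level matching at end offsets, strand
  cross-correlation with offset scan, threshold rates, rank-sum
  dependence tests, and random-guessing baselines.

The model at the core: per-base observations
**o**(t) = (init⁺, term⁺, init⁻, term⁻) are emitted as independent
Gaussians N(μ_{s,k}, σ²_{s,k}) per hidden state *s*; a strand-swap
involution σ ties μ and σ² across equivalent states and ties the joint
transition flows π(a)·T[a,b] = π(σ(b))·T[σ(b),σ(a)], so the chain's law
— and therefore every prediction — is invariant under reading a
chromosome as its reverse complement. The forward–backward posterior
marginals γ_t(s) = P(S_t = s | **o**₁..**o**_L) are the model's output
at every base.

## Worked example

Train on one synthetic genome, decode an independently simulated one
(`python examples/03_unified_model.py`):

```
model structure: 8 states, 24 allowed transitions (40 zero), 56 free parameters
expected dwell per state (bases):
  IG       1802.5
  TSS+       70.0
  Gene+     919.9
  CPA+       65.1
  TSS-       70.0
  Gene-     919.9
  CPA-       65.1
  Term      302.2

decoded 120,000 bases on an unseen genome:
  59 transcripts called, 60 implanted
  transcript-level precision 0.932, recall 0.917 (200-bp end offsets)
  per-base precision 0.989 (within 100 bp), recall 0.946
```

The dwell times are read off the fitted self-transitions
(1/(1 − T[s,s])): intergenic stretches of ~1.8 kb, gene bodies of
~900 bp, and site states matching the classifiers' positional
resolution. Precision/recall count a predicted transcript as correct
when both its ends fall within 200 bp of an implanted transcript's ends
on the same strand.

The other example scripts each exercise one capability and print what
they compute:

| script | shows |
| --- | --- |
| `examples/01_motif_densities.py` | analytic vs observed element densities in random DNA (a GRF site every ~2 kb; Hrp1 sites ~1/kb) |
| `examples/02_train_classifiers.py` | classifier training; forest vs logistic AUROC on an unseen genome |
| `examples/03_unified_model.py` | full pipeline; transcript-level accuracy |
| `examples/04_promoter_library_sortseq.py` | combinatorial promoter-library design, simulated sort-seq, score–expression correlation |
| `examples/05_random_fragments.py` | transcripts predicted from pseudo-random 3-kb fragments |

See `docs/methods.md` for the model, its assumptions, parameter
defaults, and what the synthetic data does and does not emulate.

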