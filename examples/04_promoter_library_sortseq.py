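"""Combinatorial promoter-library design and sort-seq expression readout.

Designs a small synthetic promoter library: random segments for the
-150:-80, -80:TSS and TSS:+80 promoter sections, TFBSs embedded by
sampling from the factors' frequency matrices, every segment combination
scored by the trained initiation classifier, top segments retained, and
TFBS-disrupted controls paired with each site-carrying segment.  A
sort-seq experiment (six fluorescence bins) is then simulated for the
assembled constructs, per-construct expression is estimated by
bin-weighted mean fluorescence, and the initiation score is compared to
the measured expression.
"""

import numpy as np
from scipy import stats

from txdefine import pipeline as pl
from txdefine import synthetic_data as sd
from txdefine.evaluation import threshold_rates
from txdefine.motifs import builtin_motifs

# a trained initiation classifier is the scoring engine for the design
genome, anns, _ = sd.generate_random_genome(
    sd.SyntheticGenomeSpec(length=60_000, n_chromosomes=2, n_genes=30, seed=5)
)
model = pl.train_transcript_model(genome, anns)
rng = np.random.default_rng(7)

segment_specs = [
    sd.SegmentSpec("-150:-80", 70, 10, 4, ("Reb1", "Abf1", "Rap1", "Rsc3")),
    sd.SegmentSpec("-80:TSS", 80, 8, 4, ("TATA",)),
    sd.SegmentSpec("TSS:+80", 80, 6, 3, ()),
]
from txdefine.synthetic_data import design_promoter_library, make_library_scorer

scorer = make_library_scorer(
    model.initiation, model.initiation_scheme, model.initiation.specs,
    model.motif_library,
)
design = design_promoter_library(segment_specs, builtin_motifs(), scorer, rng)
print(f"library design: segments per section "
      f"{[len(v) for v in design.segments.values()]} -> "
      f"{design.n_combinations} combinatorial promoters")
n_controls = sum(s.control_sequence is not None
                 for v in design.segments.values() for s in v)
print(f"  {n_controls} TFBS-bearing segments paired with disrupted controls")

# assemble every combination, score it, and simulate its expression:
# expression grows with promoter strength (score) plus biological noise
seqs, scores = [], []
sections = list(design.segments.values())
for s1 in sections[0]:
    for s2 in sections[1]:
        for s3 in sections[2]:
            seqs.append(s1.sequence + s2.sequence + s3.sequence)
score = np.asarray(scorer(seqs))
true_expression = np.exp(1 + 3 * score + 0.25 * rng.standard_normal(len(score)))
counts = sd.simulate_sortseq_counts(true_expression, rng, n_bins=6,
                                    reads_per_construct=500)
estimated = sd.estimate_sortseq_expression(counts).to_numpy()

rho, _ = stats.spearmanr(score, np.log(estimated))
print(f"\nsort-seq readout over {len(seqs)} constructs, six bins:")
print(f"  Spearman R (initiation score vs estimated expression) = {rho:.2f}")

expressed = (np.log(estimated) > np.median(np.log(estimated))).astype(int)
tpr, fpr = threshold_rates(score, expressed, 0.37)
print(f"  at score threshold 0.37: true positive rate {tpr:.2f}, "
      f"false positive rate {fpr:.2f}")
print("\nPromoter-defining sequence features alone predict which synthetic "
      "constructs express.")
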