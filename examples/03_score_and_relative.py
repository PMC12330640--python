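"""Score cells for two mutually exclusive programs and form their relative score.

Scores every cell against 200 expression-matched background gene sets per
program: p is the (add-one) fraction of backgrounds whose mean centered
expression beats the signature's, and the score is -log10(p) rescaled to
[0, 1].  The relative score (program A minus program B) separates the
two cell states along one axis, the way an hEMT-minus-EpiSen score does.
"""

import numpy as np

from ithkit import (ScoringConfig, SyntheticSpec, generate_cohort,
                    normalize_log, relative_score, score_program)

spec = SyntheticSpec(n_samples=4, n_genes=1000, cells_per_sample=250,
                     n_programs=4, genes_per_program=50,
                     program_sharing=1.0, seed=0)
counts, truth = generate_cohort(spec)
norm = normalize_log(counts)

cfg = ScoringConfig(n_background_sets=200, n_bins=30, seed=0)
sig_a, sig_b = (sorted(truth.program_gene_sets[i]) for i in spec.anticorrelated_pair)
scores_a = score_program(norm, sig_a, cfg, program_id="hEMT-like")
scores_b = score_program(norm, sig_b, cfg, program_id="EpiSen-like")
rel = relative_score(scores_a, scores_b)

a_idx, b_idx = spec.anticorrelated_pair
active_a = [i for i, s in enumerate(truth.cell_program_labels) if a_idx in s]
active_b = [i for i, s in enumerate(truth.cell_program_labels) if b_idx in s]
neither = [i for i, s in enumerate(truth.cell_program_labels)
           if not {a_idx, b_idx} & s]

vals = rel.to_numpy()
print(f"mean relative score (A - B):")
print(f"  cells active for program A: {np.mean(vals[active_a]):+.3f}  (n={len(active_a)})")
print(f"  cells active for program B: {np.mean(vals[active_b]):+.3f}  (n={len(active_b)})")
print(f"  cells active for neither:   {np.mean(vals[neither]):+.3f}  (n={len(neither)})")
# A-active cells score near +1, B-active near -1, uninvolved cells near 0:
# the relative score recovers the planted mutually exclusive axis
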