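"""Posterior seeding: known tail identities shrink the search.

Solves the same noisy frame under the Posture model with no prior
information and with the tail pair (then two posterior pairs) given as
seeds, comparing search effort and outcome.
"""

import numpy as np

from ehgm import build_problem, ehgm_solve, generate_series, posture_spec, reduced_config
from ehgm.evaluation import fit_corpus_template, seeds_from_truth

config = reduced_config(noise_sd=0.5, n_frames=10)
template = fit_corpus_template(config, rng_seed=3, n_embryos=6)
series = generate_series(config, np.random.default_rng(8))
frame = series.frames[4]

problem = build_problem(
    frame.points, config.n_pairs, template, frame.time, posture_spec(),
    pair_names=config.pair_names,
)

print("seeds   nodes_expanded  prunes  correct?")
for schedule in ("none", "T", "T-V5"):
    seeds = seeds_from_truth(frame.truth, config.pair_names, schedule)
    pool, stats = ehgm_solve(problem, seeds=seeds, x=1)
    ok = pool.best()[0].points == frame.truth.points
    print(f"{schedule:<7} {stats.nodes_expanded:>14}  {stats.prunes:>6}  {ok}")
# Seeding the flexible posterior region (hardest to identify) removes
# whole subtrees of the search: node counts drop sharply while the
# returned posture stays the exact seed-constrained optimum.
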