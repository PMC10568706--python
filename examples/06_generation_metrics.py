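"""Score a batch of generated molecules with the standard metrics.

Validity (fraction parsing under valence rules), novelty (fraction not
in the training corpus), uniqueness (fraction non-duplicated) and the
similarity distribution to the seed molecule.
"""

import numpy as np

from fragopt import GeneratorModel, load_bundled_corpus, optimize
from fragopt.scoring import generation_metrics, get_score_function

model = GeneratorModel.load("generator.npz")  # from 02_train_generator.py
seed = "CC(=O)Nc1ccc(O)cc1"
results = optimize(seed, get_score_function("qed"), model,
                   fragment_steps=10, atom_steps=50, rng=1)

generated = [s for s, _ in results]
metrics = generation_metrics(generated, load_bundled_corpus(), seed=seed)
sims = metrics.pop("similarity")
print(f"molecules:  {len(generated)}")
print(f"validity:   {metrics['validity']:.3f}   (1.0 by construction)")
print(f"novelty:    {metrics['novelty']:.3f}")
print(f"uniqueness: {metrics['uniqueness']:.3f}")
print(f"similarity to seed: {np.mean(sims):.2f} ± {np.std(sims):.2f}")
# Novelty near 1 means the search is not copying the training corpus;
# uniqueness 1 means the ranked output is already deduplicated.
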