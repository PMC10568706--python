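"""Constrained optimization: raise penalized logP near the seed.

Penalized logP = Crippen logP − synthetic-accessibility score − large-
ring penalty.  The similarity-constrained scorer returns -inf for any
candidate whose ECFP4 Tanimoto to the seed drops below delta, so such
candidates are never preferred by the search.  The short 2 x 100 protocol
mirrors the standard constrained-optimization budget.
"""

from fragopt import GeneratorModel, optimize
from fragopt.scoring import get_score_function, is_failed, penalized_logp, tanimoto_ecfp4

model = GeneratorModel.load("generator.npz")  # from 02_train_generator.py

seed = "CC(C)Cc1ccc(C(C)C(=O)O)cc1"  # ibuprofen
score = get_score_function("plogp_sim", seed=seed, delta=0.4)
print(f"seed {seed}: PLogP {penalized_logp(seed):.2f}")

results = optimize(seed, score, model, fragment_steps=2, atom_steps=100, rng=3)
ok = [(s, v) for s, v in results if not is_failed(v)]
print(f"{len(results)} molecules, {len(ok)} satisfy similarity >= 0.4")
for smiles, value in ok[:5]:
    print(f"  PLogP {value:6.2f}  improvement {value - penalized_logp(seed):+5.2f}  "
          f"sim {tanimoto_ecfp4(smiles, seed):.2f}  {smiles}")
# 'improvement' is the gain over the seed's penalized logP among
# candidates that stay within the similarity constraint.
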