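"""Build a fragment training corpus from a molecule library.

Cuts every bond that joins a ring atom to a non-ring atom; the connected
pieces that remain are the fragments the generator learns to build.
"""

from pathlib import Path

from fragopt import load_bundled_corpus
from fragopt.fragmenter import build_corpus, corpus_summary, write_corpus

corpus_file = Path("scratch_corpus.smi")
corpus_file.write_text("\n".join(load_bundled_corpus()) + "\n")

records = build_corpus(corpus_file, max_atoms=15)
stats = corpus_summary(records)
corpus_file.unlink()

print(f"{stats['n_fragments']} unique fragments from 500 molecules")
print(f"fragment size: {stats['n_atoms_mean']:.1f} ± {stats['n_atoms_sd']:.1f} heavy atoms")
print(f"fragment MW:   {stats['mol_weight_mean']:.0f} ± {stats['mol_weight_sd']:.0f}")
print("most common fragments:")
for r in sorted(records, key=lambda r: -r.source_count)[:5]:
    print(f"  {r.canonical_key:<12} seen in {r.source_count} molecules")
write_corpus(records, "fragments.tsv")
print("full corpus written to fragments.tsv (canonical SMILES + count)")
# Fragment counts tell the generator which chemotypes are common; size
# statistics bound how large a generated fragment needs to be.
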