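"""Score one ortholog pair and read off which side looks more thermostable.

Builds a synthetic mesophile-like sequence and a hyperthermophile-like
ortholog, then scores the ordered pair with the default model.
"""

import numpy as np

from thermoscore import GeneratorSpec, derive_hp_ortholog, sample_mp_sequence, score_pair

rng = np.random.default_rng(0)
spec = GeneratorSpec(min_length=300, max_length=300, seed=0)
mp = sample_mp_sequence(spec, rng, seq_id="mesophile")
hp = derive_hp_ortholog(mp, spec, rng, seq_id="hyperthermophile")

result = score_pair(hp, mp)
print(f"score S(hp, mp) = {result.score:+.4f}  ->  prediction: {result.prediction}")
for name, delta in result.deltas.items():
    print(f"  delta {name:9s} = {delta:+.4f}")

# A positive score predicts the first argument more thermostable.  The
# per-feature deltas show why: positive-weight features (x_K, x_E, x_pos,
# x_charge, ASA) are enriched on the HP side, negative-weight ones
# (x_small, x_tiny, x_A, x_Q, x_T) on the MP side.
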