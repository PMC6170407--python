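"""Recover the CU-rich binding consensus from bound-site sequences.

Generates 200 sequences of which 60% carry a planted UCUCUCU element (as
its DNA equivalent), then runs the seeded-EM consensus finder against a
dinucleotide-shuffled background. The printed consensus is the PWM column
argmax; enrichment is the log2 seed-count ratio vs the shuffled background.
"""

import numpy as np

import bidirscan as b

rng = np.random.default_rng(0)
sequences = []
for i in range(200):
    s = "".join(rng.choice(list("ACGT"), 41))
    if i < 120:
        pos = int(rng.integers(0, 41 - 7 + 1))
        s = s[:pos] + "TCTCTCT" + s[pos + 7:]
    sequences.append(s)

result = b.discover_consensus(sequences, k=7)
print(f"consensus: {result.consensus}  (seed k-mer {result.seed})")
print(f"enrichment: {result.enrichment:.2f} log2 vs shuffled background; "
      f"significant: {result.significant}")
print(f"max CU content of the consensus: "
      f"{b.cu_content(result.consensus, 7):.2f}")
print("A consensus of UCUCUCU with a positive enrichment reproduces the "
      "CU-rich preference of the PTB-family binder on simulated data.")
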