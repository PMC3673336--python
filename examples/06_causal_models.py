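"""Infer the causal structure of (SNP, methylation, expression) triplets.

Three structures are compared per triplet: INDEP (SNP affects both
independently), SME (SNP -> methylation -> expression) and SEM
(SNP -> expression -> methylation).  Each is scored as a Gaussian Bayesian
network by AIC; an independent causal inference test (CIT) corroborates the
call, and agreement defines the high-confidence set.
"""

import numpy as np

from methtrio import call_triplet, simulate_triplets
from methtrio.causal import MODELS, high_confidence_calls

n_per = 50
calls, truths = [], []
for model in MODELS:
    st = simulate_triplets(model, n=200, betas=(1.0, 1.0), noise_sd=0.5,
                           seed=8, n_triplets=n_per)
    for i in range(n_per):
        calls.append(call_triplet(st.s[i], st.m[i], st.e[i], n_perm=200, seed=100 + i))
        truths.append(model)
high_confidence_calls(calls)

print("truth        " + "".join(f"{m:>8}" for m in MODELS))
for true in MODELS:
    row = [
        sum(1 for c, t in zip(calls, truths) if t == true and c.bn_call == m)
        for m in MODELS
    ]
    print(f"{true:12s}" + "".join(f"{v:8d}" for v in row))

hc = [(c, t) for c, t in zip(calls, truths) if c.hc_flag]
precision = np.mean([c.bn_call == t for c, t in hc])
print(f"\nhigh-confidence calls: {len(hc)}/{len(calls)}  precision={precision:.2f}")
one = calls[n_per]  # an SME triplet
rl = {m: round(v, 3) for m, v in one.relative_likelihood.items()}
print(f"example SME triplet: relative likelihoods {rl}, "
      f"CIT p_SME={one.p_sme:.3f} p_SEM={one.p_sem:.3f} -> call {one.cit_call}")
# The recovery matrix is strongly diagonal at these effect sizes; relative
# likelihood 1 marks the winning model and the CIT p-values show which
# mediation direction (if any) is statistically supported.
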