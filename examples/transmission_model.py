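"""The analytic transmission probability and the delta bound.

For a heterozygous parent of an affected child, the probability of having
transmitted the mutant allele exceeds 1/2 exactly when the variant raises
disease risk; with a relative-risk ceiling gamma it cannot exceed the
delta bound, which shrinks as the allele becomes more common.
"""

import rvtrio as rv

print("transmission probability p(q, rr) under a dominant model:")
for rr in (1.0, 2.0, 5.0):
    row = [rv.transmission_probability(q, rr) for q in (0.001, 0.01, 0.1)]
    print(f"  rr={rr:3.0f}: " + "  ".join(f"{p:.4f}" for p in row))

print("\ndelta bound at gamma=5 (the ceiling used by the mixture LRT):")
for q in (0.001, 0.01, 0.03, 0.1):
    print(f"  q_hat={q:5.3f}: delta={rv.delta_bound(q, 5.0):.4f}")

# rr=1 always gives 1/2 (no association); as q -> 0 the bound approaches
# gamma/(1+gamma) = 5/6, so rare variants are allowed larger random effects.
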