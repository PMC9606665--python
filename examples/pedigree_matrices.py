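"""Pedigree relationship matrices: A, its direct inverse, and inbreeding.

Builds the numerator relationship matrix for a family with a full-sib
mating, shows that the diagonal carries 1 + F, and verifies that the
rule-based inverse reproduces the dense inverse exactly.
"""

import numpy as np

from kinvar import build_A, build_A_inverse, compute_inbreeding, make_fixture

ped = make_fixture("fullsib")  # founders 1,2; full sibs 3,4; their offspring 5
A = build_A(ped)
F = compute_inbreeding(ped)

print("pedigree:", ped.records())
print("A =\n", A.values)
print("inbreeding F =", F)
# individual 5 has full-sib parents: a(3,4) = 0.5, so F5 = 0.25 and A55 = 1.25

Ainv = build_A_inverse(ped)
residual = np.abs(Ainv.values @ A.values - np.eye(len(ped))).max()
print(f"max |A^-1 A - I| = {residual:.2e}")
# the Henderson-rule inverse is exact (residual at machine precision) because
# the Mendelian-sampling variances account for parental inbreeding
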