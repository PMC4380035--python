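"""The substitution-model space: GTR rate linkages, discrete-Gamma rates,
and the empirical amino-acid catalog.

A rate linkage groups the six DNA exchangeability slots (AC, AG, AT, CG,
CT, GT); every grouping is a time-reversible sub-model of GTR, and there
are Bell(6) = 203 of them.  The discrete-Gamma model approximates
continuous rate variation by c equiprobable categories with unit mean.
"""

import numpy as np

from phylokit import (SubstitutionModel, discrete_gamma_rates,
                      empirical_aa_model_names, enumerate_gtr_linkages)

linkages = enumerate_gtr_linkages()
print(f"{len(linkages)} time-reversible DNA rate linkages (Bell(6))")
hky = next(l for l in linkages if l.rgs == "010010")
print(f"example, HKY/K80 linkage {hky.rgs}: classes {hky.classes()}")

for alpha in (0.2, 0.5, 1.0, 5.0):
    rates = discrete_gamma_rates(alpha, 4)
    print(f"alpha={alpha:4}: category rates "
          + ", ".join(f"{r:.3f}" for r in rates))
print("smaller alpha = stronger among-site rate variation;"
      " each vector averages exactly 1.")

names = empirical_aa_model_names()
print(f"\n{len(names)} empirical amino-acid models: {', '.join(names)}")
wag = SubstitutionModel.empirical_aa("WAG")
db = wag.freqs[:, None] * wag.Q
print(f"WAG detailed-balance residual: {np.abs(db - db.T).max():.2e}"
      " (reversibility holds by construction)")
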