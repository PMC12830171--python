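"""Point-dose feasibility: how much more dose can a previously treated OAR take?

Fills a one-row worksheet for a spinal-cord-like constraint: cumulative limit
A = 60 EQD2 Gy, prior accumulated point dose P = 35 EQD2 Gy, new plan in 5
fractions, alpha/beta = 3 Gy.
"""

import pandas as pd

import redose as rd

sheet = pd.DataFrame({
    "oar": ["cord"],
    "constraint_A_eqd2": [60.0],
    "prior_P_eqd2": [35.0],
    "n_fractions": [5],
    "alpha_beta": [3.0],
})
filled = rd.fill_worksheet(sheet)
print(filled.round(4).to_string(index=False))

# The budget column is A - P = 25 EQD2 Gy. The allowed total (~18.6 Gy in 5
# fractions, ~3.72 Gy/fraction) is LESS than 25 Gy physical because at
# 3.72 Gy/fraction each physical Gy is biologically worth more than at the
# 2 Gy/fraction reference. Forward-converting the allowed total reproduces
# the budget exactly:
r = rd.point_dose_feasibility(60.0, 35.0, rd.FractionationScheme(5), 3.0)
check = rd.eqd2_forward(r.allowed_total, 5, 3.0)
print(f"\nforward check: EQD2({r.allowed_total:.3f} Gy / 5 fx) = {check:.3f} EQD2 Gy")
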