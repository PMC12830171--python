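"""Generate nested isodose optimization structures for a reirradiation plan.

Worked example: prior near-target OAR Dmax P = 57 EQD2 Gy, new prescription
R = 60 EQD2 Gy, cumulative OAR constraint A = 60 EQD2 Gy. Because
P + R > A, the full prescription cannot be delivered over the OAR and a dose
gradient is required; the generator builds N nested shells of the prior
isodose, each with an EQD2 limit A - D_{i-1} and a physical limit for the
new 30-fraction plan.
"""

import redose as rd

bundle = rd.make_worked_example_case()
accum = rd.accumulate(bundle.courses, bundle.geometry,
                      list(bundle.structures.values()), rd.AlphaBetaMap())

oar, ptv = bundle.structures["OAR"], bundle.structures["PTV"]
P = rd.compute_near_target_dmax(accum.summed_eqd2, oar, ptv, near_margin_mm=20.0)
print(f"prior near-target OAR Dmax P = {P:.2f} EQD2 Gy")

params = rd.OptStructParams(R=60.0, A=60.0, N=5)
sset = rd.generate(params, P, accum.summed_eqd2, oar,
                   rd.FractionationScheme(30), alpha_beta=3.0)
print(f"step d = ((P + R) - A) / N = {sset.d:.2f} EQD2 Gy\n")
print(sset.limits_table().round(3).to_string(index=False))

# Each shell S_i covers the OAR voxels between prior isodose levels D_i and
# D_{i-1}; its limit_eqd2 = A - D_{i-1} is the EQD2 the new plan may add
# there, and limit_physical is that limit expressed as physical dose for the
# prescribed 30-fraction scheme.
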