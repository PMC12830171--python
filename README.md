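# redose

A TPS-vendor-agnostic toolkit for **reirradiation dose accumulation and
planning support**. When a patient needs a new course of radiotherapy in a
region that was treated before, the cumulative biological dose to organs at
risk (OARs) — not the dose of any single course — drives toxicity. Because
prior plans often live in different treatment planning systems (Eclipse,
Pinnacle, RayStation, ...), this toolkit works purely on exported dose
grids, structure sets and registration results rather than inside any one
TPS. Its users are medical physicists and dosimetrists evaluating
reirradiation feasibility and preparing planning constraints.

## What it computes

**EQD2 conversion.** Physical dose `D` delivered in `n` fractions is
converted to the equieffective dose in 2 Gy fractions under the
linear-quadratic model,

    EQD2 = D · (d + α/β) / (2 + α/β),   d = D/n,

with tissue-specific α/β taken per voxel from the *current* plan's
structures. The inverse — the physical dose in `n` fractions equieffective
to a given EQD2 — is the non-negative root of `D²/n + (α/β)·D −
EQD2·(2 + α/β) = 0`.

**Dose accumulation.** For every prior course: resample its physical dose
onto the current planning geometry through a user-supplied rigid/deformable
registration result (pull-back, trilinear), convert to EQD2, apply an
optional dose scaling factor (DSF ≤ 1, modelling partial tissue recovery),
then sum voxel-wise. Out-of-extent voxels are zero-filled and tallied so
misregistration cannot hide.

**Point-dose feasibility.** Given a cumulative constraint `A` and the prior
accumulated point dose `P` (both EQD2, typically at D0.01cc), the remaining
budget is `B = max(A − P, 0)` and the allowed new physical dose is the
inverse conversion of `B` at the new plan's fractionation — the worksheet
logic used when volumetric accumulation is impossible.

**Optimization structures.** When `P + R > A` (R = new prescription in
EQD2), the full prescription cannot be delivered over the OAR. The toolkit
builds `N` nested shells of the prior isodose inside the OAR with step
`d = ((P + R) − A)/N`, thresholds `D_i = P − i·d`, and per-shell limits
`A − D_{i−1}` (EQD2) plus the equivalent physical limit for the prescribed
scheme. Assuming each shell received its *upper* bounding isodose makes the
limits conservative voxel-by-voxel.

**DVH & scorecard.** Cumulative DVHs, Dmax / Dmean / D_xcc / D_x% / V_xGy
metrics, pass/fail scorecards against cumulative constraints, and a
machine-readable dose-sum report.

## Worked example

`examples/optimization_structures.py` runs the built-in worked-example case
(prior course calibrated so the near-target OAR Dmax is P = 57 EQD2 Gy;
R = 60, A = 60 EQD2 Gy, N = 5 shells, new plan in 30 fractions) and prints:

```
prior near-target OAR Dmax P = 57.00 EQD2 Gy
step d = ((P + R) - A) / N = 11.40 EQD2 Gy

structure  threshold_eqd2  assumed_prior_eqd2  limit_eqd2  limit_physical  n_voxels
       S1            45.6                57.0         3.0           4.749       312
       S2            34.2                45.6        14.4          19.692       114
       S3            22.8                34.2        25.8          31.779       122
       S4            11.4                22.8        37.2          42.207       114
       S5             0.0                11.4        48.6          51.514        18
```

S1 — the OAR region inside the prior 45.6 EQD2 Gy isodose — may only
receive 3 EQD2 Gy more (4.75 Gy physical over 30 fractions); shells further
from the prior high-dose region get progressively larger limits, shaping a
dose gradient that keeps the *cumulative* OAR dose at or below 60 EQD2 Gy.
The other examples cover the point-dose worksheet, multi-course
accumulation with DSFs, and DVH/scorecard reporting.

The same workflow is scriptable from a shell:

```bash
redose synth --preset worked-example --out case/
redose accumulate --bundle case/ --config config.yaml --out out/
redose optstructs --bundle case/ --out out/ --oar OAR --target PTV \
    -R 60 -A 60 -N 5 --n-fractions 30
redose report --bundle case/ --config config.yaml --out out/
```

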