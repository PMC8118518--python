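# leafgm

Leaf-level CO2 diffusion analysis for combined gas-exchange + chlorophyll
fluorescence measurements: variable-J mesophyll conductance estimation,
FvCB A/Ci fitting, photosynthetic limitation partitioning, and analysis of
intrinsic water-use efficiency under progressive soil drying.

## The problem

When a C3 leaf (the package defaults target tomato) dries down, net
photosynthesis A_n is throttled by three resistances in series: the stomata
(conductance g_s), the mesophyll path from sub-stomatal cavities to the
chloroplast stroma (g_m), and the biochemical capacity of Rubisco itself.
Quantifying each share — and how the hydraulic signal (leaf water potential
Ψ_leaf) and the chemical signal (abscisic acid, ABA) drive g_s and g_m —
requires inverting a chain of point equations on every instrument record.
`leafgm` implements that chain as a tested, scriptable pipeline:

1. **Fluorescence reduction.** Φ_PSII = (Fm′ − Fs)/Fm′ and the electron
   transport rate J_f = Φ_PSII · PPFD · α · β (defaults α = 0.84, β = 0.5).
2. **Variable-J inversion.** Equating fluorescence-based and gas-exchange
   based electron transport gives the chloroplastic CO2 mole fraction

       Cc = Γ* (J_f + 8(A_n + R_d)) / (J_f − 4(A_n + R_d)),
       g_m = A_n / (C_i − C_c),

   with R_d = R_dark/2 and Γ*, K_c, K_o scaled to leaf temperature by
   exp(c − H_a/(R·T_k)).  Records where J_f ≤ 4(A_n + R_d) or C_i ≤ C_c are
   flagged with a reason code, never dropped — the inversion's failure mode
   is informative (see the built-in ±10/20% sensitivity analysis).
3. **Limitation partition (Grassi–Magnani).** With g_sc = g_s/1.6,
   1/g_t = 1/g_sc + 1/g_m and the Rubisco-branch sensitivity
   ∂A/∂C_c = V_cmax(Γ* + K_m)/(C_c + K_m)², the relative stomatal,
   mesophyll and biochemical limitations are

       l_s = (g_t/g_sc · ∂A/∂C_c)/(g_t + ∂A/∂C_c),
       l_m = (g_t/g_m  · ∂A/∂C_c)/(g_t + ∂A/∂C_c),
       l_b =  g_t/(g_t + ∂A/∂C_c),        l_s + l_m + l_b = 1.

4. **A/Ci fitting.** V_cmax by least squares on the Rubisco-limited segment
   of the 14-point CO2 response protocol (400, 300, 200, 150, 100, 50,
   400, 400, 600 … 1600 µmol mol⁻¹).
5. **Drydown statistics.** Pooled Pearson correlation matrices, regression
   family selection by r² among {linear, exponential, logarithmic}, and
   per-day treatment-vs-control comparisons (Welch, Holm-adjusted).

Because raw greenhouse data of this kind are rarely deposited, the package
ships a seeded synthetic drydown generator (`leafgm.drydown`) that emulates
a week-long pot experiment — RSWC 82.9 → 37.3 % of field capacity, Ψ_soil
−0.40 → −1.44 MPa, ABA flat then exponential, g_s responding to drought
before g_m — with truth tables for recovery scoring.

## Worked example

```python
import numpy as np
from leafgm import (DrydownScenario, generate_observations,
                    gm_variable_j, partition_limitations)
from leafgm.pipeline import estimate_gm_table

# one record: An=20, Ci=280 umol/mol, Gamma*=40, Rd=1, Jf=147
est = gm_variable_j(An=20.0, Ci=280.0, gamma_star=40.0, Rd=1.0, Jf=147.0)
print(f"gm = {est.gm:.3f} mol m-2 s-1, Cc = {est.Cc:.1f} umol mol-1")

part = partition_limitations(gsc=0.2, gm=est.gm, dAdCc=0.099)
print(f"ls = {part.ls:.3f}, lm = {part.lm:.3f}, lb = {part.lb:.3f}")

# synthetic drydown: estimate gm on every record, score against truth
tables = generate_observations(DrydownScenario(seed=1), include_aci=False)
estimates = estimate_gm_table(tables["observations"])
merged = estimates.merge(tables["truth"], on=["plant_id", "day", "treatment"])
drought = merged[merged["treatment"] == "drought"]
err = np.abs(drought["gm"] - drought["gm_true"]) / drought["gm_true"]
print(f"median relative gm error over {len(drought)} drought records: "
      f"{err.median():.3f}")
```

prints

```
gm = 0.250 mol m-2 s-1, Cc = 200.0 umol mol-1
ls = 0.262, lm = 0.209, lb = 0.529
median relative gm error over 42 drought records: 0.087
```

i.e. the inversion puts the chloroplastic CO2 at 200 µmol mol⁻¹ (an 80
µmol mol⁻¹ drawdown below C_i) giving g_m = 0.25 mol m⁻² s⁻¹; for that leaf
the biochemical share of the total limitation (53 %) still exceeds the
stomatal (26 %) and mesophyll (21 %) shares; and under 2 % multiplicative
observation noise the variable-J estimate lands within ~9 % of the true
mesophyll conductance for a typical drought record.

There is also a CLI:

```sh
leafgm simulate --seed 1 --outdir run/sim
leafgm gm --observations run/sim/observations.csv --out run/estimates.csv
leafgm pipeline --config config.yaml --outdir run/full
```

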