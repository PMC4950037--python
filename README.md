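# mamsrb — risk–benefit MAMS trial designs

`mamsrb` designs multi-arm multi-stage (MAMS) clinical trials in which
treatment selection and hypothesis testing use an **efficacy endpoint and a
safety endpoint jointly**.  It is written for trial statisticians planning
seamless phase II/III studies: several doses or regimens enter against a
shared control, the arm with the best risk–benefit trade-off among those
meeting a minimum safety requirement is carried forward, and the final
comparison must demonstrate that the selected arm is *both* effective and
safe.

## The model and the test

Each patient on arm `k` (arm 0 = control) contributes a bivariate normal
response with known standard deviations and within-subject correlation ρ:

    (Y_Eik, Y_Sik) ~ N2( (μ_Ek, μ_Sk), [[σ_E², ρσ_Eσ_S], [ρσ_Eσ_S, σ_S²]] )

With n patients per arm, evidence about the treatment effects
θ_Tk = μ_Tk − μ_T0 is carried by the score statistics

    Z_Tk = I_T (μ̂_Tk − μ̂_T0),   I_T = n / (2σ_T²),   T ∈ {E, S},

which have variance I_T and share correlation ½ across arms through the
common control.  For each arm the null hypothesis H0k: {θ_Ek ≤ 0} ∪
{θ_Sk ≤ 0} says the arm is ineffective *or* unsafe.

At the first analysis, arms with Z_Sk > c (default c = 0: at least as safe
as control) are eligible; among them the trial selects the maximizer of the
objective

    O_k = w_E Z_Ek/√I_E + w_S Z_Sk/√I_S,     w_E² + w_S² = 1.

If no arm is eligible the trial stops for futility.  Otherwise the selected
arm i* is tested against control: reject H0,i* only if Z_E,i* ≥ u_E **and**
Z_S,i* ≥ u_S (with J analyses, error-spending upper and lower boundaries on
both statistics, binding futility, selection at the first look only).

The boundaries (u_E, u_S) are calibrated so that the familywise error rate
is controlled at level α in the strong sense, using the two worst-case
limiting configurations (all safety effects → ∞ with null efficacy, and
vice versa); the per-arm information I₁* is searched so that the
disjunctive power — the chance of rejecting at least one false H0k under
θ_E = (δ₀, …, δ₀, δ) with all arms safe — reaches 1 − β.  Every
numerically integrated quantity has a Monte-Carlo twin, and the simulator
doubles as an operating-characteristics engine.

## Worked example

Four active doses against control, α = 0.05, power 0.9 at the desirable
standardized effect δ = 0.545 with minimum clinically important effect
δ₀ = 0.178, equal selection weights, ρ = 0.4, unit variances:

```python
from mamsrb import DesignSpec, solve_information

spec = DesignSpec(n_arms=4, delta=0.545, delta0=0.178, rho=0.4)
sol = solve_information(spec)
print(f"I1* = {sol.I_star:.3f}  n = {sol.n_unrounded:.3f} -> n* = {sol.n_star}")
b = sol.boundaries_at_I_star
print(f"u_E = {b.u_E:.3f}  u_S = {b.u_S:.3f}")
print(f"power at n* = {sol.attained_power:.4f}")
```

prints

```
I1* = 47.136  n = 94.272 -> n* = 95
u_E = 14.464  u_S = 14.464
power at n* = 0.9019
```

So each of the five arms needs information 47.14 (94.3 patients,
rounded up to 95); the selected arm is declared effective and safe only if
both its score statistics exceed 14.46 (≈ 2.11 on the standardized scale —
well above the unadjusted 1.64, the price of selecting the best of four
arms and testing two endpoints).  With equal weights and variances the two
boundaries coincide; rounding to whole patients pushes the attained power
just above the 90% target.

The same design from the shell, plus a two-stage version and an
operating-characteristics sweep:

```sh
mamsrb design single-stage --k 4 --delta 0.545 --delta0 0.178 --rho 0.4
mamsrb design multi-stage  --k 4 --delta 0.545 --delta0 0.178 --rho 0.4 \
    --stages 2 --fractions 0.5,1.0 --spend-upper pow:2 --spend-lower pow:2
mamsrb oc mixed-null --k 4 --delta 0.545 --delta0 0.178 --rho 0.4 \
    --reps 10000 --seed 1 --out mixed.csv
```

Every subcommand also accepts `--config design.yaml` (write one with
`DesignSpec.to_config`) with flags acting as overrides.

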