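# dynblup

Simulation and estimation of reaction-norm evolution in changing
environments with **dynamical BLUP**: best linear unbiased prediction from
a linear mixed model whose incidence matrix and residual covariance track
the environmental cues, with the mean reaction-norm parameters updated
each generation by Robertson's secondary theorem of natural selection.

## The problem

A linear reaction norm maps an environmental cue to a phenotype: for trait
*j* of individual *i*,

    y_ji = ābar_j + a'_ji + v_ji + Σ_k (b̄_jk + b'_jk,i + η_jk,i) u_k,

where ā and B̄ are the evolving mean intercepts and plasticity slopes,
(a', b') are additive genetic deviations with covariance **G** across
effects (and optionally a relationship matrix **A** across individuals),
and (v, η) are iid nonadditive deviations. When the fitness optimum θ_t
moves — say, under a climate trend in the cues — the population tracks it
through a mix of plasticity (the slopes acting on the shifted cues) and
microevolution (changes in ā, B̄). Disentangling those two components from
field-like data is the point of the method: at each parent generation the
model

    y_t = X ȳ_t + (Z(u_t) ⊗ I_n) x_t + e_t,
    Var(x_t) = G ⊗ A,   Var(e_t) = R(u_t) ⊗ I_n,
    r_j(u) = σ²_vj + Σ_k u_k² σ²_ηjk,

is solved with Henderson's mixed-model equations, and the mean parameters
are advanced by the secondary theorem,

    Δz̄_t = f_t · cov(w_i, ẑ'_i),

the covariance of relative fitness with each BLUP-estimated random effect
(scaled by the offspring fraction f_t when generations overlap). The
well-known BLUP shrinkage of random-effect variance — var(â') =
G²/(G+σ²) in the diagonal case — is exactly what makes this covariance the
correct selection response. Comparator update rules are included: the
selection-gradient (GRAD) form G Zᵀ P_yy⁻¹ cov(w, y), identical to the
BLUP rule when A = I and wrong (by design) otherwise, and the raw
multivariate breeder's equation G P⁻¹ cov(w, ·) on the true individual
parameters, usable only in simulation.

It is aimed at quantitative geneticists studying plasticity-vs-evolution
questions (e.g. climate-change responses of wild populations) who want a
transparent, fully synthetic testbed for the updating rules.

## Worked example

The built-in study system has two traits and two cues (think breeding date
vs spring temperature, habitat choice vs rainfall), n = 100, 60
generations, cue ramps starting at generation 10, Gaussian fitness with
width ω² = 10 and peak 4 descendants:

```python
import dynblup as db

cfg = db.toy_run_config(seed=1, methods=("robertson", "grad", "breeder"))
runs = db.run_generation_loop(cfg)
for m, traj in runs.items():
    a1, a2, b11, b12, b21, b22 = traj.params[-1]
    print(f"{m:9s} abar=({a1:+.3f}, {a2:+.3f})  b11={b11:+.3f}  "
          f"b22={b22:+.3f}  mean W = {traj.Wbar.mean():.2f}")
print("max |robertson - grad| gap:",
      f"{db.method_gap_summary(runs['robertson'], runs['grad']):.2e}")
```

prints

```
robertson abar=(-1.377, -0.905)  b11=-0.985  b22=-0.764  mean W = 3.20
grad      abar=(-1.377, -0.905)  b11=-0.985  b22=-0.764  mean W = 3.20
breeder   abar=(-1.354, -0.918)  b11=-0.994  b22=-0.739  mean W = 3.20
max |robertson - grad| gap: 2.22e-16
```

Both traits start at the stationary-optimal slopes (−0.5, the regression
of the fluctuating optimum on the cue) and intercepts 0; as the mean cues
ramp up and the optima move at −2 × the mean cue, the intercepts evolve
downward and the slopes steepen, lagging the optimum as any first-order
tracking system does. With unrelated individuals the Robertson/BLUP and
GRAD updates coincide to machine precision; the breeder's-equation
trajectory differs at n = 100 and approaches them as n grows. Repeating
the run with the banded high-relatedness matrix (`rel_kind="band"`: 1 on
the diagonal, 1/2 next to it, 1/4 elsewhere) separates the methods —
`method_gap_summary` reports a gap of 0.115 where A = I gave 2e−16 —
because only the BLUP rule uses A.

The same studies are available from the shell:

```sh
dynblup simulate --out out/sim --seed 1
dynblup compare  --out out/cmp --seed 1 --rel band
dynblup drift    --out out/drift --seed 1 --reps 100
dynblup overlap  --out out/ovl --seed 1 --rel band
dynblup envcheck --out out/env --seed 1
```

Each command writes tidy CSV trajectories and/or a JSON summary plus a
`config.yaml` echo of the fully resolved configuration and seed.

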