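# cohortdem

Stage-structured cohort demography for insect life-table experiments:
estimate a Lefkovitch projection matrix from daily cohort census and
oviposition data, derive the population growth rate λ, net
reproductive rate R₀, mean generation time T and the full
eigen-structure, and decompose treatment differences in λ with a
fixed-design life table response experiment (LTRE).

The package is built around the laboratory design used to study the
effect of antibiotic diets on the coffee berry borer (*Hypothenemus
hampei*): per diet, five cohorts of 20 eggs censused daily for 50 days
through the egg → larva → pre-pupa → pupa → juvenile → adult cycle,
plus 50 females whose oviposition is recorded daily for two months.
Because no raw rearing data of this kind are publicly deposited, an
individual-based simulator with known ground truth generates the data
the pipeline consumes, calibrated to the published stage durations,
fecundities, oviposition fractions and sex ratios.

## The model

With a 6-day projection interval, stage abundances evolve as
N_{t+1} = A N_t where

        ⎡ P₁  0   0   0   0   F  ⎤
        ⎢ G₁  P₂  0   0   0   0  ⎥
    A = ⎢ 0   G₂  P₃  0   0   0  ⎥
        ⎢ 0   0   G₃  P₄  0   0  ⎥
        ⎢ 0   0   0   G₄  P₅  0  ⎥
        ⎣ 0   0   0   0   G₅  P₆ ⎦

Pᵢ is the per-interval probability of surviving and remaining in stage
i, Gᵢ of surviving and molting to stage i+1, and F the fertility of
adult females (eggs per female per interval). λ is the dominant
eigenvalue of A; R₀ the dominant eigenvalue of F(I−U)⁻¹ (U = survival
transitions); T = ln R₀ / ln λ. The LTRE attributes
λ_treat − λ_ref to individual transitions via
C_ij = Δa_ij · S_ij(A_mid), with sensitivities S = v wᵀ evaluated at
the midpoint matrix.

Pᵢ and Gᵢ are estimated by direct interval-aligned counting of the
daily census (pooled over windows and cohorts), F from total panel
eggs per female-day, and adult survival is pinned at 0.99 per interval
because adult deaths are essentially unobservable in a 50-day census.
See `docs/methods.md` for conventions, defaults and known biases.

## Worked example

Run the numbered analysis scripts (seed 1), or equivalently the
`cohortdem run` CLI:

```
python analysis/01_simulate_cohorts.py 1
python analysis/02_estimate_matrices.py
python analysis/03_demography.py
python analysis/04_ltre.py
python analysis/05_treatment_stats.py
```

`02` prints the estimated matrices, e.g. for the control diet:

```
control:
  P = [0.275, 0.564, 0.0, 0.13, 0.0, 0.99]
  G = [0.543, 0.314, 0.842, 0.796, 0.931]
  F = 2.032 eggs/female/interval
```

(about half the eggs survive each early interval and essentially all
pre-pupae molt within one 6-day step; each adult female contributes
~2 eggs per interval). `03` writes `results/life_table_parameters.csv`:

```
        diet  lambda_mean  lambda_se  R0_mean  R0_se  T_days_mean  T_days_se
     control        1.214      0.012    81.53  11.21       135.89       2.74
  penicillin        1.215      0.018    85.33  14.13       136.74       5.21
tetracycline        1.085      0.008    16.97   2.20       208.39       8.99
```

λ is per 6-day interval: the control population multiplies by ~1.21
every 6 days while the antibiotic-treated one manages ~1.09, its R₀
is ~5× lower, and its generations are ~50% longer — the same
qualitative pattern as the published experiment (λ and R₀ reduced, T
increased under tetracycline). `04` decomposes the λ difference:

```
tetracycline vs control:
  delta lambda observed = -0.1275, sum of contributions = -0.1153
  largest |contribution|: F (fertility, -0.1193)
```

i.e. essentially the entire growth-rate reduction is attributable to
the fertility entry, not to survival or development — the headline
LTRE result. `05` reproduces the oviposition chi-square (here
12.11 with df = 2 on the simulated panel; the published table itself
gives 11.50) and runs ANOVAs across the per-cohort parameters.

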