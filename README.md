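# memokin

Turnover kinetics of CD57⁻ and CD57⁺ memory T cells from in vivo
heavy-water labeling and single-molecule telomere-length data.

CD57 is the classic surface marker of "replicative senescence" in human
memory T cells — yet CD57⁺ memory cells accumulate with age and expand
under chronic infection. Are they dead-end cells replenished by
conversion from the CD57⁻ pool, or do they self-renew by dividing in
place? `memokin` implements the quantitative analysis that separates the
two mechanisms: compartmental ODE models of deuterium label uptake,
telomere division-index dynamics, simultaneous nonlinear least-squares
fitting, nested model comparison, and a synthetic-data generator that
reproduces the study design so every stage is testable without access to
the (undeposited) raw measurements. It is written for quantitative
immunologists and biostatisticians analysing stable-isotope labeling
studies of lymphocyte dynamics.

## The model

CD57⁻ cells (x₁) convert into CD57⁺ cells (x₂) at rate m while both
compartments proliferate (p) and disappear (z):

    dx₁/dt = p₁x₁ − z₁x₁
    dx₂/dt = p₂x₂ − z₂x₂ + mx₁

During oral ²H₂O intake, body-water enrichment follows the empirical
curve U(t) = f(1 − e^(−δt)) + βe^(−δt) for t ≤ τ (exponential washout
after τ = 49 days), and the fractions of labeled deoxyadenosine obey

    dL₁/dt = p₁·b_w·U(t) − z₁*L₁
    dL₂/dt = (p₂ + mR)·b_w·U(t) − z₂*L₂

with amplification factor b_w = 3.5 and pool-size ratio R = x₁/x₂. The
label data identify only the sum p₂ + mR; the split comes from telomere
erosion. Mean division indices follow dμ₁/dt = 2p₁,
dμ₂/dt = 2p₂ − mR(μ₂ − μ₁ − K), giving a steady-state telomere-length
difference (CD57⁻ minus CD57⁺, ε = 50 bp lost per division)

    Δ_C = ε(2(p₂ − p₁)/mR + K)

which is fitted jointly with the label curves. The headline statistic is
the **self-renewal contribution** 100·p₂/(p₂ + mR): the percentage of
newly generated CD57⁺ cells arising from division within the CD57⁺ pool.
The p₂ = 0 model ("CD57⁺ cells cannot divide") is tested against the
full model by F test and small-sample AICc.

See `docs/methods.md` for assumptions, weighting, standard errors,
optimizer details and known limitations.

## Worked example

Simulate a three-volunteer CD4 study at the published median rates and
run the full pipeline (body-water fit → joint fits → model comparison):

```bash
memokin simulate -n 3 --lineage CD4 --seed 7 --outdir study
memokin fit --saliva study/saliva.csv --labels study/labels.csv \
            --telomeres study/telomeres.csv --ratios study/ratios.csv \
            --outdir out
```

which prints (rates in % per day, standard errors beside each estimate):

```
volunteer_id lineage   p1  se_p1   z1  se_z1   p2  se_p2   z2  se_z2   mR  se_mR  self_renewal
       SIM01     CD4 0.47   0.02 1.13   0.10 0.58   0.03 1.64   0.11 0.02   0.02            97
       SIM02     CD4 0.48   0.03 1.24   0.15 0.56   0.03 1.48   0.15 0.01   0.01            99
       SIM03     CD4 0.52   0.03 1.45   0.16 0.58   0.03 1.53   0.15 0.01   0.01            99

volunteer_id lineage   p1   z1   p2   z2   mR  self_renewal
      Median     CD4 0.48 1.24 0.58 1.53 0.01          99.0
```

The generating truth was p₁ = 0.53, z₁* = 1.43, p₂ = 0.59, z₂* = 1.65,
mR = 0.02 %/day — the estimates scatter around it within a couple of
standard errors, and the self-renewal column says ≳95% of new CD57⁺
cells come from in-place division, not conversion. `out/comparison.csv`
holds the nested test, e.g. for SIM01: p ≈ 3×10⁻²⁴ and ΔAICc = 145 —
the model without CD57⁺ proliferation is overwhelmingly rejected. The same workflow runs
from Python via `memokin.read_study`, `memokin.TurnoverModel(...).fit()`
/ `memokin.fit_nested_pair`, and `memokin.run_pipeline`; results objects
expose `params`, `bse`, `conf_int()`, `summary()`, `predict()` and
`plot()`.

A parameter-recovery study (bias, RMSE, Wald coverage per parameter) is
one call:

```bash
memokin recover -r 50 --lineage CD4 --seed 1 --nested
```

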