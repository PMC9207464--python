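# trajmoe

**Sparse mixture-of-experts subtyping of longitudinal cohorts with
genetic-marker gating.**

Chronic diseases such as Parkinson's disease progress differently in
different patients, and a recurring goal in biostatistics is to split a
cohort into *subtypes* that capture those progression patterns — and to ask
which genetic variants predispose a patient to one subtype rather than
another. `trajmoe` addresses both questions in a single model, for
statisticians and genetic epidemiologists working with clinical follow-up
data (repeated scores at irregular visit times) alongside a high-dimensional
genotype matrix.

## The model

Patients i = 1..N carry V clinical scores observed over visits j at times
t_ij, and L additively coded markers g_i ∈ {−1, 0, 1}^L (typically L ≫ N).
A latent subtype z_i ∈ {1..K} ties the two together:

- **Experts** (outcome model): per subtype, each score follows a polynomial
  trajectory with Gaussian noise,

  ```
  y_iv(j) | z_i = k  ~  N( Σ_p α_vkp t_ij^p ,  σ_vk² ),     p = 0..P
  ```

- **Gate** (membership model): the markers act as concomitant covariates
  through a multinomial logistic model with reference class 1,

  ```
  P(z_i = k | g_i)  =  exp(ω_k0 + ω_kᵀ g_i) / Σ_k′ exp(ω_k′0 + ω_k′ᵀ g_i)
  ```

An ℓ1 penalty λ Σ_k ‖ω_k‖₁ makes the gate sparse, so fitting the model
simultaneously clusters the trajectories and selects the markers associated
with subtype membership. Inference is a (classification) EM algorithm with
λ re-chosen by cross-validation inside every M step, multi-start
initialization scored by BIC, BIC selection of K and P, and an unpenalized
refit of the selected coefficients for debiased estimates with Wald
intervals. See `docs/methods.md` for the full account.

## Worked example

`examples/01_simulate_and_fit.py` simulates a 90-patient, 2-subtype toy
cohort (30 markers, 2 of them driving membership) and fits the model:

```
$ python examples/01_simulate_and_fit.py
cohort: 90 patients, 2 clinical scores, 30 markers
converged in 7 iterations, BIC 1884.8, selected lambda 0.0568
ARI against the simulated subtypes: 0.912 (1 = perfect recovery)
selected markers (0-based): [0, 1, 2, 3, 5, 8, 10, 14, 15, 17, 21, 22, 23]; truly active: [0, 1]
debiased gate coefficients on the selected markers (class 2 vs reference class 1):
  marker 0: omega = +2.97 [+1.35, +4.59] 95% CI
  marker 1: omega = -2.06 [-3.49, -0.64] 95% CI
  marker 2: omega = -1.79 [-3.10, -0.48] 95% CI
  marker 3: omega = +0.12 [-0.93, +1.17] 95% CI
  marker 5: omega = +0.62 [-0.38, +1.62] 95% CI
  marker 8: omega = +0.72 [-0.17, +1.61] 95% CI
  marker 10: omega = -1.22 [-2.61, +0.17] 95% CI
  marker 14: omega = +1.09 [-0.05, +2.23] 95% CI
  marker 15: omega = -1.54 [-2.74, -0.34] 95% CI
  marker 17: omega = -0.32 [-1.41, +0.77] 95% CI
  marker 21: omega = +1.45 [-0.11, +3.00] 95% CI
  marker 22: omega = -0.58 [-1.61, +0.44] 95% CI
  marker 23: omega = +1.16 [-0.18, +2.51] 95% CI
```

Reading the output: the fitted partition agrees closely with the simulated
truth (adjusted Rand index 0.91). The CV-optimal λ deliberately overselects
on a cohort this small — 13 markers kept — but the two truly active markers
(0 and 1, simulated effects +2 and −2) carry the strongest debiased
coefficients, and most false positives have Wald intervals covering zero.
Carrying the alternative allele of marker 0 roughly multiplies the odds of
subtype 2 by e² relative to the reference subtype.

The other scripts in `examples/` walk through BIC model selection over
(K, P), the benchmark comparing the integrative fit against the 2-step
baseline (cluster first, regress markers afterwards) and oracle variants,
and the preprocessing helpers (covariate adjustment by OLS residuals,
{0,1,2} → {−1,0,1} genotype recoding, CADD/allele-frequency marker
screening).

A thin CLI covers the same ground from the shell:

```bash
trajmoe simulate toy --out-dir sim --seed 3
trajmoe fit --clinical sim/clinical.csv --genotypes sim/genotypes.csv --K 2 -o fit_out
trajmoe select --clinical sim/clinical.csv --genotypes sim/genotypes.csv
trajmoe benchmark toy -n 5 --methods integrative,two_step
```

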