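# carnidens

Bayesian spatially explicit density estimation for terrestrial carnivore
communities surveyed with camera traps and live traps.

## The problem

Estimating how many foxes, mongooses, martens, badgers, genets or feral cats
share a landscape is hard because detection is imperfect and most carnivores
carry no usable individual marks. `carnidens` implements a single Poisson
encounter model that covers the three classical spatially explicit settings
and lets a whole community be analysed with one machinery:

* **SCR** (spatial capture-recapture) when every detected individual is
  identifiable,
* **SMR** (spatial mark-resight) when only a marked/recognisable subset is,
* **SC** (spatial counts) when nobody is.

Each individual *i* carries a latent activity centre *s_i*, uniform on a
state space *S*. Counts of individual *i* at device *j* in weekly occasion
*k* are Poisson,

    y_ijk ~ Poisson( z_i · (1 − dead_ik) · λ0_ijk · exp(−‖s_i − x_j‖² / 2σ²) · e_jk ),

with effort *e_jk* the days device *j* operated in occasion *k*, `dead` a
known-removal matrix, and a log-linear baseline rate

    log λ0_ijk = α0 + w1·b1·Lb_ik + w2·b2·tt_j + w3·b3·t_k,

where `Lb` is a prior-capture (behavioural response) covariate, `tt`
distinguishes cameras from live traps, `t` is a standardised occasion trend,
and `w ∈ {0,1}` are Kuo–Mallick model-selection indicators (a spike-and-slab
variant is also provided). Unidentified animals enter through
device-by-occasion totals, which by Poisson superposition are Poisson with
mean Λ_jk = Σ_i μ_ijk over a data-augmented pool of latent individuals;
population size is N = Σ z_i and density D = N / area(S). Telemetry fixes of
collared animals (bivariate normal around the shared centre) sharpen the
movement scale σ, and σ can alternatively receive an informative prior
derived from literature home ranges via σ = √(HR / (π·q)), with *q* the 0.95
chi-square quantile at 2 df (5.99).

Inference is a bespoke, fully reproducible Metropolis-within-Gibbs sampler
(numba-compiled) with exact Gibbs steps for z and ψ, multi-chain
Gelman–Rubin diagnostics, equal-tailed 95% credible intervals and CV
reporting. A synthetic-survey generator reproduces the survey design the
model targets (66 cameras on a 500-m grid plus 69 live traps, 98 days in 14
weekly occasions, device downtime, removals, telemetry), so the whole
pipeline is testable end to end.

## Worked example

```python
import numpy as np
import carnidens as cd
from carnidens import report

# survey design: smallest home range in the guild ~300 ha
sigma = cd.sigma_from_home_range(300e4)        # 399.2 m -> grid of ~500 m
lo, hi = cd.spacing_range(sigma)               # (399.2, 798.5)

# a study-like synthetic survey: 40 animals, 20% marked, 135 devices
truth = cd.SimTruth(N=40, sigma=400.0, alpha0=np.log(0.05),
                    marked_fraction=0.2, seed=1)
sim = cd.simulate_survey(truth)

spec = cd.ModelSpec(model_class="SMR", sigma_init=400.0, M=300,
                    priors=cd.PriorSpec(sigma_prior=("uniform", 2000.0)))
cfg = cd.SamplerConfig(n_chains=3, n_iter=5000, burn_in=1000, seed=1)
res = cd.run_chains(sim.enc, sim.space, spec, cfg)

print(report.rhat_table(res))
d = report.summarize(report.density_posterior(res))
print(f"D = {d.mean:.2f} /km2 (95% BCI {d.bci_low:.2f}-{d.bci_high:.2f}; "
      f"CV {d.cv:.2f})")
```

prints (density in individuals/km², state-space area 41.97 km²):

```
  parameter      rhat  converged
0         N  1.042206       True
1     sigma  1.019092       True
2    alpha0  1.031498       True
D = 2.06 /km2 (95% BCI 1.33-3.03; CV 0.20)
```

All three R-hat values are below the 1.1 convergence threshold; the
credible interval is the equal-tailed 2.5–97.5% band of the posterior of
N / area(S). The same workflow is available from the shell:

```bash
carnidens design --home-range-ha 300
carnidens simulate --preset paper-like --seed 7 --out fixtures/
carnidens fit --data fixtures/ --model smr --species red_fox --seed 1 --out out/
carnidens summarize --in out/ --out report.json --area-km2 42
```

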