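# sensearch

Encounter-rate kinetics for predators that use sensory information.

Classical models of species interactions assume searchers move
independently of their targets, which makes the encounter rate scale
linearly with target density (mass action). `sensearch` simulates and
analyses what happens when that assumption is dropped: a predator that
scans for cues, decodes them, and adjusts its movements can encounter prey
at a rate that is strongly *nonlinear* in prey density — with consequences
that propagate all the way to predator–prey population dynamics.

The package is aimed at movement ecologists and theoretical population
biologists. It provides:

* **Search simulators** on a periodic 2-D arena for three searcher types
  built from one Bayesian movement rule
  `p(move) ∝ L(signal | move) × psi(move)`, where `psi` is a (truncated)
  Pareto step-length kernel with uniform headings and `L` is the decoding
  function: a point mass at the nearest prey (*perfect sensing*), a
  constant (*purely random*), or the Poisson likelihood of a directionless
  scent count (*signal-modulated*), with scent arrival rates following the
  2-D diffusion–dissipation steady state
  `lambda(d) = R0 K0(d/xi_len)/K0(a/xi_len)`.
* **Closed-form theory** for the perfect searcher: for Poisson prey at
  density `rho` in `n` dimensions, `rate = v / E[(D − delta)+]` with
  `E[(D − delta)+] = ∫_delta^∞ exp(−rho V_n r^n) dr`, which scales as
  `rho^(1/n)` at low density; plus first-passage baselines for proximity
  (annulus) encounter probabilities.
* **Segmented power-law regression** (breakpoints and per-regime exponents
  fitted jointly by iterative linearization, model count chosen by AIC) for
  detecting multiple scaling regimes in (density, rate) data — usable
  standalone on any CSV with `density` and `rate` columns.
* **Population dynamics**: the Wald-equation functional response
  `g(N) = M f(N) T / (1 + f(N) T)` built from any encounter-rate function
  `f`, inside a generalized Rosenzweig–MacArthur model with fixed-point,
  stability, `K_crit` and limit-cycle analysis.

See `docs/methods.md` for the full model description and parameter
rationale.

## Worked example

Simulate a small density sweep for a purely random and a signal-modulated
searcher, and fit the random searcher's scaling exponent:

```python
import numpy as np
from sensearch.config import config_from_dict
from sensearch.experiment import sweep_rates
from sensearch.scaling import fit_powerlaw

densities = [0.5, 2.0, 10.0, 50.0]   # prey per 10^4 body lengths^2

rates = {}
for strategy in ("uniform", "scent_modulated"):
    cfg = config_from_dict({"strategy": strategy, "seed": 42})
    table, _ = sweep_rates(cfg, densities=densities, replicates=100)
    rates[strategy] = table.data["rate"].to_numpy()

print(np.round(rates["scent_modulated"] / rates["uniform"], 2))
fit = fit_powerlaw(sweep_rates(config_from_dict(
    {"strategy": "uniform", "seed": 42}), densities=densities,
    replicates=100)[0])
print(round(fit.slopes[0], 3))
```

Output:

```
[4.61 3.78 5.4  6.67]
1.051
```

The first line is the fold advantage of the scent-using searcher over the
purely random one at each density — sensing raises the encounter rate
roughly four- to seven-fold here. The second is the random searcher's fitted
log–log slope: encounter rate almost exactly proportional to prey density,
the mass-action prediction. The signal-modulated searcher's curve, by
contrast, bends: fitting it with `fit_segmented`/`compare_regimes` over a
denser sweep selects a multi-regime model whose upper regime is sublinear
(slope ≈ 0.8), because once prey spacing drops below the informative scent
range the searcher no longer pays the full cost of finding each prey.

The same machinery drives the population-level result: feeding a sublinear
encounter-rate function through the Wald functional response into the
Rosenzweig–MacArthur model lets predators depress prey to lower densities
and persist at lower carrying capacities than mass-action predators
(`sensearch.popdyn.steady_state_sweep`).

A thin CLI wraps these workflows:

```bash
sensearch simulate --strategy scent_modulated --density 2.0 --replicates 100 \
    --k 1 --seed 42 --out results/scent
sensearch theory --curve perfect --out curve.csv
sensearch fit results/scent.rates.csv --out fit.json
sensearch popdyn --response power:1.0,0.5 --sweep K=0.5:50:100 --out sweep.csv
```

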