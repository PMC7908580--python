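# maupmtup

Sensitivity of small-area environmental-health associations to the
**modifiable areal unit problem** (MAUP) and the **modifiable temporal unit
problem** (MTUP).

Studies that relate an environmental exposure (here: mean daily rainfall, a
drought proxy) to small-area health event counts (here: mental
health-related emergency department presentations) must choose *one* spatial
aggregation of the underlying units and *one* temporal window for outcome
and exposure. Different choices can produce materially different — even
opposed — effect estimates. This package makes that sensitivity measurable:
it simulates small-area data with a known ground truth, re-prepares the same
data under many spatial zonations and exposure-lag window arrangements, fits
the same spatial model to every preparation, and classifies how consistent
the estimated associations are across zonations.

It is aimed at spatial epidemiologists and biostatisticians who want to
stress-test an areal analysis design before committing to one, or to verify
a MAUP/MTUP sensitivity pipeline against simulated data where the truth is
known.

## The model

Each preparation is a set of zones *i* observed over repeated 12-month
outcome windows *w*. Counts follow a Besag–York–Mollié (BYM) Poisson model:

```
y_iw ~ Poisson(e_iw · θ_iw),    log θ_iw = α + β·x_iw + u_i + v_i
```

* `e_iw` — expected counts by internal indirect standardization
  (`e = pop · Σy/Σpop`, so `Σe = Σy` and θ is a standardized incidence
  ratio);
* `x_iw` — mean daily rainfall (mm) over the zone's exposure window;
* `v_i ~ N(0, σ_v²)` — unstructured zone effect;
* `u_i` — intrinsic CAR (ICAR) spatial effect,
  `u_i | u_-i ~ N(mean of neighbours, σ_u²/n_i)`, identified by a
  sum-to-zero constraint;
* hyperpriors `σ_v² ~ InvGamma(0.001, 0.001)`, `σ_u² ~ InvGamma(0.1, 0.1)`
  (shape/rate, on the variances); vague normal priors on α and β.

Fitting is by Metropolis-within-Gibbs MCMC (conjugate variance updates,
adaptive random-walk updates for everything else; see `docs/methods.md`).
Effects are reported as rate ratios `RR = exp(0.5·β)` per 0.5 mm of mean
daily rainfall, with equal-tailed 95% credible intervals. An arrangement's
estimates across zonations are *consistently positive/negative* when every
interval excludes 1 and all point estimates share a direction, otherwise
*inconsistent*.

## Worked example

Fit the BYM model to one simulated dataset with a known rainfall
coefficient of 0.1 per mm:

```python
import maupmtup as m

truth = m.SimulationTruth(alpha=0.0, beta=0.1, sigma_u2=0.05, sigma_v2=0.05)
df, graph = m.simulate_validation_dataset(truth, seed=11)   # 150 zones x 15 windows
res = m.BYMModel(df, graph).fit(seed=42)
print(res.summary().round(4).to_string(index=False))
rr = res.rate_ratio()
print(f"RR per {rr.scale} mm: {rr.rr:.4f} (95% CrI {rr.ci_low:.4f}-{rr.ci_high:.4f})")
```

```
   param    mean     sd    q2.5     q50   q97.5      ess
   alpha -0.1235 0.0208 -0.1633 -0.1231 -0.0820  73.5291
    beta  0.1072 0.0134  0.0817  0.1069  0.1337 886.8657
sigma_u2  0.1007 0.0332  0.0481  0.0965  0.1721   6.8385
sigma_v2  0.0356 0.0124  0.0145  0.0362  0.0585   6.1033
RR per 0.5 mm: 1.0551 (95% CrI 1.0417-1.0691)
```

The posterior for β (0.107, CrI 0.082–0.134) recovers the simulated truth
of 0.1 per mm; the corresponding rate ratio says each extra 0.5 mm of mean
daily rainfall multiplies the presentation rate by about 1.055. (The two
variance components are weakly identified and mix slowly — their small
effective sample sizes are expected; β is the estimand.)

An end-to-end sensitivity run (simulate → zone → prepare → fit → classify)
from the command line:

```sh
maupmtup run --smoke --out out --seed 4
maupmtup report --manifest out/manifest.json
```

```
preparations run: 8
female: 4 arrangement cells — inconsistent: 4
     August 3mo lag  0: inconsistent           mean RR 0.9933 (n=2)
     August 3mo lag  6: inconsistent           mean RR 1.4946 (n=2)
   February 3mo lag  0: inconsistent           mean RR 1.1394 (n=2)
   February 3mo lag  6: inconsistent           mean RR 0.9862 (n=2)
```

Here the generator's rainfall coefficient is 0 (the smoke default), so every
arrangement is correctly classified inconsistent: each cell averages the
rate ratios of the zonations fitted for that (endpoint, rainfall length,
lag) arrangement, and none of them separates from RR = 1.

The full study-shaped configuration (`m.RunConfig()` defaults) enumerates
6 endpoints × 2 rainfall lengths × 5 lags × 26 zonations × 2 genders =
3120 preparations; `run_pipeline` checkpoints each fit into
`manifest.json` and writes `rate_ratios.csv` and the consistency `grid.csv`.

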