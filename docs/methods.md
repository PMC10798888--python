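# Methods

## Model and assumptions

The package treats methylation drift at an age-related CpG site c in species
m as linear in age over the sampled range, with Gaussian measurement noise
and hard truncation at the beta-value bounds:

    beta_{c,m}(a) = clip( i_c + s_{c,m} · a + ε,  0, 1 ),   ε ~ N(0, σ²).

The *methylation rate* is the OLS slope of beta on age. The scaling
hypothesis is a power law linking rates to maximum lifespan l_m,

    s_{c,m} = b_c · l_m^s,

with a site-specific baseline b_c (the rate of a hypothetical 1-year-lived
mammal) and a shared exponent s. Taking logs of the ratio between two
species cancels b_c:

    log(s_{c,m1} / s_{c,m0}) = s · (log l_m1 − log l_m0),

which is why the estimator never needs absolute rates: sequential pairwise
ratios, chained by cumulative product, telescope into each species' rate
relative to the baseline species, while every individual comparison is made
over (approximately) the same age span in both species. This sidesteps the
two biases of naive cross-species regression — boundary plateaus and
R²-selection against slow sites in short-sampled species — both of which
are functions of the *sampled age range*, not of lifespan itself.

Assumptions worth keeping in mind: drift is linear within the matched
ranges (sites approaching a boundary violate this and are partially removed
by the mean-methylation filter); the set of conserved age-related sites
overlaps between neighbouring species; and a single exponent describes all
sites of a tissue (the direction-stratified experiment probes this).

## Pipeline parameters

| parameter | default | meaning / rationale |
|---|---|---|
| matching tolerance | min(0.02·lifespan_shorter, 1 yr) | maximum allowed gap between matched maximum ages |
| min initial samples | 20 | species with fewer samples are excluded outright |
| min restricted samples | 15 | after pairwise trimming |
| min lifespan coverage | 0.25 | max sampled age (raw scale) / max lifespan |
| mean-methylation bounds | [0.1, 0.9] | excludes boundary-adjacent, plateau-prone sites |
| R² grid | 0:0.2:0.01 | CpG-selection thresholds scanned; grid step not externally prescribed, 0.01 gives 21 values |
| min CpGs per comparison | 10 | a threshold is invalid if any comparison selects fewer |
| KDE | Gaussian, Scott bandwidth, 10,001-point grid over [min−3h, max+3h] | deterministic mode selection over per-threshold exponents |
| DBSCAN | per-species standardized PCs, eps = 1.0, min_samples = 5 | scale-free default usable across species of different sample sizes |

Boundary conventions are inclusive throughout (age exactly at sexual
maturity is retained; R² exactly at the threshold passes; mean methylation
exactly 0.1/0.9 passes). Ties in species ordering break lexicographically;
ties in nearest-age matching break toward the smaller age. Medians over an
even number of ratios use the midpoint. When a species fails matching or
the inclusion filters mid-chain it is dropped and the next species is
compared with the last retained one; this preserves the telescoping
identity exactly, at the cost of a slightly wider single comparison. The
final log-log regression uses the trait-table maximum lifespan as x, the
baseline contributing (log10 l_0, 0); its 95% CI comes from the t
distribution with n−2 df. The reported headline estimate is the KDE density
mode; the accompanying fit/series are taken from the valid grid threshold
whose exponent lies closest to the mode.

## Synthetic-data generator

The generator emulates the statistical structure the analysis relies on:
many species with lifespans spread over orders of magnitude (default
log-uniform over 3–120 years), per-CpG linear drift with a shared
site-specific baseline and sign across species, Gaussian noise, and
clipping to [0, 1] that produces plateaus in long-sampled species. Defaults:

* intercepts ~ N(0.5, 0.15) per CpG, shared across species (mid-range
  starting methylation);
* baseline slope magnitudes |N(0.2, 0.1)| per year at reference lifespan 1.
  This scale is calibrated to observed mammalian rates under an exponent
  near −1: it yields ≈ 0.05/yr in a 4-year-lived mouse and ≈ 0.002/yr in
  humans, matching the order of magnitude of well-known age-related sites.
  A much smaller baseline would leave the age signal below the measurement
  noise at realistic sampling, i.e. no genuinely age-related sites at all;
* sign per CpG: hypermethylating with probability 0.5, consistent across
  species (the selection step requires shared directionality);
* noise σ = 0.03 per measurement; ages uniform over the sampled fraction
  (default 0.5) of each lifespan; 40 species × 500 CpGs × 30 samples.

Randomness: one global integer seed; per-species substreams are derived
from (seed, species index), so adding a species never perturbs existing
panels. Identical specs give bit-identical panels.

The *empirical null* draws each (slope, intercept) pair with replacement
from the pool of fitted values across all species of a reference scenario,
independently of lifespan, and reuses the reference sample ages verbatim.
The method-null experiment runs it at the methylation array's probe scale
(36,000 CpGs) rather than the 500-CpG recovery scale: the null's residual
dispersion is a random walk of per-comparison median log-ratios whose step
size shrinks as 1/sqrt(selected CpGs), so flatness of the null is a
property of array-scale medians; at a few hundred CpGs the same experiment
is dominated by median noise rather than by any bias of the method.

What the generator does **not** emulate: probe failure and batch effects,
genuinely non-linear (logistic) trajectories beyond hard clipping, uneven
or sparse age distributions, cross-species probe divergence, and
phylogenetic correlation between species. Passing tests therefore
demonstrate the estimator's correctness and bias-robustness under the
stated generative model, not the quality of any particular real dataset.

## Numerical choices and degenerate inputs

Per-CpG regressions use the closed-form covariance/variance OLS,
vectorized with NaN-aware masking; sites need ≥ 3 non-missing samples and
non-constant ages, otherwise they are marked invalid and never selected.
Constant betas get slope 0 and R² 0 (and cannot be selected, since sign 0
fails the shared-direction test — this also makes division by a zero slope
impossible). Beta values outside [0, 1] by ≤ 1e-9 are clipped at load time;
larger violations are treated as corrupt input. All delimited-text I/O
round-trips floats exactly (`repr` on write, round-trip parsing on read).
PCA uses mean-centred, unscaled betas over shared CpGs with CpG-mean
imputation *only* for the embedding; component signs are fixed by making
the largest-magnitude loading positive.

## Expected behaviour on synthetic data

On noise-free, clip-free power-law panels the cumulative ratios equal
(l_i/l_0)^s to numerical precision and every grid threshold yields the true
exponent. With realistic noise and clipping the estimate carries a small
attenuation toward 0 (typically ≤ 0.1 at the default study scale): faster
sites and faster species lose more signal to the boundary, and conditioning
selection on the weaker-signal species passing the R² threshold slightly
inflates its fitted slopes. This residual plateau bias is inherent to
linear fits in a bounded space; the mean-methylation filter mitigates but
cannot eliminate it, and a plateau-aware trajectory model would be the
natural extension. The bias grows with the lifespan gap between neighbours,
so chains over few, widely spaced species are noticeably more attenuated
than densely sampled chains.

## Known limitations

* Sequential neighbour comparisons only; no all-vs-all pooling, no
  mixed-tissue chains, no phylogenetically independent contrasts.
* The log-log fit ignores uncertainty in the cumulative ratios
  (errors-in-variables) and the serial correlation the cumulative product
  induces between points.
* Chain repair after a species dropout widens one comparison's lifespan
  gap; with very sparse species sets the chain can truncate.
* Lifespan and maturity-age trait values are taken as exact.
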