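# Methods

## Model

`legumorph` treats potential vegetative shoot morphogenesis of herbaceous
legumes as a deterministic process in thermal time.  The assumptions are those
of isolated, unstressed plants during the vegetative phase: constant
phyllochrons per axis category, a constant sylleptic branching delay, organ
expansion kinetics that are invariant across phytomer positions once time is
expressed in phyllochrons of the bearing axis, and a single leaf-area
allometry.  None of these rules carries stochasticity; all randomness in the
package lives in the measurement-noise model of the synthetic generator.

### Thermal time

Temperature records (strictly increasing timestamps, °C) are converted to
degree-days with a beta response `f(T)` between cardinal temperatures
`t_min`/`t_max` with shape `q`, scaled by `(t_ref − t_base)` where
`t_ref = 20 °C`, `t_base = 5 °C`.  Integration is trapezoidal on the recorded
timestamps (greenhouse loggers typically store 15-min means, for which the
quadrature error is far below 0.1 %); the rate is interpolated linearly at
window edges so accumulation is exactly additive over adjacent windows.  Days
are 86 400 s; timestamps carry no timezone semantics.  Per-species cardinal
temperatures are placeholders (`t_min = 0`, `t_max = 40`, `q = 1.5`) and
overridable in every config; all packaged analyses either specify thermal
time directly or use constant-temperature traces for which the placeholders
cancel.

### Forward simulation

Every event is computed in closed form because the rules are linear in
thermal time: phytomer `k` of an axis appears at `tt_start + k·phyllochron`;
primary axes spawn from the collar at `(collar_lag + i·br1)` main-axis
phyllochrons (the collar lag defaults to `br1`; the trait set defines the
spawn *interval*, not the first-emission time, which is why the lag is a
separate, configurable parameter); the axillary bud of every main/primary
phytomer bursts `ram_dist` bearer phyllochrons after the phytomer appears and
becomes a secondary axis.  Secondary axes do not branch further — tertiary
branching is not part of the characterized framework — though the budburst
times are still recorded so the restriction can be lifted later.  A reporting
TT grid only chooses snapshot times; refining it cannot change the
architecture.  Guards (`n_axes_max`, `max_phytomers_per_axis`) abort runaway
simulations with a diagnostic rather than silently truncating.

Axis phyllochrons derive from the main-axis phyllochron `phy0` and the
relative development rates `phy1`, `phy2` (phytomer·phytomer⁻¹, the units the
trait table uses): a primary axis has phyllochron `phy0/phy1`, a secondary
axis `phy0/phy2`.  Values of `phy1` above 1 therefore mean primary axes
develop faster than the main axis (white and red clover), values below 1
slower (sainfoin, kura clover).

Each phytomer instantiates its organs at appearance with steepness
`s = 2·ln(19)/d95` and the configured `t50` offsets.  The leaflet convention
`t50 = 0` means a leaf is half-expanded when it is scored as appeared, so
organs legitimately carry non-zero size at `τ = 0`.  Instantaneous leaf area
is final area × (relative leaflet length)², since area is a length × width
product and both follow the leaflet kinetic.  Plant height sums current
internode lengths along the main axis.  Ranks are 1-based from the axis base
throughout; apex-based positions are a view computed at analysis time only.

### Species configurations

Six YAML configurations are packaged.  Printed anchors: phyllochrons 32.6
(birdsfoot trefoil) and 64.2 °Cd (kura clover) with the between-species
ordering BT–A < SF < WC < RC < KC; branching delays from 2 (alfalfa) to 8
(kura clover) phyllochrons; whole-phytomer expansion spans of 5 phyllochrons
(alfalfa, birdsfoot trefoil) versus 2.5 (white clover); the internode-first
coordination of white clover encoded as `t50_in = −0.25`; organ maxima from
the published measurement tables (petiole/internode lengths in cm, leaf area
in cm²); sainfoin's leaflet count rising to 25.  Everything else — the
intermediate species' phyllochrons, `br1`, the rate ratios, the rank-profile
parameters, cardinal temperatures — is interpolated to respect those
orderings, flagged `interpolated` in the files, and overridable.  The
sainfoin leaflet rule is linear in rank from 5 to the cap, rounded to the
nearest odd count.  Stipules are simulated only for birdsfoot trefoil, with
leaflet-like kinetics by default.

## Trait estimation

* **Phyllochron**: OLS of decimal phytomer count on TT, using only censuses
  with ≥ 3 unfolded leaves; the phyllochron is the reciprocal slope and the
  regression's x-intercept dates the axis start.  At least two usable
  censuses at distinct TT are required; non-positive slopes are rejected as
  degenerate.
* **br1 / phy1**: per primary axis, the same regression gives its phyllochron
  and start time; `phy1` is the mean ratio of main to primary phyllochron and
  `br1` the mean gap between consecutive start times in main phyllochrons
  (needs ≥ 2 fitted primary axes).
* **ram_dist**: mean over main-axis phytomers of
  `(burst TT − appearance TT)/phyllochron`, with appearance from the census
  regression.
* **Organ kinetics**: series from replicate phytomers (ranks 5–7, 11–13 main;
  3–5 primary) are pooled per organ type through a joint nonlinear
  least-squares fit sharing `(s, t50)` with one `l_max` per series.  Sharing
  the kinetics across replicates is the pooling the framework justifies
  (kinetics are position-invariant); estimating per-series maxima avoids the
  bias of normalizing by an observed maximum the logistic never attains.
  `t50` offsets are reported relative to the fitted leaflet `t50`; `d95`
  always equals `2·ln(19)/s`.  Initialization: `l_max ← 1.05 × max`, `t50`
  from the half-maximum crossing by linear interpolation, `s` from the
  25–75 % crossings; three deterministic multi-start perturbations before a
  fit is flagged failed (the pipeline continues with the flag set).  The
  single-series fitter also offers a constrained mode fixing `l_max` at an
  observed final length; free estimation is the default.
* **Growth cessation**: series are truncated after four consecutive
  unchanged readings, mirroring the measurement stopping rule; continuous
  synthetic series pass through unchanged.
* **Branching probability**: per position, the fraction of plants whose bud
  has burst by a date, with a three-parameter logistic over position
  (asymptote bounded at 1); all-zero profiles are flagged flat.
* **Allometry**: regression through the origin of scanned leaf area on
  length × width × leaflet count.
* **Trait matrix and PCA**: individuals missing more than half the traits
  are excluded with a warning; remaining gaps are imputed by species mean and
  flagged.  PCA is on the correlation matrix (columns standardized) because
  the traits mix °Cd, phyllochrons, cm and cm²; zero-variance columns are
  dropped with a warning, and component signs are fixed so each component's
  largest-magnitude loading is positive.

## Synthetic data

The generator samples the simulated plant the way the study protocol measured
real ones: weekly decimal censuses of every axis, daily organ lengths on the
monitored ranks, end-of-experiment leaf scans of mature main-axis leaves, and
budburst records.  Noise is additive Gaussian on observations only —
`length_sd` and `area_sd` as fractions of the final dimension, `stage_sd` in
phytomers with noisy censuses floored at the previous value to preserve
monotonicity.  Defaults (5 % length, 0.2 phytomers, 5 % area) are stated
assumptions; real error magnitudes were not published.  One seed fully
determines a dataset, and the ground-truth trait record is emitted with the
same schema as the trait matrix.

Two deliberate idealizations: replicate plants share one architecture
(potential development is deterministic, so only their measurement noise
differs), and the branching table records exact budburst TTs rather than
weekly burst statuses — weekly bracketing would quantize the recovered delay
to about half a census interval, whereas burst timing is in reality fitted
from its linear relation to thermal time.  Consequently, passing round-trip
tests demonstrate the estimators are consistent with the generative rules and
robust to measurement noise; they do not validate the framework against real
plants, nor cover stress responses, competition, senescence, reproductive
transition or year effects, which are out of scope.  Under multiplicative
scan noise the `max_lf` estimator (a maximum statistic) is biased upward by a
few percent; the noiseless estimate is exact.

## Problem sizes and numerical choices

Round-trip analyses use one virtual plant over 80 days at constant 20 °C
(1 200 °Cd, enough for all monitored ranks of every packaged species to
complete expansion); kinetics-only studies use 40 days.  The noisy
leaf-appearance study uses 100 replicates per species at `stage_sd = 0.3`
phytomers; the d95-recovery study 50 replicates at 5 % length noise.
Logistic fits use `scipy.optimize` least squares with tight tolerances
(`xtol = ftol = 1e-14` for the joint fit) so noiseless fits reach machine
precision.  CSV output keeps pandas' shortest round-trip float formatting and
is re-read with `float_precision="round_trip"`, making write → read → write
byte-identical.  Degenerate inputs (flat series, all-zero profiles, empty
tables) raise typed errors rather than returning NaN.
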