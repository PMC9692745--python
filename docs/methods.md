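# Methods

## The physical model

A conductive pore across a planar bilayer is treated as an equivalent
cylinder of radius *r* spanning the hydrophobic thickness *h* and filled
with electrolyte of the bulk specific conductivity *g*, giving
G = π·g·r²/h and r = √(G·h/(π·g)). This is an *effective* geometry: real
nanoparticle- or peptide-induced defects need not be cylindrical, and the
package makes no claim about pore shape beyond the effective area the
conductance implies. The pore conductance entering the formula is the
level conductance minus the intact-membrane baseline; with typical
baselines of 5–17 pS against pore levels of 10²–10³ pS this changes radii
by < 0.03 nm, below any realistic uncertainty, but it is the physically
correct quantity (the leak of the intact bilayer is not part of the pore).

Radius uncertainties are first-order propagated from the level SD,
δr = (r/2)·(δG/G). No attempt is made to reproduce any particular
reporting convention for uncertainties; the propagation rule is stated
and applied uniformly.

Metastable states are linked to dwell times by a Kramers-type attempt
relation τᵢ = (1/ν·Vᵢ)·exp((E_max − Eᵢ)/kT), where Vᵢ ≈ 2π·rᵢ²·h is the
membrane volume whose lipid fluctuations can drive a transition and ν is
the attempt-rate density. Energies are carried in kT units at the bath
temperature (294.15 K default); conversion to joules is a presentation
utility only. Two consequences structure the API:

- **Energy differences** depend only on dwell-time and volume *ratios*:
  E_b − E_a = ln(τ_a·r_a²/(τ_b·r_b²)). They are antisymmetric and
  independent of ν, hence comparatively robust.
- **Barrier heights** E_max − Eᵢ = ln(τᵢ·ν·Vᵢ) inherit the ~10-order
  uncertainty of ν; `barrier_interval` therefore evaluates both ends of
  the literature span (5×10³² and 2×10⁴² s⁻¹m⁻³) and reports an interval,
  never a point estimate.

## The simulator and what it does (not) emulate

Gating is a continuous-time Markov chain over pore states. Escape rates
along an edge follow the same attempt relation,
k = ν·Vᵢ·exp(−(E_max − Eᵢ)), making simulation and analysis two views of
one model; parameter recovery is therefore a meaningful closed loop. The
closed (intact) state has no observable fluctuation volume, so opening
rates are direct model parameters rather than derived from a fictitious
pre-pore volume — openings are rare events whose rate is an empirical
quantity. Default transition graphs are chains between adjacent
conductance levels; arbitrary extra edges can be added.

Rendering mimics the reference acquisition: conductance → current at the
holding voltage (25 mV), a single-pole low-pass with the amplifier
integration constant τ = 20 ms discretised as y[n] = y[n−1] +
α(x[n] − y[n−1]) with α = 1 − exp(−Δt/τ) (exact for piecewise-constant
inputs, DC gain exactly 1; a step reaches 1 − e⁻³ ≈ 95.0 % of its
amplitude at 3τ), 1 kHz sampling, additive Gaussian noise (default 2 pS,
matching observed quiet-level SDs of 2–13 pS) and optional 16-bit ADC
quantisation over a ±2 nA span. Noise is injected *after* the filter, on
the assumption that amplifier output noise dominates; where that
assumption fails the noise spectrum of real recordings will differ from
the synthetic one. Features deliberately not emulated: baseline drift
between additions, addition-artefact transients, 50 Hz pickup,
open-channel excess noise, membrane rupture, and high-variance "flicker"
episodes in which two levels alternate faster than the filter can
resolve. Passing tests on synthetic data therefore demonstrate
correctness of the algorithms under the stated recording model, not
robustness to every artefact of real recordings.

The dose–response generator draws per-membrane conductances
mean-preservingly log-normal around an effect curve (pore count × unit
conductance per added volume). The log-SD default of ~1.3 reproduces the
order-of-magnitude membrane-to-membrane scatter that rare, discrete pore
formation produces at fixed observation time. Added volume maps to
concentration as c = v·c_stock/V_chamber (1 mg/mL stock, 2.5 mL chamber),
ignoring the added volume's own dilution — the convention used in the
dose–response reporting this mirrors.

## Change-point detection

The detector must find both dense level hopping *and* a handful of
brief closures inside stretches of tens of minutes at one level. A global
least-squares search (plain binary segmentation) fails on the latter: a
4 s excursion in a 600 s trace barely moves whole-trace means, so the
top-level split is rejected and recursion never reaches the event. The
package instead uses a local two-stage scheme:

1. **Detection.** A moving two-window jump statistic (MOSUM),
   d[n] = mean(g[n:n+w]) − mean(g[n−w:n]), computed on the filtered
   series via cumulative sums and rescaled by the known attenuation
   κ(w) = 1 − (τf_s/w)(1 − e^(−w/τf_s)) that a filtered step suffers over a
   w-sample window. Local peaks of |d| with height ≥ max(min_step,
   nσ·σ̂), minimum separation w and prominence ≥ half the threshold are
   candidates. Defaults: w = 40 ms, min_step = 20 pS (below the smallest
   step one would interpret as a pore-size change), nσ = 5, with σ̂ the
   scaled median absolute first difference. At these settings the
   statistic's noise is ≈ 0.4 σ, so the 5σ threshold sits far above the
   expected extremes of minute-long pure-noise traces (no false
   positives), while any step ≥ the threshold with ≥ w-sample dwells on
   both sides produces a peak.
2. **Localisation.** Around each candidate the discrete single-pole
   filter is inverted exactly, x[n] = (y[n] − (1−α)y[n−1])/α, restoring
   the underlying step signal with transitions at their true sample
   positions, and the breakpoint is placed by an exact single-split
   least-squares search on the restored window. On noiseless filtered
   steps this lands on the true transition sample for any amplitude, so
   no heuristic delay correction (e.g. shifting breakpoints back by some
   fixed fraction of τ) is needed. Restoration amplifies post-filter
   noise ~20-fold per sample, which is why it is used only for
   localisation over short windows, never for detection or SD estimates.

Consequences and limits: dwells shorter than about the detection window
(40 ms default) are unresolvable and silently merge into their
neighbours; this biases individual dwell-time means upward, but the bias
largely cancels in the dwell-ratio energy estimator (both states are
censored the same way), as the end-to-end recovery test demonstrates.
Breakpoints within one window of the series edges may be missed. For
unfiltered series (`filter_tau_s=None`) the same machinery runs with
κ = 1 and no restoration; on short series with well-separated steps it
matches an exhaustive least-squares segmentation oracle.

Segment means are computed on the restored signal (unbiased across the
settling ramp); segment SDs on the filtered signal with the first 3τ
excluded, so they reflect within-level noise rather than transients.

## Events, levels, kinetics

Events shorter than 3τ = 60 ms are *flagged*, never deleted: against a
20 ms integration constant such pulses cannot be confidently attributed
to a new metastable state. Flagged events are excluded from level
construction and kinetics by default but remain in the event table for
audit; an event of exactly 60 ms is kept unflagged (boundary convention).

Levels are built by sorting unflagged segment means and splitting where
adjacent means differ by more than a merge tolerance (default 20 pS);
each cluster's mean is occupancy-weighted and levels are numbered
ascending from the baseline (= lowest level = 1). Pore occupancy per
level is the integer n minimising |mean − baseline − n·G_unit|, flagged
ambiguous when the residual exceeds a tolerance (default G_unit/4).

Baseline estimation uses median and scaled MAD over a designated control
window, with a warning if the window itself contains a detectable step.
Baseline drift between additions is not modelled; the baseline is treated
as constant per analysed stretch and the control window is the user's
statement of where that holds.

A kinetic *visit* is a maximal run of consecutive same-level segments
after flagged segments are dropped, so a spurious split or an
unresolvable interruption does not fragment a dwell. The first and last
visits of a record are censored (true durations unknown) and excluded
from dwell means by default; with the small visit counts typical of rare
events this is the conservative choice. Opening frequency counts
baseline → pore-level transitions per minute; the closed fraction is the
percentage of the observation window spent at baseline, with the window
opening by default at the first pore appearance. The sign test is the
exact binomial test on the signs of paired differences, one-sided by
default because coating comparisons are directional claims; the pairing
unit and sidedness are explicit arguments, not baked in.

## Numerical and design choices

- Seeds: every stochastic component takes an explicit seed;
  (model, duration, seed) fully determines a simulated trace, and the
  pipeline report is deterministic given (config, seed).
- Degenerate inputs fail loudly (zero chamber volume, zero holding
  voltage, empty baseline window, overlapping event rows, non-uniform
  time axes, unknown config keys) rather than being repaired.
- Sub-sample dwells in rendering emit a warning — they are invisible at
  the sampling rate but intentionally allowed, since the gating model can
  legitimately produce them.
- On-disk formats are plain text (CSV/TSV + YAML sidecar) with full
  float precision (`%.17g`) and round-trip-exact parsing; vendor
  acquisition formats are an out-of-scope adapter point.
- Test and example problem sizes (traces of 1–25 minutes at 1 kHz,
  ~100–200 visits per state) are chosen so every check runs in seconds
  on one CPU while CLT-based acceptance bands remain tight; they are the
  package's own study conditions, stated here once.

## Known limitations

- The analysis cannot distinguish "the same pore reopened" from "a new
  pore of similar size opened"; the simulator treats states as belonging
  to one pore, and occupancy inference reports counts of *simultaneously
  open* unit pores only. This identifiability limit is inherent to
  conductance-only recordings.
- Dwell-time estimates from a handful of visits carry large errors; the
  package reports SEs but does not model multi-exponential dwell
  mixtures or survival censoring beyond dropping edge visits.
- No hidden-Markov joint idealisation/kinetic fitting: the analysis is
  deliberately level-based, mirroring how multilevel traces are read in
  practice; an HMM layer would be a natural extension.
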