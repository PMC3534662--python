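# Methods

## The readout model

The tempotron is a leaky integrate-and-fire neuron driven by a fixed set of
afferents. Each input spike at time $t_{ij}$ (spike $j$ of afferent $i$)
contributes a postsynaptic potential $\omega_i R_{ij} K(t - t_{ij})$ with
the double-exponential kernel

$$K(t) = V_0 \left(e^{-t/\tau_m} - e^{-t/\tau_s}\right),\quad t > 0,$$

normalized so $\max_t K(t) = 1$; the analytic time-to-peak is
$t^\* = \frac{\tau_m \tau_s}{\tau_m - \tau_s}\ln(\tau_m/\tau_s)$ (4.621 ms at
the defaults). Defaults are $\tau_m = 10$ ms and $\tau_s = \tau_m/4$; the
fixed ratio keeps a biologically plausible PSP shape as $\tau_m$ is swept.
The classification readout is binary: the neuron fires (at least one output
spike, $V \ge \theta$ with $\theta = 1$) for target patterns and stays
silent for null patterns. No post-spike reset is modeled — all analyses use
only the peak voltage and the first threshold crossing.

**Exact peak finding.** Between consecutive input spikes the voltage is
$A e^{-t/\tau_m} - B e^{-t/\tau_s}$; the interior extremum of each interval
has a closed form, so the global maximum (and, by bisection within the
crossing interval, the first threshold-crossing time) is computed exactly
rather than on a time grid. The test suite pins this event-driven path
against an independent dense-grid maximization (0.01 ms grid plus local
refinement) to $10^{-6}$.

**Learning.** The rule is error-driven. After a miss on a target,
$\Delta\omega_i = +\lambda \sum_{t_{ij} < t_\mathrm{max}} R_{ij}
K(t_\mathrm{max} - t_{ij})$, where $t_\mathrm{max}$ is the time of the
voltage maximum; after a false alarm the sign flips. A momentum term
($v \leftarrow \mu v + \Delta\omega$, $\omega \leftarrow \omega + v$,
default $\mu = 0.9$; $0.99$ in the orientation experiment) accelerates
convergence. $\lambda$ is the maximal weight change per input spike;
defaults of order $10^{-3}$ suit unit-threshold problems with tens of
afferents.

A known fixed point: if every weight is initialized negative, the voltage
never becomes positive, the argmax is undefined and the rule prescribes no
update. The training protocol therefore runs several independently seeded
initializations per hyperparameter setting and keeps the best run — which
is also the standard protocol here for performance measurement.

**Short-term depression.** Successive PSPs from one afferent are attenuated
by resource depletion: each spike consumes a fraction $U$ of resources,
which recover exponentially with $\tau_D$,

$$R_1 = 1,\qquad R_{j+1} = 1 - \bigl(1 - (1-U)R_j\bigr)
e^{-(t_{j+1}-t_j)/\tau_D}.$$

This depression-only form reproduces the relevant limits: $U=1$ with slow
recovery silences everything after the first spike
($R_2 = 1 - e^{-\mathrm{ISI}/\tau_D}$), instant recovery restores static
synapses, and disabling depression makes the learning update identical to
the static rule. The learning gradient simply carries the $R_{ij}$ factors.

## Training protocol

Each learning run cycles through all labelled trials in a seeded random
order fixed across cycles, for 2000 cycles by default. The per-cycle
misclassification fraction is smoothed by a centered 50-cycle moving
average; the run's performance is the minimum of the smoothed curve and the
returned model is the weight snapshot at that cycle (earliest on ties).
Task-level performance is the best over multiple runs per
$(\lambda, \text{init sd})$ grid point, averaged over all realizations of a
task. Cross-validation uses a stratified 75/25 split and an optional
training margin (target correct only above $\theta(1+m)$, null only below
$\theta(1-m)$, $m$ chosen on the training split from
$\{0, 0.025, 0.05, 0.1, 0.15, 0.2\}$, test evaluation at $m=0$). The margin
is a multiplicative band around the threshold — equivalent, by the scale
invariance of the classifier, to the usual additive margin in threshold
units.

## Tasks

Eight grating phases are quarter-bar-width shifts of one square-wave
grating; phase $i$ and $i+4$ are polarity inverses. The luminance task
(bright vs dark at a location) pits an adjacent pair $\{i, i+1\}$ against
its inverse pair $\{i+4, i+5\}$ — 8 realizations counting role swaps. The
boundary task (edge present regardless of polarity) pits a polarity pair
$\{i, i+4\}$ against the quarter-period-shifted pair $\{i+2, i+6\}$ — 4
realizations. This counting convention (role swaps distinct, cyclic
duplicates not) is the unique one producing 8 and 4.

## Benchmark decoders

The spike-count perceptron thresholds $\sum_i w_i c_i + b$ on counts within
a window (presets 150 ms and 80 ms); the bias is trained. The temporal
winner-take-all assigns each afferent a binary label and decides by the
earliest spike (k=1) or the majority of the three earliest (k=3); it is fit
by exhaustive enumeration of all $2^N$ labelings ($N \le 25$), and a trial
without spikes votes null. The rank-order decoder computes
$\sum_i \omega_i m^{r_i}$ where $r_i$ is the rank of afferent $i$'s first
spike among the afferents that fired (ties broken by index; silent
afferents simply don't contribute — ranks are not renormalized); weights
are set to each afferent's average attenuation factor over target patterns,
and $m$ and the threshold are grid-searched ($m \in \{0.5 \ldots 0.99\}$,
threshold over 100 quantiles of the training potentials).

## Two-afferent analytics

With one spike per afferent the only stimulus variable is
$\Delta t = t_2 - t_1$. $V_{\max}(\Delta t)$ equals $w_1 + w_2$ at
synchrony and $\max(w_1, w_2)$ at large separation, so a threshold between
those values dissects the $\Delta t$ axis into three parts (fire inside the
interval for two excitatory weights, outside for mixed signs). The forward
problem is solved by bracketing + Brent root refinement ($10^{-6}$ ms); the
inverse problem exploits the linearity of $V_{\max}$ under common weight
scaling, collapsing the 2-D system to a 1-D root search in the weight ratio
over three sign families (both excitatory; inhibitory second; inhibitory
first), followed by rescaling to the threshold. Requests infeasible under
the current kernel are reported as such; the mixed-regime boundary can
never exceed the kernel's time-to-peak (inhibition landing after the
excitatory peak vetoes nothing), and approaches it at rate
$O(\sqrt{\epsilon})$ as the excitatory weight approaches threshold, because
the kernel is quadratically flat at its peak.

Threshold-noise robustness assumes a per-stimulus Gaussian over $\Delta t$
and Gaussian threshold noise with sd equal to 5% of the mean weight
magnitude by default; the expected error integrates the Gaussian firing
probability over $\pm 5$ sd of each stimulus by trapezoidal quadrature.
Empirical pair analyses score every trial, counting spike failures (a
single remaining PSP peaks exactly at its weight; a fully silent trial
never fires).

## Tuning characterization

Cosine tuning $f(\varphi) = b + a\cos(\varphi - \varphi_0)$ is fitted by
the exact linearization $b + \alpha\cos\varphi + \beta\sin\varphi$ (the
same model class, convex least squares), with
$a = \sqrt{\alpha^2+\beta^2}$, $\varphi_0 = \mathrm{atan2}(\beta, \alpha)$.
$r^2$ on single trials is not clipped below zero. A second statistic scores
the same fit against per-phase *mean* responses, separating trial-to-trial
noise from model misfit. Latency correlations are Pearson $r$ within each
stimulus condition over trials where both cells fired; the trial-shift
control rotates one cell's trial order by one within each condition,
destroying the shared jitter component while preserving the marginals.

## Synthetic retina

The generator is the stand-in for recorded fast-Off RGC populations, and
its defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| latency baseline $b$ | $\mathcal{N}(80, 10)$ ms | per-cell tuning-curve offset |
| latency amplitude $a$ | $\mathcal{N}(25, 5)$ ms, $b > a > 0$ | modulation depth |
| preferred phase $\varphi_0$ | uniform $[0°, 360°)$ | population covers all phases |
| count tuning | antiphase ($\varphi_0 + 180°$) | fast responses are strong responses |
| shared / private jitter sd | 2 / 2 ms | pairwise latency correlation $\rho = \sigma_{sh}^2 / (\sigma_{sh}^2 + \sigma_{pr}^2) = 0.5$ |
| contrast shift $\Delta b(c)$ | config per level | additive, common to all cells |
| burst ISI | 8 ms | spikes after the first, inside 150 ms |
| failure rate | 0 at full contrast, configurable per level | whole-trial silence |

First-spike latency on a trial is
$b + \Delta b(\mathrm{contrast}) + a\cos(\varphi - \varphi_0) +
\eta_\mathrm{shared} + \eta_\mathrm{private}$, with the shared draw common
to all cells of the trial. What this emulates — and what it does not: real
fast-Off populations have correlated count noise, non-cosine harmonics,
and stimulus-dependent jitter; none of these are modeled, so passing tests
establish the decoding machinery's behaviour under the assumed statistical
structure, not performance on any specific recording.

For continuous gratings (orientation experiment) each cell has an isotropic
Gaussian receptive field (sd 0.12 grating periods, centers uniform in a
disc of radius 1.5 periods; 200 cells). The dark-covered fraction $D$ of
the field is computed by projecting the Gaussian onto the grating's
modulation axis and summing the 1-D Gaussian measure of the dark
half-periods (truncation tail $< 10^{-12}$); orientation is treated as a
direction modulo 180° — a grating has no arrow — which makes $D$ exactly
invariant under $\psi \to \psi + 180°$. The latency law is
$b + a\cos(\pi D)$: monotone from bright-slow ($D=0$, $b+a$) to dark-fast
($D=1$, $b-a$), the simplest cosine-in-coverage law consistent with
smooth periodic phase tuning. It is exposed as a pluggable function.

The 7-cell hexagonal schematic enumerates all $2^7$ binary dark/bright
stimuli; each cell fires once, early (20 ms) if dark, late (+30 ms) if
bright. The preferred pattern and its polarity inverse are the 2 targets;
126 remain as nulls.

## Orientation experiment

The full stimulus grid is 201 phases × 101 orientations (20301 stimuli);
targets are all stimuli with $|\psi|$ within 15° (narrow) or 30° (wide).
Training uses a ±10%-of-threshold margin except within 3° (narrow) or 6°
(wide) of the band edge, initial weights $\mathcal{N}(0, 0.001)$, momentum
0.99, up to 10,000 cycles in a random but fixed order, and the step-size
schedule $\lambda_n = \lambda_0 / (1 + n/n_0)$ with $\lambda_0 = 3\times
10^{-4}$ and $n_0 = 2\times 10^5$ presentations — a standard
Robbins–Monro-style decay. Convergence (zero margin-free error on the full
grid) is checked every 50 cycles, and training stops early once reached.
The inner loops are compiled (numba) for the one-spike-per-afferent
patterns of this workload and asserted equal to the reference event-driven
path.

A reduced 41 × 21 grid is a first-class preset; routine testing and the
acceptance script run convergence statistics there (5 seeded runs per band
width, majority required), which keeps the whole experiment under a minute
per run. The full-size grid with 20 runs per band width is supported by the
same entry points and is an overnight-scale job.

## Problem sizes and numerical choices

* Protocol tests and the acceptance script use 8-cell populations, 15
  trials per phase, 300 training cycles, 1–2 runs per grid point; these
  sizes keep each decoder comparison within seconds while leaving the
  qualitative decoder hierarchy stable across seeds.
* Root finding: Brent's method, `xtol` $10^{-6}$ ms (boundaries),
  $10^{-12}$ (weight-ratio search); threshold crossings by 80-step
  bisection.
* Ties: equal smoothed-error minima resolve to the earliest cycle; equal
  latencies resolve to the lower afferent index; the winner-take-all
  enumeration keeps the first-found optimum in lexicographic order.
* Degenerate inputs: empty spike trains are legal everywhere (the
  tempotron sees $V_{\max} = 0$; winner-take-all votes null; rank-order
  ranks only firing afferents); constant tuning responses yield a flagged
  amplitude-zero fit with $\varphi_0$ reported as 0.

## Known limitations

* The spike-count perceptron's near-chance boundary-task error depends on
  count tuning being informative yet polarity-symmetric; with very small
  count amplitudes it would fail for lack of signal instead — a different
  mechanism with the same error rate.
* The depression recursion models depletion only; facilitation is out of
  scope.
* The two-afferent analytics assume exactly one spike per afferent and
  Gaussian latency noise.
* The all-inhibitory-initialization fixed point of the learning rule is
  handled by multiple runs, not by modifying the rule.
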