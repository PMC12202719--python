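# Methods

## Signal model

Each readout line `l` of coil `c` records

```
x_c(l, tau) = s_c(l, tau) + A_c(t_l) e^{i(phi(t_l) + 2*pi*f(t_l)*tau + phi_c)} + n_c(l, tau)
```

where `s_c` is the desired image signal along the spiral trajectory
(zero on sniffer coils and in noise-only scans), and the pilot-tone
carrier has per-coil amplitude

```
A_c(t) = V * a0_c * (1 + m_resp_c * r(t) + m_card_c * card(t) + eddy * g(theta_l))
```

with `V` the transmit-amplitude analog of the generator voltage
setting, `r(t)` and `card(t)` unitless respiratory and cardiac
waveforms, and `g(theta)` a zero-mean band-limited function of the
spiral arm angle standing in for trajectory-locked (eddy-current-like)
amplitude deviations. The physiological modulation evolves
continuously (linearly interpolated within each readout); the carrier
frequency `f(t)` drifts slowly because the generator is free-running
relative to the receiver clock, and the carrier phase — the integral
of the instantaneous frequency — is coherent but never used: only
amplitude modulations carry motion information.

Assumptions that the method relies on: the carrier sits outside the
image-signal bandwidth; sniffer coils receive the carrier (strongly)
but negligible anatomy; motion modulation is slow compared with a
readout; interference coupling is linear and approximately constant
over a few hundred milliseconds.

## Processing chain

1. **Carrier estimation.** Per line, the coil-summed magnitude
   spectrum of the Hann-tapered readout (zero-padded 8×) is
   peak-searched within ±50 kHz of the nominal offset and refined to
   sub-bin precision by quadratic interpolation of the log-magnitude;
   per-coil amplitude is the magnitude of the tapered projection onto
   the refined exponential, normalised by the taper sum. The taper
   matters: the image signal occupies the low-frequency part of each
   readout and a rectangular projection folds its angle-dependent
   leakage into the navigator as broadband common-mode noise. Lines
   whose in-band peak is below `snr_floor` (default 5) times the
   median in-band level are flagged lost and linearly interpolated so
   uniform TR sampling holds downstream.
2. **Angular detrend.** Samples are stably sorted by arm angle (ties
   by time); a Fourier mask along the sorted axis removes angular
   harmonics 1..8 (the trajectory-locked component) while golden-angle
   reordering leaves physiological motion broadband and essentially
   untouched; order 0 is preserved and `max_harmonic = 0` disables the
   stage entirely.
3. **Savitzky–Golay smoothing**, window 21 samples (~112 ms at TR
   5.32 ms), polynomial order 3 — short enough not to blunt the
   cardiac upstroke relative to the 0.375-s refractory window.
4. **Band splitting.** A raised-cosine mask (transition 20% of each
   edge, DC removed) applied to the Fourier transform of the whole
   record — retrospective and zero-phase by construction. The record
   is mirror-extended first: the respiratory modulation is an order of
   magnitude stronger than the cardiac one, and the edge discontinuity
   of a plain periodic transform leaks low-frequency energy across the
   1–20 Hz band at a level comparable to the cardiac signal itself.
5. **Channel selection.** Correlation is the signed maximum of the
   normalised cross-correlation over small lags (±1 s respiratory,
   ±0.1 s cardiac) to absorb inter-coil delays; zero-lag-only is a
   config switch. Respiratory: the channel with the highest total
   correlation to the rest seeds the set and channels above 0.9 join.
   Cardiac: a seed channel (configured index, or `auto` = largest
   band-limited variance) is fixed and the threshold sweeps 0.90 →
   0.50 in 0.05 steps until at least three channels are accepted; if
   the sweep is exhausted the final set is kept when it has at least
   two members, otherwise extraction fails. The ≥3 stop rule with a
   ≥2 floor is deliberate: both counts are physiologically plausible
   and both behaviours are reachable through configuration.
6. **Source separation.** Respiratory: SOBI — whitening by
   eigendecomposition of the channel covariance, then Jacobi joint
   diagonalisation of symmetrised lagged covariances (lags 1–50
   samples ≈ up to 0.27 s, tolerance 1e-8, ≤100 sweeps); among the
   recovered sources the one with the largest spectral power fraction
   inside 0.05–0.9 Hz is returned. Cardiac: first principal component
   of the accepted channels. Both navigators are unit variance;
   polarity follows the mean channel (respiratory) or the seed channel
   (cardiac). Rank-deficient covariance falls back to PCA with a
   warning; an all-zero channel set is an error.

## Interference cancellation

**EDITER.** Lines are partitioned into windows of 50 (~266 ms); per
window and imaging coil, the readout samples are regressed onto the
sniffer-coil samples with FIR taps spanning ±K in-readout positions
and optionally ±Δ lines. The solve is least squares with singular
values below `0.02 × s_max` truncated, and the fit rows are
Hann-weighted (the prediction is applied unweighted). Window kernels
whose concordance similarity `2|<k1,k2>| / (|k1|² + |k2|²)` exceeds
the grouping threshold are merged and refit on pooled rows.

Three defaults differ from the obvious first guesses, all for the same
reason — *do not spend noise-spanned degrees of freedom, they project
out desired signal at ~sqrt(p/n) RMS per window*:

* `kernel_halfwidth = 0`. A narrowband carrier is a per-line complex
  gain away from the sniffer record; extra taps only add directions
  spanned by sniffer receiver noise. K > 0 remains available (and is
  what the broadband-interference tests use).
* `group_corr_threshold = 1.0` (no merging). Cosine-style similarity
  is scale-invariant, so windows in different amplitude-modulation
  states would always merge, leaving the pooled kernel stale by the
  full modulation depth. The concordance form is scale-sensitive;
  grouping is useful for piecewise-static interference and is enabled
  by lowering the threshold.
* Truncated SVD instead of an automatic ridge fallback: ridge
  re-admits the noise directions with weight `s²/(s²+λ)` and there is
  no λ that both preserves exact static cancellation and suppresses
  them. `ridge_lambda > 0` switches to ridge explicitly.

The residual after EDITER has two irreducible parts: within-window
modulation staleness (∝ window length × modulation slope) and sniffer
receiver noise injected through the kernels (∝ ‖kernel‖·σ_sniffer,
which is why strong sniffer-to-carrier coupling is the favourable
operating point).

**Model subtraction (baseline).** One global carrier frequency from
the record-averaged spectrum — quadratic interpolation then a bounded
Brent refinement of total projection power within ±1 bin — then a
per-line, per-coil complex amplitude by projection, and subtraction.
Exact for a static tone; degraded by anything that makes the carrier
non-sinusoidal at the global frequency within a readout, which is
precisely what frequency drift does and why the sniffer-based method
wins at high amplitude.

## Gating

Triggers: central-difference derivative of the cardiac navigator,
affinely normalised so the 10th percentile is 0 and the 98th is 1;
local maxima with minimum separation 0.375 s (taller peak wins) and
topographic prominence above 0.5. A flat navigator (equal percentiles)
yields zero triggers with a warning. The detection is invariant to
positive affine transforms of the navigator by construction.

Matching walks consecutive reference R-wave pairs with half-open
windows `[R_k, R_{k+1})`: first pilot-tone event inside is the match,
extras are false positives, an empty window is a false negative;
events before the first or after the last R-wave are out of scope.
Jitter is the sample SD (n−1) of the matched time differences; the
failure rate is `100·(FP+FN)/n_triggers` with `n_triggers` the number
of R-waves heading a window — the convention under which the published
per-patient counts reproduce their printed failure rates exactly.

Binning: cardiac phase bin `floor(20·(t−T_k)/(T_{k+1}−T_k))` within
each RR interval (clipped to bin 19; lines outside the trigger span
unassigned); respiratory bins by rank-based equal-count amplitude
quantiles (12), the amplitude-gating convention of retrospective
binning.

## Reconstruction and noise metric

Adjoint gridding with a width-4 Kaiser–Bessel kernel at 2×
oversampling (Beatty β), deapodisation, root-sum-of-squares coil
combination; density compensation by Voronoi cell areas of the sampled
k-space points (duplicates share their cell, unbounded boundary cells
are clipped to the largest finite area), cached per trajectory. View
sharing reconstructs frame `j` from `footprint` (55) lines starting at
`j · stride` (17); 17·TR = 90.4 ms and 55·TR = 292.6 ms — frame timing
follows the arm counts, not rounded millisecond labels. The noise
ratio is the SD of magnitude pixels inside a centred circular ROI
(default diameter 53% of FOV, the 16-cm-of-30-cm analog) of a
noise-only reconstruction, divided by the same quantity for a no-PT
reference; magnitude statistics are Rayleigh-biased but the bias
cancels in the ratio. Pipeline-level evaluation pools the ROIs of
non-overlapping view-share frames to shrink the sampling error of the
SD estimate.

## Simulator: what it does and does not emulate

Emulated: golden-angle spiral geometry (increment 137.507764°,
configurable), TR 5.32 ms (188 Hz navigator sampling), an analytic
ellipse phantom sampled along the trajectory, per-coil modulated
carrier with continuous within-readout evolution, generator frequency
drift (default 500 Hz over the scan — an exaggerated stand-in for the
combined frequency/phase wander of an unsynchronised generator),
angle-locked eddy-like deviations, receiver noise, a PT-proportional
receiver-local noise floor (saturation/quantisation leakage, the
mechanism that makes the noise ratio grow with amplitude even under
perfect carrier cancellation), noise-only scans, and arrhythmic beat
sequences (skipped and ectopic beats).

Defaults are calibrated to the published operating points: the ratio
of PT-proportional noise to receiver noise (0.0075/0.003) reproduces
noise increases of roughly 12% at 0.2 V and ~40% at 0.4 V; cardiac
modulation depth 1% of the carrier (top of the plausible range at this
field strength), respiratory 5%; sniffer coils couple to the carrier
about twice as strongly as imaging coils, as elements near the
transmit antenna would.

Not emulated: Bloch/bSSFP physics (banding), realistic coil
sensitivity maps, B0 drift of the imaging signal, receiver saturation
as a nonlinearity (only its noise-floor effect), gradient-imperfection
trajectory errors, and broadband generator noise that is *correlated*
across coils — cancelling that component requires spending
noise-spanned fit directions and therefore trades directly against
desired-signal preservation; the simulator keeps the PT-proportional
noise receiver-local instead. Consequently, passing tests demonstrate
correctness of the algorithms under a faithful but idealised
interference model, not performance on scanner data.

## Numerical choices

* Seeds: one global seed expands into per-stage `SeedSequence`
  children in fixed order; identical configuration ⇒ byte-identical
  artifacts.
* PCA sign ties: orientation by the seed-channel inner product, then
  by the first nonzero loading — deterministic under repeated calls.
* Degenerate inputs: flat navigators, all-zero channels, empty line
  subsets, missing sniffer coils and unidentifiable windows raise
  typed errors (`ValidationError`, `ExtractionError`) rather than
  propagating NaNs.
* The trigger suite is checked against an independent brute-force
  implementation (exhaustive local-maximum, greedy tallest-first
  separation, direct prominence definition) for exact peak-set
  agreement.
* Test problem sizes: 90 s for parameter recovery, 30 s per amplitude
  for the six-point sweep, 20 s for desired-signal preservation —
  chosen so each property is measured well clear of its sampling
  error.

## Known limitations

Everything here is retrospective (whole-record filters, full-record
PCA/SOBI); prospective gating would need causal replacements and can
be expected to trade jitter for latency. The cardiac seed-channel
`auto` heuristic (largest band-limited variance) is a convenience, not
a validated substitute for anatomically informed selection. Voronoi
density compensation is adequate for quick-look gridding but not a
substitute for iterative reconstruction. The failure-rate convention
ties `n_triggers` to reference R-waves heading a search window; other
conventions would change the printed rates.
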