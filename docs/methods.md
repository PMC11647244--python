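# Methods

## Model

The lattice holds one oscillator per column. Per step (1 ms), each node
averages its neighbours' activation differences (the grid Laplacian
`Δ'`), integrates that average into a lateral-feedback variable `Δ`
(damped by `1+f`), and integrates `Δ` into the activation `A` (damped by
`1+g`), with the Laplacian term scaled by the coupling `c²`. Setting
`c² = 1, f = g = 0` recovers the bare twice-integrated-Laplacian rule.
The update is linear and, with zero damping on a torus, conserves the
total activation; stimuli therefore superpose exactly, which is the
substrate of the interference ("holographic") storage the codec exploits.

State is double precision throughout; each step checks for non-finite or
overflowing (≥ 1e120) amplitudes and raises an instability error carrying
the step index. Every stochastic element (noise drive, lesion masks,
coupling jitter, burst onsets) takes an explicit seed.

### Normal modes, dispersion, stability

On a torus the spatial DFT modes evolve independently through the 2×2 map

    Δ_k ← (Δ_k + c² μ_k A_k)/(1+f),   A_k ← (A_k + Δ_k)/(1+g)

where `μ_k` is the eigenvalue of the neighbour-mean-minus-centre
operator: `(cos θx + cos θy)/2 − 1 ∈ [−2, 0]` for the 4-neighbour
stencil, `(2cos θx + 2cos θy + 4cos θx cos θy)/8 − 1 ∈ [−1.5, 0]` for the
8-neighbour stencil. The map's determinant is `1/((1+f)(1+g))`; its
eigenvalues `z = e^{−λ_k ± iω_k}` give the damping and frequency of each
mode. The Jury conditions collapse to a closed-form stability bound

    c²_max = (2+f)(2+g) / |μ_min|,

i.e. 2 (4-neighbour) and 8/3 ≈ 2.667 (8-neighbour) undamped. All
underdamped modes share the same decay `λ = ½ ln((1+f)(1+g)) ≈ (f+g)/2`,
which yields the `1/(f+g)` energy-decay timescale used by the
image-persistence analyses.

**Why the presets use the 8-neighbour stencil.** The waking parameter set
(c² = 2.6655, f = 0.01, g = 0.0001) exceeds the 4-neighbour bound
(≈ 2.01) — it would diverge within milliseconds — but sits 0.55 % below
the 8-neighbour bound (2.680). Since the waking state is described as
coupling "approaching its maximum", the presets run the 8-neighbour
lattice on a torus; the 4-neighbour stencil remains the constructor
default for the bare model and for the closed-form `c²_max = 2` checks.

### Boundaries, lesions and the pinning gap

Two averaging rules are implemented. *Renormalized* (`renormalize=True`):
a node divides by its actual live-neighbour count; missing or lesioned
neighbours simply drop out. *Fixed-divisor* (`renormalize=False`): the
divisor stays at the full stencil size and dead or out-of-grid neighbours
contribute zero activation.

The choice matters near the stability bound. Renormalized lesioned (or
clamped-edge) lattices have Laplacian spectra extending *below* the
full-torus `μ_min` (measured −1.52…−1.73 for 4–20 % lesions), so the
waking coupling becomes unstable and any lesion experiment explodes.
Under the fixed-divisor rule the operator on live nodes is a principal
submatrix of the torus operator scaled by 1/k, so Cauchy interlacing
guarantees `μ ≥ −1.5` for *every* lesion pattern: waking-coupling runs
remain stable under arbitrary lesioning. Lesion semantics therefore
default to fixed-divisor ("absorbing": dead columns read as zero), with
the renormalized variant available.

Fixed-divisor lesions act as pinning sites and open a low-frequency
spectral gap of order `sqrt(c² · fraction)` rad/step (≈ 50 Hz at 4 %
lesions at waking coupling): drive below the gap becomes evanescent and
does not propagate to distant electrodes. The lesion-robustness protocol
therefore probes fundamentals above the gap at the largest tested
fraction (periods of 5–9 steps, 111–200 Hz). This is a genuine property
of the absorbing-lesion model, not an artifact: sub-gap information is
truly lost, supra-gap information survives heavy lesioning.

### Analytic engine and codec

`evolve_analytic` evaluates each mode in closed form via spectral
projectors, `M^n = (z1^n (M − z2 I) − z2^n (M − z1 I))/(z1 − z2)` (with
the confluent limit where `z1 ≈ z2`), plus a per-injection sum for
stimuli; it matches the stepping simulation to ~1e−14 relative error and
serves as the package's central oracle (asserted at ≤ 1e−8).

Static-image decoding divides each snapshot mode by its scalar response
`s_k(t̄) = Σ_τ f(τ)·[M^{t̄−τ+1}]_{00}`; modes with `|s_k|` below
1e−12 × max are zeroed and counted (and can be made to raise). In exact
arithmetic the inversion is exact at any `t̄`; failure sets in only when
`e^{−λt̄}` reaches machine precision — with f = g = 0.001 that is far
beyond 12 s of model time, which is why the round trip still reaches
r ≈ 1.0 at the latest tested snapshot.

Dynamic decoding inverts the per-mode temporal convolution in the
frequency domain with the same relative floor. A causal (recursive)
inverse is numerically unstable for modes whose inverse filter has a pole
outside the unit circle (`|1 + c²μ/(1+f)| < 1/(1+f)`); the two-sided
frequency-domain inverse is stable and exact to ~1e−14 provided the
recorded history extends past the stimulus until the response has decayed
(about `1/(f+g)` steps). Output known only every s-th step is
sinc-interpolated first, so recovery is band-limited to the coarse
Nyquist band.

Audio follows the inject/record protocol: input resampled to 1000 Hz with
a polyphase anti-aliasing filter (`scipy.signal.resample_poly`), injected
at one node, recorded at (50,0), (0,50), (50,50), compared by Hann STFT
(window 128). Recording uses 2 mm-diameter discs by default: single
columns under-represent the lowest fundamentals relative to the lattice's
own high-frequency ringing (see electrode scale below).

## Electrodes

An electrode is a disc (half-open: a node is covered when its centre lies
strictly inside the radius) reporting the spatial **mean** of `A` so that
amplitudes are size-invariant; a sum option exists. Unit = 0.25 mm radius
(one column), LFP ≈ 1 mm, EEG ≈ 10 mm, grating EEG = 2.5 mm. Large discs
average out spatially alternating high-frequency modes (high-frequency
masking), which is also why complexity comparisons between states are
made at EEG scale: at the single-column scale the waking state's coherent
band-edge ringing binarizes to a nearly periodic (highly compressible)
sequence and the complexity ordering of states is not interpretable.

## Analysis choices

- **Peak detection:** Hann taper, 4× zero-padding, local maxima above 5×
  the median spectral magnitude.
- **Peak half-width:** width at half *power* (−3 dB), by linear
  interpolation — the standard linewidth convention; for a Hann taper on
  a T-second record it equals 1.44/T (0.48 Hz at 3 s).
- **Wave speed:** distance divided by the first crossing of a threshold
  (default 1 % of source amplitude; tests use 0.1 % for weak far-field
  fronts and cover the sensitivity). Torus wrap-around distances are the
  shorter arc. The measured first-arrival speed equals the analytic axis
  group velocity where the dispersion is nearly linear (near-maximal
  coupling); at weak coupling precursors make threshold speeds exceed the
  small-k group velocity, so the quantitative comparison is pinned at the
  waking point.
- **Coherence:** Welch magnitude-squared coherence, non-overlapping
  windows (independent-noise bias 1/K, asserted).
- **Correlation networks:** Pearson matrix over a uniform subgrid of
  columns (the full N² matrix is subsampled), threshold ρ+ = 0.07. Tail
  growth with coupling is measured on *long-range* degrees (edges beyond
  15 columns): stronger coupling correlates distant columns and extends
  the right tail of P(k).
- **Lempel–Ziv complexity:** median binarization, LZ76 exhaustive-history
  phrase counting (verified against a brute-force parser; the constant
  string has 2 phrases, the alternating string 3); normalized variant
  `c·log2(n)/n`.
- **Induced/evoked HF power:** single Hann taper, 50 ms windows sliding
  in 1 ms steps, 20–500 Hz in 20 Hz steps, relative baseline correction
  (−0.25…−0.1 s), HF envelope = mean over 250–450 Hz, envelope
  demodulated by FFT (Hann, zero-padded to 3 s) separately for the
  pre (−0.6…−0.1 s) and post (−0.1…0.4 s) windows; evoked variability
  over 10-trial averages. Latency = first time the induced envelope
  exceeds 25 % of its post-onset maximum.
- **Resonances vs size:** counted as spectral peaks above 1 % of the
  strongest line with ≥ 1 Hz separation — a relative criterion, because
  the mode spectrum of a large grid is dense and a median-floor criterion
  drowns in it.

## Stimulus generators

Pulse trains are 1-step rectangles scheduled by accumulated phase, with
exact counts at period boundaries (7 Hz over 3 s gives 21 pulses). The
multi-train protocols use integer step periods (e.g. 143, 91, 77, 59,
53, 43, 34, 32 → 7.0–31.3 Hz) so the drive is exactly periodic and the
spectrum a clean comb; non-integer periods carry 1 ms scheduling jitter
whose phase noise floods the upper spectrum and buries the low-frequency
lines. The grating is 8 equal-width alternating stripes (+10 / −9 mV)
clipped to a 10 mm disc, 1 s on / 1 s pre / 1 s post per trial. The
complex-burst state input is 50 high-frequency bursts with a slow
envelope at random nodes and onsets. The synthetic "song" is 12 harmonic
tone stacks (fundamentals 60–460 Hz) plus two chirps at 44.1 kHz, built
to exercise the audio path without external data. All generators are
deterministic under their seed.

## What the synthetic data does and does not show

The generators emulate the *structure* of the study conditions —
grid-scale, timing, amplitudes, trial layout — not biological variability:
there is no electrode noise, no volume conduction, no spiking, no
plasticity, and trials of the deterministic grating run are identical up
to startup transients (so induced ≈ evoked there). Passing tests
demonstrate the model's internal consistency and its qualitative
phenomenology, not fidelity to any particular animal recording.

## Problem sizes

Test and acceptance runs use the full 150×150 waking lattice for 3 s
records, a 64×64 torus for codec round trips (snapshots up to 12 s),
12-trial grating sessions, and 5 lesion seeds per fraction up to 30 % —
sizes chosen so the whole suite completes in well under an hour on one
CPU while exercising the printed parameter regimes unchanged.

## Known limitations

- The analytic engine (and hence exact decoding) requires the torus; on
  clamped grids encoding works but decoding is approximate (not offered).
- Near the stability bound, band-edge modes are classified "overdamped"
  (real negative eigenvalues) yet oscillate at Nyquist; the dispersion
  table reports them with ω = π and two decay rates.
- The schizophrenia/SWS/anesthesia/Alzheimer presets are defined relative
  to waking by documented multipliers (coupling ×0.5; dampings ×10/×100;
  4 % lesions; ±20 % edge jitter with coupling rescaled below the jittered
  stability bound); they are qualitative state analogues, not fits.
- Wave-speed estimates depend on the arrival threshold away from the
  dispersionless regime; only the near-bound comparison is quantitative.
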