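# smtrack

Single-molecule tracking and residence-time analysis for live-cell
fluorescence time-lapse movies, with tracking parameters calibrated by an
explicit model of tracking errors.

Measuring how long a molecule — say, a transcription factor — stays bound to
chromatin means detecting it frame after frame, linking the detections into a
track, and reading the binding time off the track length.  Three processes
end a track: genuine dissociation, photobleaching of the label, and tracking
errors.  Only the first carries biology; the other two must be corrected or
they masquerade as fast dissociation.  `smtrack` implements the full chain —
spot detection, nearest-neighbour linking with one-frame gap bridging, the
tracking-loss model that picks the tracking radius for a chosen loss
probability, a Gillespie-based synthetic movie simulator that grounds every
claim, and the downstream kinetic and mobility analyses.

## The tracking-loss model

A bound molecule's apparent jump between consecutive frames mixes residual
diffusion and localization error,

    σ²(τ) = σ₀² + 4 D τ,          z = s²/σ²,

with `s` the tracking radius and `τ` the frame-cycle time.  Per frame the
track is falsely terminated with probability

    a_tr = a_NN + a_z (1 − f)(1 − a_NN),

where `a_z = exp(−z)` is the chance of a jump beyond the radius,
`a_NN = 0.76 π ρ σ²` the chance of an erroneous link to a neighbouring spot
at density ρ, and `f ≤ 0.5` the fraction of out-of-radius losses recovered
by allowing one gap frame (a correlated bivariate Gaussian integral this
package evaluates by deterministic quadrature).  Inverting `a_tr(s)` per
time-lapse condition gives radii that hold the loss probability *constant
per frame*, so tracking loss and photobleaching combine into a single decay
factor that the survival-time analysis fits and removes.  Residence times
are then inferred as a spectrum of dissociation rates over a fixed log-rate
grid by a global non-negative inverse-Laplace fit of all time-lapse
conditions at once.

## Worked example

`examples/calibrate_radius.py` simulates an immortal immobile molecule,
calibrates the radius for a 1 % loss per frame at three frame-cycle times,
then measures the realized loss by tracking:

```
target loss 1% per frame
  tau= 0.05 s: radius   84.7 nm (min bound-track length 3 frames), predicted loss 0.0109, measured 0.0132
  tau= 1.00 s: radius  156.4 nm (min bound-track length 2 frames), predicted loss 0.0101, measured 0.0112
  tau= 5.00 s: radius  313.8 nm (min bound-track length 2 frames), predicted loss 0.0100, measured 0.0102
```

The radius grows with the frame-cycle time (diffusion spreads the jumps),
keeping the per-frame loss at the target across conditions.
`examples/rate_spectrum.py` runs the whole pipeline on the five-state
scenario (dissociation rates 0.003–10 /s at frequencies 3–52 %, 1 %
photobleaching per frame) and prints the recovered spectrum:

```
fitted per-frame loss: 0.022
clusters (weighted mode, weight):
  0.0001077 /s     1.4 %
   0.009994 /s     9.8 %
     0.1661 /s    17.3 %
       1.21 /s    15.0 %
       9.24 /s    56.6 %
recovered within half a decade: {0.003: True, 0.02: True, 0.2: True, 1.3: True, 10.0: True}
```

All five rate clusters resolve, and the fitted per-frame loss ≈ 2 % is the
product of 1 % bleaching with the 1 % calibrated tracking loss — the
correction working as designed.  Further examples cover movie simulation
and rendering (`simulate_movie.py`), detection + linking
(`detect_and_track.py`) and the mobility analyses (`mobility_analysis.py`).

A thin command line mirrors the library:
`smtrack simulate | detect | track | suggest-radius | spectrum | batch | export`.

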