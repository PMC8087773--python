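# retinostat

Quantitative analysis tools for studies of retinal ON-bipolar cell (OBC)
signaling: electroretinogram (ERG) and rod-photocurrent sensitivity
fitting, oscillatory-potential extraction, confocal quantification of
synaptic-protein puncta at OBC dendritic tips, and the paired WT/KO
statistics (jackknife bias-corrected ratios, paired and Welch's t-tests)
that such experiments report. A synthetic-data generator with exact
ground truth makes every stage verifiable at desk scale.

## Who this is for

Visual neuroscientists comparing knockout and wild-type littermates on:

* **Response sensitivity.** B-wave peak amplitudes follow the hyperbolic
  saturation law *B*/*B*<sub>max</sub> = *S*<sub>B</sub>*I* / (1 +
  *S*<sub>B</sub>*I*), where *S*<sub>B</sub> is the inverse of the
  half-saturating flash intensity. Two flashes (dim + saturating)
  suffice: `SaturationModel` inverts the law in closed form, or fits by
  least squares for more intensities.
* **Phototransduction activation.** A-wave and rod-photocurrent rising
  phases follow *A*(*I*,*t*)/*A*<sub>max</sub> = 1 −
  exp(−*S*<sub>A</sub>*I*(*t* − *t*<sub>d</sub>)²).
  `RisingPhaseModel` fits (*S*<sub>A</sub>, *A*<sub>max</sub>,
  *t*<sub>d</sub>) jointly over a family of flash intensities, with the
  delay constrained to its physiological range and the rising window
  chosen per recording mode (fixed 60 ms for dim-flash rod currents; up
  to the response peak, shortened by 5 ms for long rises, for ERG).
* **Inner-retinal activity.** Oscillatory potentials (75–300 Hz wavelets
  on the photopic B-wave rising phase) are band-passed and measured as
  the negative-to-positive peak swing, normalized by
  *B*<sub>max</sub>.
* **Synaptic protein levels.** Two-channel confocal z-stacks are
  normalized to the outer-nuclear-layer background; dendritic tips are
  found as strict 3-D local maxima of the mGluR6 reference channel,
  classified rod vs cone by their mask extent (≤0.5 µm per side vs
  >1.1 µm including the centre), and the target protein is summed over a
  1.1 × 1.1 µm window per tip, in background units.
* **Paired ratios.** The KO/WT ratio-of-sums *r* = Σ*y*/Σ*x* carries an
  O(1/*n*) bias; the jackknife correction *r*<sub>c</sub> = *n r* −
  (*n* − 1)/*n* · Σ*r*<sub>i</sub> (leave-one-out ratios
  *r*<sub>i</sub>) reduces it to O(1/*n*²), with leave-one-out spread
  giving the uncertainty. Welch's t (single and double-difference, p =
  I<sub>v/(v+t²)</sub>(v/2, ½) with Satterthwaite degrees of freedom)
  and correlation t-transform p-values round out the toolkit.

## Worked example

```python
import numpy as np
from retinostat import synth, RisingPhaseModel, PairedSample, jackknife_ratio

# round-trip a rod photocurrent family through the activation model
traces = [synth.gen_rising_phase_trace(7.1, 14.1, 0.015, I, dt=0.001,
                                       duration=0.09,
                                       intensity_unit="R*/rod")[0]
          for I in (2.0, 10.0, 50.0)]
fit = RisingPhaseModel(traces, "rod_photocurrent").fit()
print(fit.summary())

# jackknife bias-corrected KO/WT ratio on a paired intensity table
est = jackknife_ratio(PairedSample([1.0, 2.0, 3.0], [2.0, 3.0, 7.0]))
print(est.summary())
```

prints

```
Rising-phase fit  A(I,t) = A_max (1 - exp(-S_A I (t-t_d)^2))
------------------------------------------------------------
S_A    7.10000 [R*/rod]^-1 s^-2
A_max  14.1000
t_d    15.00 ms
mode            rod_photocurrent
traces/samples  3/183
residual (RSS)  2.77e-30
converged       True
Jackknife paired-ratio estimate (KO/WT)
--------------------------------------------
n pairs                3
naive ratio r          2.00000
jackknife SD s         0.2406
bias-corrected r_c     2.05556
corrected SD s_c       0.3099
```

The fit recovers the generating sensitivity (7.1 per R*/rod per s²),
saturated amplitude (14.1 pA) and delay (15 ms) from the noise-free
family; the ratio example shows the naive ratio 2.0 shifted upward by
the bias correction with its jackknife uncertainty.

Full simulate→analyze rounds are available from the shell:

```bash
retinostat run-all --seed 1 --out-dir out/
```

which reports paired KO-vs-WT tests on sensitivity and saturated
amplitude, the OP-vs-sensitivity correlation, and jackknife KO/WT
ratios for OPL, rod-tip and cone-tip protein levels.

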