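# fp-photodyn

Quantitative image analysis for fluorescent-protein (FP) photostability
studies. The package implements, as a tested reusable library, the four
analyses used to characterize highly photostable green-emitting FPs such as
StayGold against references like EGFP and mNeonGreen:

1. **Brightness-adjusted photobleaching.** Raw intensity decays are placed on
   a standardized scale on which every curve starts at an emission rate of
   1,000 photons/s/molecule. The per-molecule rate follows from the
   absorption cross-section σ = 10³·ln10·ε/N_A, the quantum yield Φ and the
   excitation photon flux I·λ/(hc); the time axis is stretched by that
   rate/1,000 so equal normalized times mean equal photons emitted per
   molecule. The photostability figure of merit is t½, the first time the
   normalized rate falls through 500, and the irradiance dependence is
   summarized by the power law log₁₀(t½) = −α·log₁₀(I) + c.
2. **Molecular and cellular brightness.** Molecular brightness is
   ε(λab)·Φ (ε in 10³ M⁻¹ cm⁻¹); cellular brightness is the median per-cell
   green/mCherry ratio of a bicistronic co-expression field, normalized to
   EGFP. Extinction coefficients can be derived by the alkali-denaturation
   ratio method (ε₄₄₇ = 44,000 M⁻¹ cm⁻¹ for the denatured chromophore).
3. **ER-network rearrangement maps.** Time-lapse movies of the endoplasmic
   reticulum are binarized per frame with an adaptive Otsu threshold, divided
   into 16×16-pixel sub-blocks, and movement is quantified per block and
   frame pair as the fraction of pixels that flip between foreground and
   background; the T−1 fraction maps are rendered as 0–255 heat maps and
   aggregated into per-cell temporal profiles.
4. **Tubule-oscillation kymographs.** Along the perpendicular bisector of a
   user-drawn axis, per-frame intensity profiles form a kymograph; the peak
   position tracked over time is Fourier-analysed in 128-sample windows
   (at 134.47 frames/s the frequency unit is 134.47/128 ≈ 1.05 Hz), and
   radially averaged image FFT spectra monitor resolution over time.

A synthetic-data module generates all inputs with known ground truth
(exponential bleaching decays, movies of oscillating tubular networks,
bicistronic expression fields), so every pipeline is testable end to end
without microscopy data.

## Worked example

`examples/04_tubule_oscillation_fft.py` simulates a 736-frame movie at
134.47 frames/s of tubules oscillating transversely at 7 Hz, builds a
kymograph on the most isolated tubule, and recovers the frequency:

```
programmed frequency: 7.0 Hz
frequency unit:       1.05 Hz (134.47/128)
windows analysed:     5
dominant frequency:   7.35 Hz
```

The dominant FFT bin (7.35 Hz) is the bin nearest 7 Hz on the 1.05 Hz grid —
recovery is exact to the spectral resolution. The other example scripts show
the photobleaching half-time pipeline (a mono-exponential decay with
k = 0.005 s⁻¹ under StayGold's photophysics normalizes to t½ = 712.1 s,
exactly scale_factor·ln2/k), the brightness table (StayGold 148, EGFP 36,
SiriusGFP 10, mClover3 83, mNeonGreen 97; a programmed cellular brightness
of 2.06 recovered as 2.081 from 200 simulated cells), and a movement map
whose motion-pause dip ratio is 0.167.

## Command line

Each analysis is also exposed as a thin CLI over the library:

```bash
fp-photodyn simulate ermovie --seed 1 --out sim/
fp-photodyn ermap --movie sim/movie.tif --block 16 --out ermap/
fp-photodyn kymo --movie sim/movie.tif --axis 60,30,100,34 --out kymo/
fp-photodyn bleach --trace trace.csv --name StayGold \
    --irradiance 5.6 --wavelength 488 --out bleach/
```

Every output directory contains the resolved configuration and seed.

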