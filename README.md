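# circalux

Circadian and brightness metrics for light-source spectra, computed from
absolute spectral irradiance distributions, plus a correlation pipeline that
relates the metrics to each other across a light-source ensemble.

Lighting research and practice currently quantify the non-visual (ipRGC-
mediated) effect of light with several competing metrics, and the perceived
brightness of polychromatic white light with several more. This package
implements the full stack as spectral-integration operations on one common
observer-function bundle:

* **CL_A 1.0 / CL_A 2.0** — the circadian-light models of Rea et al.
  (2018 and 2021 revisions), which combine a melanopsin term with a
  blue-versus-yellow (b−y) cone-opponent term and rod terms. The sign of
  b−y = ∫S_c E dλ − k·∫V_c E dλ selects the "warm" or "cold" branch
  (empirically near 3400–3710 K CCT); both versions are anchored so that CIE
  illuminant A at 1000 photopic lx gives CL_A = 1000.
* **CS** — circadian stimulus, the predicted fractional nocturnal melatonin
  suppression: CS = 0.7 − 0.7 / (1 + (CL_A·t·f / 355.7)^1.1026), with
  exposure time t (hours) and field factor f ∈ {0.5, 1, 2}. CS saturates at
  0.7 and equals 0.35 at the half-saturation dose 355.7.
* **mEDI** — melanopic equivalent daylight (D65) illuminance per CIE S 026:
  the melanopic irradiance of the test light divided by the melanopic
  irradiance of D65 at one photopic lux.
* **Giménez et al. melatonin suppression** — the published logistic formula
  from mEDI, exposure duration and pupil dilation, evaluated verbatim as
  printed in its secondary source and flagged `as_printed` (the transcription
  is internally inconsistent; see `docs/methods.md`).
* **L_eq** (Fotios–Levermore) — equivalent luminance L_v·(S/V)^0.24.
* **B₂** (Bullough) — V + 0.6·g·S + 0.5·Mel with a caller-supplied
  adaptation factor g.
* **M_TUD** — the TU Darmstadt brightness model
  M = 8.9974·[E_v^0.2629·(S^0.074 + 0.5·G^0.0424)] − 1.3307, entered either
  from printed S-cone/photopic and melanopsin/photopic ratios or from a
  spectrum.

Because the measured 884-spectrum corpus these metrics are usually compared
on is not publicly deposited, `circalux.ensemble` generates a seeded
synthetic stand-in with the same class composition (28 incandescent,
252 fluorescent, 419 LED, 185 daylight) and CCT coverage (2201–17815 K),
and `circalux.pipeline` runs the comparison: all metrics at 125/500/750 lx,
pairwise r² matrices for the full corpus and for the warm (CCT ≤ 3710 K) and
cold (CCT > 3710 K) partitions, metric conversion fits, and a Planckian sweep
that locates the warm/cold branch discontinuity.

## Worked example

```python
from circalux import *

bundle = load_bundle()                      # 380-780 nm at 1 nm
led = synth_spd("led", {"blue_peak": 450.0, "blue_fwhm": 20.0,
                        "phosphor_center": 580.0, "phosphor_fwhm": 100.0,
                        "ratio": 0.55}, bundle.grid)
led = scale_to_illuminance(led, 500.0, bundle)   # 500 photopic lx at the eye

chrom = chromaticity_cct_duv(led, bundle)
r18, r21 = cla_2018(led, bundle), cla_2021(led, bundle)
print(f"CCT {chrom.cct:.0f} K  Duv {chrom.duv:+.4f}")
print(f"E_v 500 lx, mEDI {medi(led, bundle):.1f} lx")
print(f"CL_A 1.0 {r18.value:.1f} ({r18.branch}), CL_A 2.0 {r21.value:.1f} ({r21.branch})")
print(f"CS_2018 {circadian_stimulus(r18.value):.3f}  CS_2021 {circadian_stimulus(r21.value):.3f}")
print(f"L_eq {leq_fotios(led, bundle):.1f}  M_TUD {m_tud_from_spectrum(led, bundle):.2f}")
```

prints

```
CCT 3410 K  Duv +0.0128
E_v 500 lx, mEDI 205.9 lx
CL_A 1.0 365.3 (warm), CL_A 2.0 291.3 (warm)
CS_2018 0.355  CS_2021 0.312
L_eq 383.1  M_TUD 94.76
```

i.e. this warm-white LED at 500 lx delivers a melanopic dose equivalent to
206 lx of daylight; both circadian-light models put it on the warm branch
(CCT below the b−y sign change), predicting roughly a third of the maximum
attainable melatonin suppression after one hour; and its blue-lean spectrum
makes it perceptually dimmer than a flat-spectrum source of equal photopic
illuminance (L_eq 383 < 500).

The same computations are available from the shell:

```sh
circalux ensemble  --seed 1 --out-dir spds/          # synthetic corpus + manifest
circalux compute   --spd spds/led_000.spd --level 500 --out metrics.json
circalux m-tud     --ev 108 --s-ratio 0.27 --mel-ratio 0.14
circalux correlate --seed 1 --out report.json --matrices-dir matrices/
```

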