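# Methods

This note records the models implemented in circalux, the numerical
conventions, the design choices that were genuinely open, and what the
synthetic ensemble does and does not establish.

## Observer functions and quadrature

All metrics are trapezoidal integrals on a common wavelength grid, by
default 380–780 nm at 1 nm; functions are extended with zero outside their
tabulated support. A 5 nm grid changes metric values for smooth (Planckian)
spectra by well under 0.5 %.

Bundled tables (plain text, `circalux/data/`):

* CIE 1924 photopic V(λ) (identical to ȳ of the 1931 2° observer) and the
  CIE 1951 scotopic V′(λ), both peak-normalized as published.
* An S-cone fundamental proportional to the CIE 1931 z̄ colour-matching
  function (the Smith–Pokorny construction S ∝ z̄), peak-normalized. Only
  ratios and correlations of S-weighted integrals enter any result, so the
  proportionality constant is immaterial.
* The melanopic action spectrum s_mel after CIE S 026 (energy basis,
  peak-normalized, 10 nm tabulation interpolated linearly).
* Macular pigment relative optical density (Snodderly-type, peak at
  460 nm), converted to transmittance as mp = 10^(−D·d_rel) with peak
  density D = 0.35 (the standard 2° value; a load-time parameter).
* Crystalline-lens optical density of an average young observer.
* The CIE 1931 2° colour-matching functions at 5 nm.

Melanopsin M_c is not tabulated in any citable standard at the precision
needed, so it is constructed: Govardovskii A1 opsin template with
λ_max = 480 nm (quantal), converted to an energy basis (×λ), multiplied by
the bundled lens transmittance, and peak-normalized. Two independent checks
pin this construction and the typed tables: the melanopic irradiance of D65
per photopic lux computes to 1.3277 mW m⁻² lx⁻¹ (the canonical CIE value is
1.3262, 0.1 % away), and the CL_A illuminant-A anchor lands at 1005.8
(0.6 % from its defining value of 1000).

The macular-corrected functions V_c = (V/mp)/max(V/mp) and
S_c = (S/mp)/max(S/mp) are built once per bundle; the correction is
idempotent up to scale and peaks at exactly 1.

## Chromaticity, CCT, Duv

The CMFs are rescaled at bundle construction so their three trapezoidal
integrals over the working grid are exactly equal (scale factors within
0.2 % of unity). This makes the equal-energy chromaticity exactly
(1/3, 1/3) and is self-consistent downstream because the Planckian locus is
computed with the same scaled CMFs.

CCT/Duv uses an Ohno-style search: the locus is pre-sampled in the CIE 1960
(u, v) diagram from 1000 to 25000 K at a 0.04 % multiplicative step, the
nearest sample is found by direct search and refined by parabolic
interpolation of the squared distance in log-T, giving sub-kelvin effective
resolution (Planckian inputs are recovered to ≪ 1 K with |Duv| < 10⁻⁸).
Duv is the signed (u, v) distance, positive above the locus. |Duv| > 0.05
flags the CCT as not meaningful instead of silently reporting a number.

Reference illuminants: Planck's law with c₂ = 1.4388·10⁷ nm K; the CIE
D-series from the S₀/S₁/S₂ characteristic vectors (domain 4000–25000 K);
D65 reconstructed from the same vectors at its defining chromaticity
(0.31272, 0.32903) rather than from a separate table — mEDI self-calibration
(below) makes the residual tabulation difference irrelevant.

## Circadian-light models

CL_A 1.0 (2018): warm branch 1548·∫M_c E dλ; cold branch adds
0.7·(b−y) and subtracts 3.3·(1 − e^(−∫V′E dλ / 6.5)), with the rod
saturation constant in scotopic W m⁻². CL_A 2.0 (2021): both branches
subtract 2.3·(∫V′E / (∫V_c E + 1.00·∫S_c E))·(1 − e^(−∫V′E/6.5)); the cold
branch adds 0.21·(∫S_c E − 0.2616·∫(V/mp) E) and subtracts the analogous
second rod term with weight 1.60 and denominator weight 0.16. The cold
opponent amplitude deliberately mixes the normalized S_c with the
unnormalized V/mp, exactly as the model is printed; the per-term breakdown
returned by both functions makes this auditable, and
value = 1548 · Σ(terms) holds to 10⁻⁹ by construction.

**Branch switch normalization.** Both versions decide the branch with the
peak-normalized corrected functions: b−y = ∫S_c E − 0.2616·∫V_c E. For the
2.0 model this is the printed definition. For the 1.0 model the printed
switch uses unnormalized S/mp and V/mp; with standard peak-1 tables that
form crosses zero near 2500 K, which would place CIE illuminant A (2856 K)
on the cold branch and break the model's own definitional anchor
CL_A(A @ 1000 lx) = 1000 by a factor of about two. Since the anchor is the
defining property of the quantity, the 1.0 switch (and its cold-branch
amplitude) is evaluated with the normalized functions, which moves the
crossing into the same ~3500 K band as the 2.0 switch — consistent with a
single empirical warm/cold boundary near 3710 K for the model family. On
the default bundle the Planckian b−y sign change sits at ≈ 3635 K.

CS: 0.7 − 0.7/(1 + (CL_A·t·f/355.7)^1.1026), defaults t = 1 h, f = 1.0
(central visual field); f outside {0.5, 1, 2} warns but computes. CS is
strictly increasing in the dose and bounded below 0.7.

mEDI: ∫E·s_mel dλ divided by the melanopic irradiance of D65 at one
photopic lux, the divisor computed at first use from the bundled tables
with the same quadrature. This self-calibration guarantees
mEDI(D65 at E lx) = E identically, independent of grid step or table
rounding.

Giménez et al. suppression: evaluated verbatim as printed,
(0 − 100)/(1 + log₁₀(mEDI·10⁶)/(9.002 − 0.008·Δt − 0.462·dil)). The printed
transcription is internally inconsistent — its magnitude tends to 0 rather
than 100 % at infinite illuminance and decreases with mEDI over the
photopic range, contradicting the increasing linear relation to CS that the
same literature reports. No corrected form is guessed; the result carries
an `as_printed` flag and caveat, and the quantity is excluded from the
pipeline's headline ordering checks and from the reproduced headline
numbers.

## Brightness metrics

Signal ratios use the equal-energy convention: an S/V or G/V ratio is 1 for
a spectrally flat source (each weighted integral is divided by the integral
of its weighting function). The underlying psychophysical ratio convention
is not recoverable from the published worked examples, which enter through
printed ratios anyway; any alternative global convention multiplies L_eq by
a constant and shifts M_TUD smoothly, leaving every correlation unchanged
(property-tested). L_v in L_eq is represented by photopic illuminance: the
inputs are irradiances at the eye, no geometry is modelled, and only ratios
and correlations are used downstream. B₂ uses M_c as its melanopsin
weighting, takes the adaptation factor g from the caller (default 1.0), and
is excluded from the headline pipeline. M_TUD has two entry paths — printed
ratios (reproducing the published equibrightness table to ≤ 0.4 %) and
spectrum-derived ratios — that agree by construction at equal inputs.

## Synthetic ensemble

The generator emulates the class composition and CCT/Duv placement of the
undeposited 884-spectrum corpus: 28 incandescent (Planckian, 30 % behind a
smooth exponential tilt filter solved to a CCT target, range 2201–5000 K),
252 fluorescent (mercury lines at 404.7/435.8/546.1/577.0 nm, σ = 2 nm,
over a warm/cool phosphor-band mixture solved to target, 2700–6500 K),
419 LED (blue pump Gaussian 440–460 nm FWHM ~20 nm plus one broad phosphor
band, pump/phosphor ratio solved to target, 2201–9000 K), 185 daylight
(CIE D-series, 4000–17815 K; the corpus extremes are daylight). CCT targets
are drawn log-uniformly per class — the real corpus's CCT histogram is
unknown, and this is the flagged stand-in assumption behind every
ensemble-dependent number. Draws are rejected unless the achieved CCT stays
in the class range and |Duv| < 0.02. The generator is fully seeded:
identical config and seed give bit-identical ensembles.

What the ensemble does *not* emulate: measured lamp libraries, colour
rendering targets, multi-band phosphor structure, atmospheric daylight
variability off the D-series locus. Passing correlation checks on this
ensemble therefore demonstrates properties of the metric definitions across
a realistic CCT/Duv span, not properties of any particular measured corpus;
exact published r² cell values are deliberately not targeted, only
orderings and bands that are robust to the stand-in.

## Correlation pipeline

Each spectrum is rescaled to 125/500/750 lx (practical indoor levels) and
all metrics are evaluated per (spectrum, level) row; correlations pool the
rows across levels (a `per_level` switch preserves the alternative —
pooling matches the single-cloud structure and hundreds-of-lx residual
scale of the published conversion fits). The warm/cold partition sits at
CCT = 3710 K, the empirical proxy for the b−y sign; the actual per-row sign
is recorded so the two partitions can be compared. Undefined r² (a constant
metric within a subset) surfaces as NaN, never 0. Conversion fits are
ordinary least squares (statsmodels) with RMSE the root mean squared
residual; on the default ensemble the pooled fit of mEDI on CL_A 2.0 has
slope ≈ 0.72 and r² ≈ 0.98. The discontinuity sweep walks Planckian
radiators at ≤ 25 K steps, locates the branch change of each model version,
and reports each metric's jump across the boundary pair of grid points;
mEDI serves as the continuous control, and the 1.0 model's CS jump exceeds
the 2.0 model's by roughly a factor of three at 500 lx.

Problem sizes: the default analyses use the full 884-spectrum ensemble ×
3 levels (2652 rows); oracle and plumbing tests use a 40-spectrum ensemble,
and the end-to-end determinism check a 22-spectrum config, determinism
being size-independent.

## Known limitations

* Observer tables are the standard 2°, adult-average ones; no age-dependent
  lens models, 10° observers, or field-size-dependent fundamentals.
* The melanopsin construction carries the tabulation uncertainty of its
  lens model; the 0.6 % residual on the illuminant-A anchor is the measured
  size of that uncertainty.
* Spectra are treated as irradiance at the eye; no radiance fields,
  luminance maps, or measurement-device corrections.
* The Giménez formula is reproduced, not repaired.
* CIE Ra / TM-30 fidelity indices are out of scope; the ensemble does not
  target them.
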