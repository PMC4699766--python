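# Methods

## Scope and assumptions

`rifvar` models the link between two distributions measured over a large
population of G0/G1 cell nuclei after photon irradiation: the per-nucleus
count of radiation-induced γH2AX foci (RIF), and the specific energy *z*
absorbed in a sub-nuclear target volume *V*. The working hypothesis is that
in a suitable *V* the count of a nucleus is proportional to the *z* it
absorbed, so the observed cell-to-cell count spread is the microdosimetric
energy spread seen through a constant yield factor, plus a small
radiation-independent background.

Assumptions inherited from that framing:

- track arrivals are Poisson with mean *n* proportional to dose (low-LET
  photon fields at these doses);
- single-track depositions are i.i.d., so the ν-track distribution is the
  ν-fold self-convolution of f₁(z);
- for the track numbers relevant here (n > 20 in nucleus-scale volumes above
  ~0.2 Gy) the compound distribution is well approximated by
  N(n·z̄₁, √(n·(z̄₁² + SD²_z₁)));
- DNA content is held constant across the analysed nuclei (hence the G0/G1
  gate), so the yield factor does not vary with cell-cycle state.

## The energy-spread relation and its calibration

The normal limit implies SD_rel(V, D) = k1·(V^k2·D)^(−1/2) with
beam-quality constants k1, k2 (valid only under the fixed convention V in
μm³, D in Gy, recorded on the model object). The form forces
SD_rel(V, 2D)/SD_rel(V, D) = 1/√2 exactly — the same fold change the count
data show — and the absolute SD (= D·SD_rel) to grow as √D.

The literature constants for the ⁶⁰Co beam are not available to this
package, so defaults are **calibrated** from a reference grid of
specific-energy statistics at two volumes (whole nucleus 293.7 μm³,
DNA molecule 8.5 μm³) × three doses (0.5/1/2 Gy), stored in
`rifvar.reference`. The fit is ordinary least squares in log space,
ln SD_rel = ln k1 − (k2/2)·ln V − (1/2)·ln D, with the dose exponent fixed
at −1/2 (it is structural, not free). This yields k1 ≈ 0.3165, k2 ≈ 0.8196
with r² > 0.999. The 1.6 μm³ block of the reference grid is deliberately
excluded from the fit and used as held-out validation (reproduced within 1%
per cell). Because the grid values carry only 2–3 significant figures, the
calibration carries ~5–10% uncertainty into the inverted volume (1.68 vs
1.6 μm³); alternative (k1, k2) can be supplied via the API or CLI.

Inversion is closed-form, V = (k1/(SD_rel·√D))^(2/k2), and round-trips with
the forward relation to < 1e−10 relative error.

## The discrete convolution engine

`rifvar.spectrum` keeps an exact discrete counterpart of the analytic
story, used as the oracle for the normal approximation. Spectra are pmfs on
an explicit grid; arbitrary atom sets are rebinned onto a uniform grid
(default step z̄₁/50) by linear mass-splitting, which preserves the mean
exactly and the variance to O(dz²). Convolution powers use binary
exponentiation of `np.convolve`; the Poisson mixture over ν is truncated at
cumulative mass 1−1e−9 (moment error well below grid error). Support
overflow raises — never silent truncation — with a pointer to the normal
approximation, whose moments n·z̄₁ and √(n·(z̄₁²+SD²_z₁)) the discrete
compound matches to 1e−6 on small on-grid spectra.

## Specific-energy sampling

Population energy samples are drawn from N(D, D·SD_rel(V, D)) with negative
draws resampled rather than clipped, preserving unimodality; the affected
mass at the worst case used here (0.5 Gy, V = 1.6 μm³, SD_rel ≈ 0.37) is
~0.3%, logged, and warned about above 1%.

## The synthetic population generator

No raw per-nucleus data are distributed with the package; the generator in
`rifvar.population` emulates the statistical structure the analysis needs,
at the per-nucleus summary level an imaging platform would export. Study
conditions (defaults):

| parameter | default | meaning |
|---|---|---|
| pooled n per dose | 25114 / 8242 / 8993 / 9010 | 0, 0.5, 1, 2 Gy group sizes |
| replicates | 9 (sham) / 3 | independent irradiations per dose |
| `foci_per_gray` | 15.5 | focus yield α (RIF·Gy⁻¹) |
| `target_volume_um3` | 1.6 | energy target for count generation |
| `background_mean`, `background_var` | 0.6, 2.1 | sham counts, negative binomial (r = mean²/(var−mean) = 0.24) |
| `dose_jitter_rel_sd` | 0.06 | per-replicate relative SD of delivered dose |
| `cycling_fraction` | 0.2 | S+G2/M fraction (plausible for high-confluence primary culture; not a published value) |
| `cluster_fraction` | 0.03 | touching-nuclei segmentation artefacts |

Count modes: `energy_only` (default) sets the induced count to
round(α·z), ties to even — the hypothesis that the energy spread carries
*all* the biological variability; `poisson_given_z` adds conditional Poisson
counting noise for comparison. The sham background is additive and
dose-independent in both modes, since sham counts are reported separately
and never subtracted.

Intensity features are placeholders in arbitrary units (their absolute
scales are not published): DAPI is lognormal around a 2N peak, ×(1.05–1.95)
in S, ×2 in G2/M; the γH2AX channel has a low G0/G1 baseline plus a minor
additive per-focus term and is strongly elevated in cycling nuclei through
a latent proliferative-activity factor shared with KI67 (giving the
observed rank correlation between KI67 and γH2AX background); clusters get
×1.8–3.2 area and 0.45–0.72 circularity. Only ordering and separability of
these features matter for gating, and that is all the passing tests
establish: the generator says nothing about segmentation quality, antibody
variability, focus merging at high dose, or any other property of real
images.

The 6% dose uncertainty is interpreted as a per-replicate relative SD on
the delivered dose (the error model is not otherwise specified); it
reproduces replicate-mean spreads of the right order (~0.9 foci at 1 Gy).

Known consequence of the additive background: group means are
α·D + 0.6 = 8.35/16.1/31.6, within ~5% of the observed pooled means
(8.8/17.6/30.6) but not equal, and the population SD_rel at 0.5 Gy comes
out ≈ 0.381 rather than the observed 0.363 — the background variance is
counted once in the observation (which the 1.6 μm³ inversion already
attributes entirely to energy spread) and once more by the generator. This
is a deliberate fidelity-to-structure choice, not a fit to the observed
table; the 1 and 2 Gy spreads land within ±0.015 of the observed values.

## Gating

`auto_gate_thresholds` derives both scatter-plot regions from the data:
the DAPI window is centred on the dominant (2N) mode found by Gaussian KDE
in log₁₀ space (half-width 0.125 decades ≈ ×1.33, vs the 0.30-decade 2N→4N
separation; KDE bandwidth scales with the data, so the window is exactly
scale-equivariant), and the γH2AX ceiling plus the area/circularity fences
are quartile fences Q1 − k·IQR / Q3 + k·IQR with k = 2. Quartile fences
were chosen over fixed percentile cuts because they adapt to contamination:
on default synthetic data they recover ≥ 99% of true G0/G1 singlets and
admit ≤ 0.1% of cycling nuclei, while on a pure non-cycling population they
exclude < 1%. A fixed percentile cut cannot do both. If the KDE mode search
fails the window falls back to the median with a warning. Gating only
subsets records; counts are never modified.

## Statistics

Sample variance uses the n−1 denominator throughout (at n ≥ 1500 the
distinction is < 0.1%). The mode is the most frequent value, ties broken
toward the smallest, for determinism. Fold changes are consecutive-dose
ratios with an explicit warning when doses do not double. The dose-response
line is unweighted OLS of per-dose averages of replicate means, with the SD
of replicate means reported as annotation; a replicate-level fit is
reported alongside because the two differ slightly under unbalanced
replicates (≈15.0 vs ≈15.4 foci/Gy on the default synthetic study). Q-Q
comparison pairs sorted order statistics for equal sizes, otherwise
interpolates both empirical quantile functions at (i−0.5)/n of the smaller
n; the fitted line is unweighted OLS, with an optional trim of the lowest
5% of pairs since the low-count corner bends away from the line. Tail
metrics report the fraction strictly below a reference mean and the percent
shortfall of a percentile relative to the mean.

## Problem sizes and determinism

Default study sizes match the experimental design (≈51k nuclei total) and
run in under a second; tests and examples use scaled-down groups
(hundreds to a few thousand nuclei per dose) chosen so that every assertion
still has ≥3-SE headroom. All randomness flows from one root seed through
`numpy.random.SeedSequence` spawning (disjoint streams per dose group,
replicate and stage), so a fixed seed yields bit-identical tables and
byte-identical report JSON.

## Limitations

- The true ⁶⁰Co single-track spectrum is not transported; the convolution
  engine works on user-supplied or synthetic spectra, and the beam enters
  only through the calibrated (k1, k2).
- Per-nucleus volume variability is not propagated into the energy
  calculations (a ~15% volume variation does not materially change the
  spreads at these doses); the geometry module exposes the volumes for
  sensitivity checks.
- Intensity-feature distributions are invented placeholders; conclusions
  about gating transfer to real data only insofar as the 2N/4N separation
  and the cycling-background elevation hold there.
- No significance testing across replicate sets is provided; the analysis
  is descriptive, as is the comparison it replicates.
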