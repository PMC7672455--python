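# Methods

## The measurement and the model

`h1fret` analyzes ensemble FRET measurements of Cy3/Cy5-labeled linker
histone H1 binding to nucleosomes.  The donor and acceptor sit at the two
ends of the intrinsically disordered H1 C-terminal domain (CTD); when H1
binds a nucleosome the CTD condenses, the fluorophores approach each other,
and transfer efficiency rises.  A second labeling scheme places the dyes at
the two linker-DNA ends of a reconstituted nucleosome to read out linker-DNA
geometry.

Each sample is scanned twice on a spectrofluorometer: an emission scan under
donor excitation (λ′ = 515 nm) and one under direct acceptor excitation
(λ″ = 610 nm).  The acceptor-normalized ratio

    (ratio)_A = A-emission(λ′ excitation) / A-emission(λ″ excitation)

obeys, for a population in which a fraction d⁺ of acceptor-bearing molecules
also carries a donor,

    (ratio)_A = (E · ε^D(λ′) · d⁺ + ε^A(λ′)) / ε^A(λ″)
    E = (ε^A(λ″) · (ratio)_A − ε^A(λ′)) / (ε^D(λ′) · d⁺)

Because the numerator and denominator share the acceptor emission lineshape
and detection chain, (ratio)_A is independent of acceptor concentration,
quantum yields and detector response.  The efficiency *difference* between
a nucleosome-bound sample and the free-label reference,

    ΔE = E_ref · ((ratio)_A,exp − (ratio)_A,ref)
               / ((ratio)_A,ref − ε^A(λ′)/ε^A(λ″)),

is algebraically equal to E_exp − E_ref and cancels d⁺ entirely, so only one
accurately determined reference efficiency is needed.  ΔE is the package's
primary condensation readout.

A consistency note on the printed form of the ratio equation: some published
statements of (ratio)_A carry ε^D evaluated at λ″ in the transfer term while
the inversion to E uses ε^D(λ′), and only ε^D at λ′ is ever tabulated for
this dye pair.  This package uses ε^D(λ′) in both directions, which makes the
forward and inverse maps exact mutual inverses — the property every
downstream statistic (and the simulator contract) relies on.  This is a
deliberate design choice, flagged here rather than silently applied.

## Constants

Two extinction-coefficient sets (cm⁻¹M⁻¹) ship as `H1_PAIR` and `DNA_PAIR`:

| quantity | H1 CTD labels | DNA-end labels |
|---|---|---|
| ε^D(515) (Cy3) | 92 058 | 53 160 |
| ε^A(515) (Cy5) | 6 078 | 3 749 |
| ε^A(610) (Cy5) | 161 103 | 118 400 |
| d⁺ | 0.66 (measured) | 1.0 (site-specific labels) |

d⁺ is a config input; its experimental determination is out of scope.  For
the H1 preparation, labeling both cysteines (G101C, K195C) with a 50/50
Cy3/Cy5 maleimide mix predicts d⁺ = 2/3 by enumeration of the two-site
outcome space (`mixture_from_site_probabilities`), numerically consistent
with the measured 0.66.

## Isolating the acceptor emission

How the acceptor component under donor excitation is extracted from a scan
is not fixed by the ratio equations; this package's default is two-component
linear unmixing: the background-subtracted scan is fit as
a_D·(donor reference lineshape) + a_A·(acceptor reference lineshape) by
nonnegativity-constrained least squares (NNLS; unconstrained optional).
Reference lineshapes come from measured donor-only/acceptor-only scans when
the manifest provides them, else from the simulator's parametric bands, which
keeps the real-data and synthetic paths symmetric.  The direct-excitation
scan is fit against the acceptor reference alone (λ″ barely excites Cy3).
Both amplitudes are in units of the same acceptor lineshape, so its
normalization cancels in the ratio.  A simpler mode — integral over a
660–680 nm window after scaled donor-reference subtraction — is provided for
sensitivity checks, not as the default.  Unmixing refuses collinear
references (condition number > 1e8) and a non-positive direct-excitation
amplitude.

## Spectra handling

Scans are two-column CSV (wavelength_nm, intensity_au), comma-separated,
optional single header auto-detected by a non-numeric first token.  Grids
must be strictly increasing; duplicates are rejected with the offending
wavelengths named.  Canonical analysis grids are 530–750 nm (donor
excitation) and 620–750 nm (acceptor excitation) at 1 nm — wide enough to
bracket the Cy3 (~560 nm) and Cy5 (~670 nm) emission peaks while excluding
excitation scatter; the instrument's true scan ranges are not documented, so
these defaults are an assumption, configurable per run.  Interpolation is
always linear and never extrapolates (spectra are smooth and densely
sampled; extrapolation invents signal).  Buffer-blank background subtraction
interpolates the blank onto the sample grid; negative results are kept, not
clipped — clipping would bias the amplitude fits — and counted in the QC
report.

## The synthetic-data generator

The generator emulates the study's measurement conditions: Cy3/Cy5 emission
bands as unit-area parametric lineshapes (default Gaussian, σ 18 nm at
560 nm and σ 20 nm at 670 nm; a red-tailed lognormal is available — the
instrument's true bandwidths are not documented, so these are stated
assumptions), a four-species labeling mixture from the 50/50 two-site
labeling scheme (d⁺ = 2/3), flat buffer background (default 20 a.u.,
~2% of the donor-band peak), and shot-like Gaussian noise with variance
proportional to intensity, parameterized by the relative SD at the scan peak
(default 1%).  Quantum yields and detector response are absorbed into a
single brightness constant, which the ratio method cancels; donor leakage
into the direct-excitation scan is zero by default with an optional leakage
parameter for robustness tests.

Titrations place 3 replicates at nucleosome:H1 ratios
(0.4, 0.6, 0.8, 1.0, 1.1, 1.2) plus free-H1 reference replicates; the bound
fraction at ratio r is min(r/r_sat, 1) (tight stoichiometric binding,
saturating at r_sat = 1), and partially bound points are population mixtures
of free and bound spectra — ensemble spectroscopy is linear in species
concentrations, so the ensemble efficiency is the bound-fraction-weighted
mean.  Condition presets use plateau ΔE 0.40 (wild-type H3), 0.18 (tailless
H3) and 0.28 (six-lysine acetylation mimic), with free-H1 reference
efficiency 0.15.  All randomness flows from one integer seed; repeated runs
are byte-identical.

What the generator does **not** emulate: photobleaching, inner-filter
effects, anisotropy, instrument drift, donor spectral shifts on binding, or
distance distributions within the CTD ensemble.  Passing recovery tests
therefore demonstrate the correctness of the analysis chain under the ratio
method's own assumptions, not robustness to violations of those assumptions
in real measurements.

## Distance conversion

E = 1/(1 + (r/R₀)⁶) under the single-fixed-distance assumption, with
default R₀ = 6.0 nm for Cy3/Cy5.  The R₀ actually underlying any given
published distance is rarely stated, so the package always echoes the R₀ it
used into its outputs, flags distances outside [0.5·R₀, 2·R₀] where the
sixth-power law loses resolution, and reports values as average
inter-fluorophore distances under that idealization — no orientation-factor
(κ²) modelling, no distance-distribution deconvolution.  Exact reproduction
of any particular published distance value is possible only given the same
R₀.

## Statistics

Per-ratio summaries report mean and sample SD (n−1); single-replicate
points get SD = missing plus a QC flag, and comparisons with n < 3 are
flagged.  Conditions are compared with a two-tailed Student's t-test —
pooled-variance by default, matching the assay's stated convention, with
Welch as an option since the two can disagree in star code.  Stars use
strict thresholds: *** p<0.001, ** p<0.01, * p<0.05, else NS (p = 0.05
exactly is NS).  No multiple-testing correction is applied by default (raw
per-comparison p values are the convention for this assay); Holm adjustment
is available.  Two zero-variance groups with equal means give p = 1 by
convention.

Saturation is detected as the smallest titration ratio from which every
successive pair of per-ratio mean ΔE values differs by less than
`flatness_tol` (default 0.1, a choice — the underlying criterion is
qualitative) times the plateau mean, requiring a plateau of at least two
ratios; otherwise "no plateau".  The default condition contrast pools
replicates across the saturated ratios (1.0, 1.1, 1.2 under the default
design) before testing, mirroring the aggregate analysis this assay uses;
at saturation all pooled draws share one true ΔE, so pooling is exact.
With 3 replicates per ratio this gives n = 9 per group — the power to
detect the wild-type versus tailless-H3 effect (ΔE 0.40 vs 0.18, replicate
SD 0.03) at α = 0.001 then exceeds 95%, whereas a single-ratio n = 3
comparison has df = 4 and only ~60% power at that α.

## Numerical choices

- NNLS for unmixing; falls back to `numpy.linalg.lstsq` when the
  nonnegativity constraint is disabled.  Noiseless synthetic scans unmix to
  machine precision; the noiseless pipeline recovers E to < 1e-8.
- Scan CSVs are written with shortest round-trip float repr, so
  write-then-read is bit-identical and seeded dataset generation is
  byte-reproducible.
- Efficiencies slightly outside [0, 1] (within ±0.05) are tolerated with a
  QC flag — they arise from noise near the limits; values beyond that are
  flagged unphysical.  Distance conversion requires E strictly inside (0, 1).
- Monte-Carlo studies use `numpy` seed sequences spawned from one master
  seed, so every reported number is reproducible from the seed alone.

## Problem sizes

The shipped studies use scan grids of 221/131 points, 3 replicates per
titration point, 100 Monte-Carlo replicates per efficiency-grid cell, 500
runs for power and 2000 for type-I calibration — sizes chosen so the full
analysis and test suite run in seconds on a laptop while keeping Monte-Carlo
standard errors well below the decision thresholds they feed.

## Known limitations

- The ratio method yields one ensemble-averaged E; heterogeneous bound
  states or partial binding away from the plateau appear only as shifted
  averages.
- Reported distances inherit all Förster-law idealizations (κ² = 2/3
  implicit in R₀, single fixed distance).
- The saturation detector assumes a monotone approach to a plateau; non-
  monotone titrations (e.g. aggregation at high ratios) will confuse it.
- d⁺ enters E directly; an inaccurate d⁺ biases absolute efficiencies,
  which is precisely why ΔE is the primary readout.
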