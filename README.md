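# h1fret

Ensemble FRET analysis of linker histone H1 C-terminal domain (CTD)
condensation and linker-DNA geometry in nucleosomes, built around the
acceptor-normalized **(ratio)_A** method.

The H1 CTD is intrinsically disordered in solution and condenses when H1
binds a nucleosome.  With Cy3/Cy5 at the CTD termini (or at the two
linker-DNA ends of a reconstituted nucleosome), condensation is read out as
a rise in FRET efficiency measured on a spectrofluorometer: each sample is
scanned under donor excitation (λ′ = 515 nm) and under direct acceptor
excitation (λ″ = 610 nm), and

    (ratio)_A = (E · ε^D(λ′) · d⁺ + ε^A(λ′)) / ε^A(λ″)
    E         = (ε^A(λ″) · (ratio)_A − ε^A(λ′)) / (ε^D(λ′) · d⁺)
    ΔE        = E_ref · ((ratio)_A,exp − (ratio)_A,ref)
                      / ((ratio)_A,ref − ε^A(λ′)/ε^A(λ″))

where ε are extinction coefficients, d⁺ the donor-labeled fraction of the
acceptor-bearing population, and ΔE — the efficiency change of bound versus
free H1, independent of d⁺ — the primary condensation readout.  Distances
follow the Förster law E = 1/(1 + (r/R₀)⁶).

The package is aimed at anyone running ensemble FRET titrations of this
kind: it reads fluorometer scan CSVs grouped by a JSON manifest,
background-subtracts against buffer blanks, isolates the acceptor emission
by spectral unmixing, computes (ratio)_A / E / ΔE per sample, detects
titration saturation, compares conditions with replicate t-tests, and
converts efficiencies to distances.  A seedable synthetic-scan generator
with known ground truth makes every stage testable end to end; no measured
spectra ship with the package.  See `docs/methods.md` for the model,
assumptions and numerical choices.

## Worked example

Simulate a noiseless wild-type titration and analyze it:

```sh
h1fret simulate --condition WT --noise 0 --seed 4 --out demo_data
h1fret analyze demo_data/manifest.json --out demo_out
h1fret distance -e 0.5 --r0 6.0
```

`demo_out/titration_summary.tsv` then contains

```
condition  ratio  n  mean  sd   qc
WT         0.4    3  0.16  0.0
WT         0.6    3  0.24  0.0
WT         0.8    3  0.32  0.0
WT         1.0    3  0.40  0.0
WT         1.1    3  0.40  0.0
WT         1.2    3  0.40  0.0
```

ΔE climbs linearly while nucleosomes are limiting and plateaus at 0.40 from
a nucleosome:H1 ratio of 1.0 — binding saturation; `qc.json` records
`"saturation_ratio": 1.0, "plateau_delta_E": 0.4` and the reference
efficiency 0.15 the ΔE values are anchored to.  The `distance` call prints
`{"E": 0.5, "distance_nm": 6.0, ...}`: at the Förster radius, transfer is
half-efficient.

The numbered scripts under `analysis/` run the package's full study on
synthetic data — `01` simulates three nucleosome conditions (wild-type H3,
tailless H3, an acetylation-mimic H3; plateau ΔE 0.40 / 0.18 / 0.28 with 1%
shot noise), `02` recovers those plateaus by the full analysis chain, `03`
tests each condition against wild type on replicates pooled over the
saturated ratios, `04` recovers linker-DNA end-to-end distances
(6.04 / 6.63 / 4.56 nm geometries) from DNA-end-labeled simulations, and
`05` reports estimator bias/RMSE, test power and type-I calibration.
Outputs land in `results/`.

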