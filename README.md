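# rodfold

Quantitative analysis toolkit for elongated tandem-repeat surface
proteins, built around the SasG G5/E repeat system of *Staphylococcus
aureus*: a monomeric protein that is simultaneously long (tens of nm)
and mechanically strong, without covalent cross-links.

The package implements the four bespoke analysis pipelines such a study
needs, each paired with a seeded synthetic-data generator so every
pipeline can be validated end-to-end against known ground truth:

1. **SHRImP localization** (`rodfold.shrimp`, `rodfold.steps`,
   `rodfold.psf`): two fluorophores closer than the diffraction limit
   are resolved by stepwise photobleaching. Intensity traces are
   smoothed with an edge-preserving Chung–Kennedy filter, the two
   bleach steps are found by robust derivative thresholding, and the
   surviving fluorophore (mean image *I₂* of the 7 frames after the
   first step) and the bleached one (difference *I₁ − I₂*) are each
   localized by least-squares fitting of a pixel-integrated rotated 2D
   Gaussian `A·exp(−(a·Δx² + 2b·ΔxΔy + c·Δy²)) + B`. Spot-shape QC
   uses the eccentricity `e = √(1 − (σmin/σmax)²)`.
2. **AFM force spectroscopy** (`rodfold.afm`, `rodfold.wlc`): sawtooth
   peaks in constant-velocity force–extension traces are detected,
   each rising edge is fitted with the Marko–Siggia worm-like chain
   `F = (kBT/p)·[1/(4(1−x/Lc)²) − 1/4 + x/Lc]` with the persistence
   length fixed at 0.4 nm, and contour-length increments
   ΔLc = Lc(i+1) − Lc(i) classify each event as an E-domain
   (~145 Å) or G5-domain (~216 Å) unfolding. Modal forces and ΔLc come
   from Gaussian fits to pooled histograms; the mode-force-vs-ln(speed)
   slope gives the Bell–Evans transition-state distance kBT/xu.
3. **Folding thermodynamics** (`rodfold.thermo`): two-state urea
   denaturation fits (`Y = [(αN+βN·D) + (αD+βD·D)·K]/(1+K)` with
   `K = exp(m(D−D₅₀)/RT)`, so ΔG = m·D₅₀), chevron fits (two-state and
   sequential transition-state), ΔΔG comparisons, and an interface
   free-energy ledger with explicit bound propagation that attributes
   multi-domain stability to domain terms plus inter-domain interface
   terms.
4. **Shape models** (`rodfold.shape`): coarse bead-chain models of the
   multi-domain rod with per-junction flexing, and the model-level
   solution-scattering observables P(r), Dmax, cross-sectional
   distance distribution, Debye I(s), Guinier Rg, cross-sectional Rc
   and Porod exponent.

`rodfold.simulate` provides the generators (TIRF movies with Poisson
photon and camera noise, quasi-static Bell/WLC force traces,
denaturation curves, chevron tables), all seeded and returning
ground-truth tables. `rodfold.reference` holds the published parameter
sets used as generator truth.

## Worked example

Simulate a photobleaching movie of one doubly-labelled 13-domain
molecule and measure its end-to-end distance:

```python
import numpy as np
from rodfold.simulate import TIRFSimConfig, simulate_tirf_movie
from rodfold.shrimp import analyze_movie, LocalizationPair

dists = []
for seed in range(1, 101):
    stack, truth = simulate_tirf_movie(TIRFSimConfig(separation=59.0,
                                                     seed=seed))
    for res in analyze_movie(stack):
        if isinstance(res, LocalizationPair) and res.passed_qc:
            dists.append(res.distance)
print(f"{len(dists)} accepted pairs, "
      f"mean = {np.mean(dists):.1f} nm, sd = {np.std(dists):.1f} nm")
```

which prints

```
56 accepted pairs, mean = 57.2 nm, sd = 4.0 nm
```

— about half the movies survive the two-clean-steps and spot-shape QC,
and the recovered mean distance sits within the localization scatter of
the 59 nm ground truth, the same end-to-end distance measured for the
real 13-domain construct. The equivalent shell command is
`rodfold simulate-tirf` followed by `rodfold shrimp`.

The same closure runs for every pipeline via the umbrella CLI:

```sh
rodfold reproduce --seed 7 --fast --out report.md
```

which regenerates synthetic data with the published equilibrium, AFM
and imaging parameters as truth, re-analyzes them, and writes a table
of recovered vs published values (m, D₅₀, modal ΔLc and forces, SHRImP
distance).

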