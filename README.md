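# maraq — metal-artifact quantification for CT

`maraq` implements a semi-automated, threshold-based method for quantifying
metal artifacts in CT volumes, aimed at comparing acquisition protocols —
in particular photon-counting detector CT (PCD-CT) with high-energy
thresholding against conventional energy-integrating detector CT (EID-CT)
— around a hip prosthesis. Because such phantom scans are rarely shared,
the package includes a synthetic hip-prosthesis phantom generator that
produces co-registered CT series with known ground-truth artifact masks, so
every stage of the measurement chain can be validated end to end.

## Method

For each material *m* (cortical bone, bone marrow, water) an artifact-free
reference region yields mean CT number μ_m and standard deviation σ_m. The
normal range of the material is the closed interval

    [μ_m − k·σ_m, μ_m + k·σ_m],   k = 3 by default,

which covers 99.7% of normally distributed artifact-free voxels. Every
voxel of a volume of interest (VOI) around the prosthesis whose CT number
falls strictly outside this range counts as metal artifact; the raw
artifact percentage is 100·|artifact ∩ VOI| / |VOI|. Since the rule
misclassifies ≈ 2·Φ(−3) ≈ 0.3% of perfectly normal voxels (more when the
thresholds come from a different acquisition than the one being measured),
a per-series, per-material **correction factor** — the out-of-range
percentage of that series' own artifact-free reference under the applied
thresholds — is subtracted, floored at zero:

    corrected % = max(raw % − correction %, 0).

Image **noise** is the SD of CT numbers in a water bath scanned without the
phantom. **CNR** of a tissue against the water bath with the phantom present
is |μ_t − μ_w| / √((σ_t² + σ_w²)/2).

The simulator paints a tapered metal stem inside a foam femur model
(cortical shell + marrow core) in a 13 × 22 cm water bath, injects analytic
streak artifacts (alternating hyper-/hypo-dense angular rays, amplitude
falling as 1/(1 + d/d₀) with distance d from the stem) and adds Gaussian
noise at per-protocol magnitudes; Chess-mode series default to √2 × the
Macro-mode noise, reflecting each Chess threshold setting using only half
of the detector subpixels.

## Worked example

```python
from maraq.io import SeriesConfig, StudyConfig
from maraq.pipeline import run_study

config = StudyConfig(
    series=[SeriesConfig(id="eid140", protocol="EID-CT 140"),
            SeriesConfig(id="macro140_75", protocol="Macro-HTI 140/75")],
    phantom={"voxel_spacing_mm": [4.0, 1.5, 1.5]},
    artifacts={"amplitude_hu": 600.0, "truth_cutoff_hu": 150.0,
               "decay_mm": 20.0},
    seed=11,
)
result = run_study(config)
print(result.artifacts[["series", "material", "raw_percent",
                        "correction_percent", "corrected_percent"]].round(2))
```

prints

```
        series       material  raw_percent  correction_percent  corrected_percent
0       eid140  cortical_bone        38.44                0.12              38.32
1       eid140    bone_marrow        26.89                0.30              26.59
2       eid140          water        18.27                0.29              17.97
3  macro140_75  cortical_bone        53.77               36.32              17.45
4  macro140_75    bone_marrow        32.99                9.32              23.67
5  macro140_75          water        21.92                6.45              15.47
```

Both series carry the same injected streaks. The EID series is measured
against its own thresholds, so its correction factor is just the Gaussian
0.3% floor (0.12–0.30%). The PCD series is measured against the EID-derived
thresholds — as the method prescribes, thresholds per tube potential come
from the conventional acquisition — and because energy thresholding shifts
its material means and raises its noise, a third of its cortical-bone VOI
is "out of range" for reasons that have nothing to do with streaks. The
correction factor, computed on the PCD series' own artifact-free reference,
absorbs exactly that (36.32%), leaving corrected percentages driven by the
actual artifacts. `result.noise` reports 32.9 HU (EID) vs 55.1 HU (Macro
HTI), and `result.cnr` the per-series contrast-to-noise ratios.

The numbered scripts under `analysis/` run the full study: `01` reproduces
the published CNR table from the published material statistics, `02`
simulates and quantifies all twelve protocols, `03` calibrates the ±3SD
misclassification rate, `04` checks the √2 Macro/Chess noise law, and `05`
demonstrates ground-truth recovery and the distance decay of artifacts.

A CLI wraps the same pipeline: `maraq run --config study.yaml --out DIR
[--seed N]`, with `simulate`, `segment`, `quantify` and `report`
subcommands writing NIfTI volumes/masks and CSV/JSON tables.

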