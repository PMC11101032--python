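# mwibreast

Anatomically realistic numerical breast models for microwave imaging (MWI)
research, built from co-registered Dixon-style breast MRI channels — or from
a built-in synthetic phantom generator — and turned into frequency-resolved
dielectric property maps.

MWI systems for breast-cancer screening are designed and validated against
numerical models whose voxels carry the relative permittivity εr and
effective conductivity σeff of breast tissues at microwave frequencies.
This package implements the full model-construction chain for prone breast
MRI exams:

1. **Pre-processing** — N4 bias-field correction, min-max intensity
   normalization, 3×3×3 median filtering (skipped for exams with
   infra-centimetric lesions so sub-centimeter tumors keep their shape).
2. **Anatomy segmentation** — sternum-seed estimation on the water-only (W)
   channel; running-mean region growing on the fat-only (F) channel to
   separate breast fat from thoracic fat; radius-3 ball dilation and
   anterior column fill to obtain the breast region; skin and muscle shell
   extraction; a two-component Gaussian mixture on the in-phase (I) channel
   to split fat from fibroglandular tissue, each subdivided into
   low/median/high intensity tertiles plus a transition class.
3. **Tumor segmentation** — running-mean region growing on the
   contrast-enhanced subtraction channel plus Hoshen–Kopelman union-find
   cluster labeling; per-tumor records with equivalent diameter, laterality
   and relative size classes (XS/S/M/L/XL among same-kind tumors).
4. **Dielectric assignment** — per-tissue dispersion curves evaluated at
   any frequency on the 3–10 GHz grid (0.01 GHz step), mapped voxelwise by
   water-channel intensity.

## Label vocabularies

Two label-map dialects are emitted per exam:

| label | simple | detailed |
|------:|--------|----------|
| -4 | benign tumor | benign tumor |
| -3 | malignant tumor | malignant tumor |
| -2 | skin | skin |
| -1 | muscle | muscle |
| 0 | background | background |
| 1 | fat + fibroglandular | fibroglandular low |
| 2 | — | fibroglandular median |
| 3 | — | fibroglandular high |
| 4 | — | transition |
| 5 | — | fat low |
| 6 | — | fat median |
| 7 | — | fat high |

## Dispersion models

Normal tissues follow single-pole Debye dispersions; with ω = 2πf,

    εr(ω)   = ε∞ + Δε / (1 + ω²τ²)
    σeff(ω) = σs + ε0 Δε ω² τ / (1 + ω²τ²)

Malignant tumors use a 1-pole Cole–Cole dispersion
ε\*(ω) = ε∞ + Δε/(1 + (jωτ)^(1−α)) + σs/(jωε0), converted to a
band-limited Debye equivalent by least squares over the 3–10 GHz grid.
Skin and muscle carry ±5% heterogeneity bands around their nominal curves;
fat/fibroglandular subclasses span envelopes built from the adjacent
subclass curves; benign tumors span the fibroglandular envelope.  Within
each tissue, voxels are mapped linearly between the lower and upper
envelope by their water-channel intensity (brighter W = more water = higher
permittivity and conductivity).  The parameter table ships as an editable
CSV (`src/mwibreast/data/tissue_dielectrics.csv`).

## Worked example

Generate a synthetic exam that mirrors a clinical scenario — one malignant
and one benign tumor in the left breast, a healthy right breast — and build
its 6 GHz property maps:

```sh
$ mwibreast phantom --preset exam4_like --seed 1 --outdir Exam04
phantom exam written to Exam04 (seed 1)

$ mwibreast assign --exam Exam04 --freq 6 --save --timestamp 20240101_120000
frequency 6 GHz | permittivity [1.000, 50.886] | conductivity [0.0000, 6.3753] S/m
saved Exam04/SavedFiles/Permittivity_Matrix_6_20240101_120000.mha / .mat
saved Exam04/SavedFiles/Conductivity_Matrix_6_20240101_120000.mha / .mat
```

The printed ranges are physical end points of the 6 GHz maps: background
air is free space (εr = 1, σ = 0) and the malignant-tumor curve tops out
near εr ≈ 51 and σeff ≈ 6.4 S/m at this frequency.  The exam folder holds
the pre-processed water-only channel (`T1w_Dixon_W.mha`), both label-map
dialects, the raw channels under `channels/`, and per-tumor ground truth
(`tumors_truth.csv`).  Maps are saved under `SavedFiles` in both MHA and
MATLAB formats, named
`Permittivity_Matrix_<freq>_<date>_<time>` /
`Conductivity_Matrix_<freq>_<date>_<time>`; omit `--timestamp` to stamp the
current UTC time.  Off-grid frequencies exit with code 2 and a message
listing the nearest valid values.

Segmentation runs on the raw channels of any exam folder:

```sh
mwibreast segment --exam Exam04
```

The same operations are importable as a library
(`mwibreast.generate_phantom`, `mwibreast.segment_exam`,
`mwibreast.generate_property_maps`, ...).

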