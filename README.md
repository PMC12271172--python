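# nanoorg

Nanoscale organization analysis of inhibitory synapses after chronic
benzodiazepine exposure: a Python pipeline for two-channel single-molecule
localization microscopy (DNA-PAINT) of the GABA_A receptor γ2 subunit and
its scaffold gephyrin, with the accompanying fixed-imaging mask logic, FRAP
normalization, synthetic ground-truth generators, and group statistics.

## Who this is for

Labs quantifying inhibitory-synapse architecture from localization
microscopy: each DNA-PAINT binding event yields one localization
`(frame, x, y, photons, precision)` in nm. The pipeline turns two such
channels plus a presynaptic VGAT snapshot into per-synapse measurements —
areas, localization densities, subsynaptic domains (SSDs), cross-channel
enrichment — and compares treatment groups (vehicle vs chronic diazepam)
under a normality-gated testing policy.

## The core quantities

* **Re-blink linking** — localizations persisting over consecutive frames
  within a search radius are merged (photon-weighted mean position, photons
  summed).
* **Synapse selection** — scaffold-channel density clusters that overlap the
  receptor channel and the VGAT mask, with circle-equivalent diameter in
  100–800 nm; imported hand-drawn polygons are equally supported.
* **DBSCAN denoising** — γ2: ε = 40 nm, minPts = 5; gephyrin: ε = 30 nm,
  minPts = 5 (deterministic border-point assignment).
* **Areas** — alpha-shape (α = 150 nm) area `A`; circle-equivalent diameter
  `d = 2·√(A/π)`.
* **SSD detection** — per-localization local density (r = 30 nm) thresholded
  against randomized (CSR) re-placements of the same points inside the
  synapse shape; supra-threshold points grouped by DBSCAN; each group of ≥ 5
  becomes an SSD with its own alpha-shape area and density peak.
* **Enrichment index** — mean local density of protein *a* within 60 nm of
  protein *b*'s SSD peaks divided by the uniform expectation `N_a/A`
  (= 1 under CSR, > 1 when co-organized).
* **Masks (IF/PLA)** — synaptic = receptor ∧ marker; extrasynaptic =
  receptor ∧ ¬dilate(synaptic); a PLA spot is synaptic iff any of its pixels
  touches the marker.
* **FRAP** — recovery `(F_t − F_0)/(F_i − F_0)` with `F_i` the mean
  pre-bleach intensity, `F_0` the post-bleach intensity.
* **Statistics** — per-culture vehicle normalization (vehicle mean ≡ 100),
  four-test normality gate (D'Agostino–Pearson, Anderson–Darling,
  Shapiro–Wilk, Lilliefors-KS) choosing unpaired t vs Mann-Whitney,
  iterated two-sided Grubbs outlier removal (α = 0.05).

## Worked example

The repository is organized as an analysis project: the library lives in
`src/nanoorg/`, and numbered drivers under `analysis/` run the study on
synthetic fields generated at the published group means:

```sh
python analysis/01_simulate_fields.py     # vehicle + DZP fields, truth.json
python analysis/02_localization_pipeline.py
python analysis/03_group_comparison.py
python analysis/04_masks_and_pla.py
python analysis/05_frap_recovery.py
python analysis/06_calibration.py
```

`02_localization_pipeline.py` prints, per group and channel, the recovered
means next to the planted truth (areas ×10³ nm², densities ×10⁻³/nm²):

```
vehicle gephyrin:  60 synapses | area  117.5 (truth  125.2) x10^3 nm^2 | density 4.21 x10^-3 /nm^2 | diameter   383 nm | 2.18 SSDs/synapse | enrichment 1.07
vehicle gamma2  :  60 synapses | area   44.3 (truth   46.6) x10^3 nm^2 | density 4.58 x10^-3 /nm^2 | diameter   235 nm | 1.47 SSDs/synapse | enrichment 0.50
dzp     gephyrin:  60 synapses | area   92.6 (truth  100.4) x10^3 nm^2 | density 4.29 x10^-3 /nm^2 | diameter   339 nm | 2.22 SSDs/synapse | enrichment 1.11
dzp     gamma2  :  60 synapses | area   35.6 (truth   34.9) x10^3 nm^2 | density 6.43 x10^-3 /nm^2 | diameter   209 nm | 1.42 SSDs/synapse | enrichment 0.56
```

Reading it: chronic-DZP synapses are smaller in both channels while the γ2
localization density rises — the group contrasts the generator plants and
the statistics in `03_group_comparison.py` then test (total synapse area
differs at p < 10⁻⁴ in both channels; γ2 density at p ≪ 0.001).

The same steps are available as a CLI for real data, e.g.

```sh
nanoorg link --radius 30 --max-gap 0 locs.csv linked.csv
nanoorg align --model affine ref_beads.csv mov_beads.csv -o transform.json
nanoorg ssd --vgat vgat.png --seed 7 receptor.csv scaffold.csv -o metrics.csv
nanoorg compare metrics.csv --variable total_area -o report.csv
```

## Layout

```
src/nanoorg/        library (locio, roi_select, nanoscale, region_masks,
                    frap, synth, stats_report, pipeline, calibration, cli)
analysis/           numbered study drivers (write results/)
tests/              pytest suite incl. brute-force oracle checks
scripts/            acceptance.py reproduction script
docs/methods.md     model, parameters, design choices, limitations
```
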