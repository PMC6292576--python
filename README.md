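# ovotrace

Phenomics from time-lapse embryo video.

`ovotrace` turns dark-field video-microscopy recordings of developing
aquatic embryos — a bright embryo inside a bright-ringed egg capsule on a
dark background, recorded as repeated short image sequences over hours to
weeks — into quantitative developmental phenotypes:

* **morphology**: per-frame embryo segmentation (area, perimeter,
  centroid, solidity) and per-embryo growth rates;
* **behaviour**: within-recording centroid movement and cumulative
  movement through development;
* **spectral proxy traits**: mean pixel intensity of multiresolution
  block grids (1x1 ... 16x16 over the egg ROI) turned into Welch power
  spectra and frequency-band energies — "total energy" summarises an
  embryo's overall activity without needing any explicit behavioural
  classifier;
* **physiology**: cardiac rate per recording, identified from block
  spectra within a physiological band, and a fitted cardiac ontogeny
  model per embryo — linear, or segmented (continuous piecewise-linear
  with one estimated breakpoint) for hearts whose rate rises then
  plateaus:

  f(t) = b0 + b1·(t − t_b) + b2·max(0, t − t_b),

  with breakpoint t_b chosen by exhaustive search over observed
  timepoints minimising residual sum of squares;
* **lethal end points**: time-to-death per embryo from stage-appropriate
  signatures — an osmotic-failure area spike (rapid swell then shrink)
  for early stages, a sustained collapse of in-band spectral energy for
  stages with heartbeats — and cohort survival curves with LT25/50/75
  percentiles.

A fully seeded synthetic generator renders embryo recordings with known
ground truth for every quantity (analytic areas, centroid paths,
instantaneous cardiac frequency, death times), so the entire measurement
chain is testable end to end. It is intended for researchers running
video-microscope phenotyping rigs who need a tested, scriptable analysis
stack rather than a GUI.

## Worked example

Generate one snail-like recording (600 frames at 20 fps, heart pulsing
at 1.5 Hz), locate the egg, segment the embryo and identify the cardiac
frequency:

```python
import ovotrace as ot

spec = ot.SyntheticSpec(seed=1)          # 600 frames @ 20 fps, heart 1.5 Hz
seq, truth = ot.generate_sequence(spec, timepoint=0)

roi = ot.locate_egg(seq)
fm = ot.segment_embryo(seq.frames[0], roi)
est = ot.estimate_sequence_heart_rate(seq, band=(0.5, 5.0))
```

which prints, via the obvious f-strings:

```
egg ROI: centre=(80.0, 80.0), semi-axes=(57.6, 50.3) px
embryo area: 1354 px^2 (generator truth 1357)
cardiac frequency: 1.484 Hz (truth 1.500, quality 1.00)
```

The ROI recovers the rendered capsule (centre (80, 80), semi-axes
(55, 48) px before the 5% safety inflation); the contour area is within
0.3% of the analytic ellipse area; and the cardiac estimate sits on the
Welch frequency bin nearest 1.5 Hz (bin width 20/256 ≈ 0.078 Hz — a
frequency-domain method cannot resolve finer than its bin).

## Command line

The same workflow as a batch tool:

```bash
ovotrace init experiment.yaml                 # write a config template
ovotrace simulate --preset radix --n-embryos 6 --seed 1 --out data/
ovotrace quantify experiment.yaml data/ results/
ovotrace heart-rates results/ --model segmented --out rates.csv
ovotrace endpoints results/ --stage E3 --out deaths.csv
ovotrace report results/ --out reports/
```

`quantify` writes one HDF5 dataset per embryo (groups /traits, /spectra,
/cardiac, /endpoints), a per-embryo summary CSV and a run manifest; its
exit code is 0 when every embryo analysed, 3 on partial success, 1 when
nothing could be analysed, so schedulers can branch. One failed embryo
never aborts a batch.

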