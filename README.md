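# axmwi — UWB radar microwave imaging of axillary lymph nodes

Breast-cancer staging needs a non-invasive way to tell whether axillary
lymph nodes (ALNs, the bean-shaped nodes in the armpit) have been
metastasised. Radar microwave imaging (MWI) is a candidate: an ultra-wide-band
pulse illuminates the axilla from an array of on-skin antennas, and the
dielectric contrast between healthy tissue and (especially metastasised)
nodes produces backscatter that can be focused into an energy image.

`axmwi` is an end-to-end *simulated* MWI test bench for this problem:

* **Phantoms** — 2D numerical models of the axillary region: a 2-mm skin
  layer (uniform or sinusoidally undulating), optional subcutaneous adipose
  and muscle bands, 5 % dielectric heterogeneity on 4-mm tiles, and
  bean-shaped ALNs (12 mm long axis) with distinct surface/cross-section
  single-pole Debye parameters.
* **Forward solver** — dispersive 2D FDTD (TMz) with an
  auxiliary-differential-equation Debye update and convolutional-PML
  boundaries; 16 antennas on the skin, spread over 80 mm, acquired
  monostatically with a 150 ps differentiated-Gaussian pulse centred at
  7.5 GHz.
* **Artifact removal** — the dominant skin response is suppressed either by
  across-channel average subtraction or by per-channel adaptive (FIR
  least-squares) filtering of the other channels.
* **Beamformers** — Delay-And-Sum (DAS), Delay-Multiply-And-Sum (DMAS) and
  their channel-ranked variants (CR-DAS, CR-DMAS) that weight channels by
  the rank of their propagation distance:

  DAS: I(p) = Σ_t [ Σ_m w_m s_m(t + τ_m(p)) ]²,  τ_m(p) = 2‖r_p − r_m‖/v

  DMAS: I(p) = Σ_t [ Σ_{i<j} ŝ_i(t) ŝ_j(t) ]²,  ŝ_m(t) = w_m s_m(t + τ_m(p))

* **Metrics** — signal-to-clutter (SCR), signal-to-mean (SMR), max-to-max
  (MMR, metastasised vs healthy), full width at half maximum (FWHM) and
  localization error (LE), plus a two-node distinguishability predicate for
  resolution sweeps.

## Worked example

Run the baseline study — a single metastasised node at 20 mm depth under
uniform skin — through both artifact-removal methods and all four
beamformers:

```python
from axmwi import built_in_scenarios, range_calibration, run_scenario

cal = range_calibration()                      # point-reflector range calibration
sc = built_in_scenarios()[0]                   # "single_uniform_skin"
table, maps = run_scenario(sc, time_reference=cal)
print(table.round(2).to_string(index=False))
```

which prints (abridged):

```
           scenario artifact beamformer  ... scr_db  smr_db  le_mm  fwhm_mm
single_uniform_skin  average        DAS  ...   1.09   14.61   0.35    12.33
single_uniform_skin  average       DMAS  ...   2.67   22.65   0.35     8.05
single_uniform_skin  average    CR-DMAS  ...   3.34   24.54   0.35     6.73
single_uniform_skin adaptive       DMAS  ...   3.39   23.24   0.35     6.35
single_uniform_skin adaptive    CR-DMAS  ...   3.22   25.29   0.35     6.36
```

The node is localized to within one 0.5-mm pixel (LE 0.35 mm), the
pair-product beamformers roughly double the background suppression (SMR
~23–25 dB vs ~15 dB for DAS), and the apparent node width (FWHM 6–12 mm)
stays within the 12-mm node size. `maps[("adaptive", "CR-DMAS")]` holds the
energy image; `axmwi.io.render_map_png` writes it as a figure with the
ground-truth centre overlaid.

The same pipeline is scriptable from the shell:

```bash
axmwi scenario --name single_uniform_skin --outdir out
axmwi sweep --separations 15,11,9,7,5,3 --outdir out
```

## Layout

```
src/axmwi/tissues.py     Debye tissue library and permittivity model
src/axmwi/pulse.py       differentiated-Gaussian excitation
src/axmwi/phantom.py     phantom geometry, bean masks, heterogeneity
src/axmwi/fdtd.py        dispersive FDTD solver, monostatic acquisition
src/axmwi/artifact.py    skin-artifact removal (average / adaptive)
src/axmwi/beamform.py    DAS / DMAS / CR-DAS / CR-DMAS
src/axmwi/metrics.py     SCR, SMR, MMR, FWHM, LE, peak finding
src/axmwi/scenarios.py   built-in studies, resolution sweep, calibration
src/axmwi/io.py, cli.py  persistence (HDF5/CSV/YAML/PNG) and the CLI
docs/methods.md          modelling assumptions and numerical choices
```
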