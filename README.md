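# flimchip

Optical metabolic imaging (OMI) and viability analysis for
tumor-on-a-chip nutrient-gradient experiments — with a synthetic-data
generator that makes the entire pipeline testable against known ground
truth.

## The problem

A microfluidic chamber holds tumor cells in a 3D hydrogel with a
medium-perfused lumen along one side. Nutrients reach cells only by
diffusion from that lumen, so seeding density controls whether cells far
from the lumen thrive, turn quiescent, or die: at high density a
necrotic core forms at the distal wall. Two imaging readouts probe this
gradient:

- **FLIM/OMI** — two-photon autofluorescence of NAD(P)H and FAD.
  Per-pixel TCSPC histograms are fit to a bi-exponential decay
  `I(t) = IRF ⊛ (α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂)) + C`, giving the
  amplitude-weighted mean lifetime `τₘ = α₁τ₁ + α₂τ₂` and intensity
  images whose per-pixel ratio NAD(P)H/FAD is the **optical redox
  ratio**, a label-free metabolic readout. Per-cell values are averaged
  over the cytoplasm (cell minus nucleus, from nuclei-seeded
  segmentation) and normalized to the untreated control at the same
  chamber position (proximal vs distal, distal = 10 mm from the lumen).
- **Live/dead staining** — calcein-AM (green, live) and propidium
  iodide (red, dead) images, quantified as per-region percent live,
  axis intensity profiles, and the necrotic-core extent (the contiguous
  dead-dominated stretch ending at the distal wall).

Metabolic inhibitors (2DG for glycolysis, etomoxir for fatty-acid
oxidation, oligomycin for ATP synthase) shift these readouts in a
density- and position-dependent way; per-cell metrics are compared with
a Kruskal–Wallis omnibus test followed by Mann–Whitney U tests against
control (two-sided, p < 0.05, stars at 0.05/0.001).

No raw microscopy from such experiments is publicly deposited, so the
package ships a first-class **synthetic scene generator**: cells placed
across a chamber-shaped frame with a logistic live/dead axis gradient,
per-cell true decay parameters with programmed condition effects, TCSPC
stacks rendered through a 244 ps Gaussian IRF with Poisson photon
statistics, and matching two-channel viability images. Every analysis
stage can therefore be scored against programmed truth.

## Worked example

```python
import flimchip as fc

# a high-density glycolysis-inhibition sample paired with its control
cfg = fc.load_fixture("highdensity_2dg")
summary = fc.run_all(cfg, outdir="out/highdensity_2dg")

print(summary["redox_percent_decrease"])
# {'proximal': 39.70, 'distal': 39.46}
print(summary["viability"]["proximal"])
# {'live_percent': 33.3, 'n': 54}
print(summary["stats"]["pairwise"][2])
# {'stratum': 'proximal', 'condition': '2DG', 'n': 70, 'n_ctl': 61,
#  'U': 0.0, 'p': 6.9e-23, 'stars': '***'}
```

The printed numbers say: after fitting ~18 000 per-pixel decays in two
channels for the treated and control scenes, segmenting ~300 cells per
scene and normalizing cytoplasm-averaged redox ratios to the control at
the same position, the pipeline measures a ≈39.5% redox-ratio decrease
in both strata (the generator programmed 40%), 33% of detected objects
in the proximal band alive (programmed 33%), and a decisively
significant treated-vs-control Mann–Whitney comparison in every
stratum.

The same stages are available as a CLI for file-based workflows:

```bash
flimchip simulate --fixture lowdensity_ctl --seed 7 --outdir out/sim
flimchip run-all --fixture highdensity_2dg --seed 7 --outdir out/run
```

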