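# mitodyn

Regional mitochondrial dynamics and bioenergetics analysis for single-cell
fluorescence microscopy and extracellular-flux respirometry.

Mitochondria supply ATP locally, so *where* they sit inside a cell matters:
the nucleus draws its ATP from mitochondria in the narrow perinuclear space,
while the rest of the cell is served by the peripheral population.  This
package quantifies that regional organisation from standard assays:

- **Region partition** — the cytoplasm is split into a *perinuclear* band
  (a 3 µm shell immediately outside the nucleus boundary, found by an exact
  Euclidean distance transform from the segmented nuclear stain) and the
  remaining *peripheral* region.
- **Motility** — mitochondria are detected frame by frame in a time-lapse
  stack (101 frames every 3 s), linked into tracks by mutual-nearest-neighbor
  matching, and summarised by their *net displacement* d (first-to-last-frame
  Euclidean distance).  Displacements are log-normal; the central tendency is
  the geometric mean exp⟨ln d⟩ and the spread the geometric SD exp(σ_ln d),
  reported per region.
- **Membrane potential** — TMRM accumulates with inner-membrane potential
  ΔΨ_m; the readout is mean mitochondrial pixel intensity minus local
  background per region, normalized to the control perinuclear mean.
- **Respirometry** — a four-stage mito stress test (baseline → oligomycin →
  FCCP → rotenone) yields, after background- and non-mitochondrial
  correction, baseline, proton leak, maximal respiration, and the exact
  identities SRC = maximal − baseline and Resp^ATP = baseline − leak.
- **Bioenergetic partition** — the scaled ATP-linked respiration
  R = Resp^ATP / Resp^ATP_control is divided between the regions in
  proportion to the regional weight w = ψ*L · V^mito (linearized potential ×
  mitochondrial volume):

      BC_perinuclear = w_perinuclear · R / (w_perinuclear + w_peripheral)
      BC_peripheral  = w_peripheral  · R / (w_perinuclear + w_peripheral)

  so BC_perinuclear + BC_peripheral = R exactly, and the control condition
  totals 1.

A synthetic-data generator produces image stacks, TMRM scenes and plate
traces with *exact* ground truth (net displacements are imposed at the track
level through a constrained Brownian bridge), which is how every stage of
the pipeline is validated.

## Worked example

Simulate a motility epoch and analyze it end to end:

```python
import numpy as np
from mitodyn import (SyntheticCellSpec, generate_cell, simulate_tracks,
                     render_stack, analyze_stack)

spec = SyntheticCellSpec(seed=3)          # 200 mitochondria, 101 frames @ 3 s
geo = generate_cell(spec)
tracks, truth = simulate_tracks(spec, geo)
stack = render_stack(tracks, geo, orientations=truth.orientations)

res = analyze_stack(stack, geo.masks, frame_interval=spec.frame_interval)
print(f"geometric mean {res.overall.geometric_mean:.1f} nm "
      f"(truth {np.exp(np.log(truth.net_displacements).mean()):.1f} nm), "
      f"n={res.overall.n} tracks, "
      f"perinuclear volume fraction {res.volumes.fraction_perinuclear:.2f}")
```

which prints

```
geometric mean 77.6 nm (truth 78.7 nm), n=145 tracks, perinuclear volume fraction 0.25
```

i.e. the tracker recovers the epoch's true geometric-mean displacement
within ~1.5% from 145 full-epoch tracks, and about a quarter of resolvable
mitochondrial volume lies in the perinuclear band (30% of mitochondria were
seeded there; in the crowded band some touching neighbors are excluded as
unresolved clusters — see `docs/methods.md`).

The same workflow is available from the shell:

```
mitodyn simulate --preset dynamics --seed 3 --out sim/
mitodyn analyze-dynamics --stack sim/stack.tif --nucleus sim/nucleus.tif \
        --pixel-size 162.5 --out results/
mitodyn simulate --preset plate --seed 1 --out plate/
mitodyn analyze-respiration --plate plate/plate.csv --out resp.json
```

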