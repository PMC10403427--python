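# emflowreg

Registration of serial-section electron microscopy (ssEM) stacks with
feature-driven dense optical flow, cumulative-error compensation
("structural regression"), and a split strategy for long series — plus a
synthetic phantom/deformation generator and evaluation metrics so the whole
pipeline is testable without any external data.

## Who this is for

Connectomics and volume-EM practitioners who need to restore axial
continuity in a stack of 2-D sections (multipage TIFF, numbered image
sequence, or an HDF5 volume) before 3-D reconstruction, and tool builders
who want the individual stages — warping, pairwise flow, rigid SIFT+RANSAC
anchoring, error compensation, Dice/NCC evaluation — as a library.

## The method

Sequential pairwise registration aligns each section to its already-warped
predecessor: F_{i→i−1} = E(s_i, ws_{i−1}), ws_i = φ_F(s_i). Two problems
follow. Pixel-similarity data terms erase genuine morphological change
between sections (overregistration), so the photometric loss here is
measured between per-pixel *descriptors*,

    L_ph = ‖feat(s_{i−1}) − feat(φ_F(s_i))‖²,

with smoothness and augmentation-consistency regularizers. And each
pairwise step leaves a residual Δe_i that accumulates, e_i = Σ_{j≤i} Δe_j,
bending neurites over the series. Because a neurite over a short span is
approximately a cylinder, the residuals share a direction; anchoring the
first and last sections rigidly makes the *total* accumulated error visible
as the flow F_{n−1→n} between the last two warped sections. Structural
regression removes a per-section fraction of that error flow,

    w_i = (Σ_{j≤i} d_j) / (Σ_{j≤n} d_j),   d_i = ‖feat(ws_i) − feat(ws_{i−1})‖₂,  d_1 = 0,

warping each interior section by w_i · F_{n−1→n}. Long stacks are split
into near-equal short series sharing single "benchmark" sections that are
rigidly chained in advance; each short series is registered and compensated
independently and the results are restacked.

Two flow estimators implement one interface: a deterministic classical
coarse-to-fine Lucas–Kanade pyramid operating on descriptor maps (default),
and a lightweight trainable coarse-to-fine cost-volume model optimized with
the unsupervised losses above. See `docs/methods.md` for conventions,
parameters and safeguards.

## Worked example

Register a synthetic deformed phantom end to end and score it:

```python
import numpy as np
from emflowreg.experiments import serial_tps_experiment

out = serial_tps_experiment(seed=0)
print(f"top-k Dice unregistered: {out['dice_unregistered']:.3f}")
print(f"top-k Dice registered:   {out['dice_registered']:.3f}")
print(f"NCC to ground truth:     {out['ncc_unregistered']:.3f} -> {out['ncc_registered']:.3f}")
```

prints

```
top-k Dice unregistered: 0.772
top-k Dice registered:   0.941
NCC to ground truth:     0.710 -> 0.883
```

i.e. on a 16-section labeled cylinder phantom whose interior sections were
each deformed by a random thin-plate-spline field, sequential registration
plus structural regression raises the mean whole-volume Dice of the
neurite labels from 0.77 to 0.94 and the mean NCC between the registered
sections and the undeformed ground truth from 0.71 to 0.88.

The same pipeline on files, via the CLI:

```
emflowreg simulate --kind phantom --seed 0 --out demo/
emflowreg register --input demo/phantom.h5 --format hdf5 --out demo/registered.h5
emflowreg evaluate --gt demo/phantom.h5 --result demo/registered.h5 --report demo/report.json
```

`register` writes the warped stack, the per-section flows, and a JSON run
manifest (descriptor distances d_i, weights w_i, error-flow statistics,
endpoint transform). `--segments K` switches to the long-series split;
`emflowreg train` fits the learned estimator on synthetic pairs.

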