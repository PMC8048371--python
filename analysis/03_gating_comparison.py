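#!/usr/bin/env python
"""Gated vs non-gated radial acquisition: effect of respiratory motion on
the apparent diffusivity.

Runs noiseless simulations over ten motion realizations per condition so
the contrast is purely motion-driven, and writes per-seed water and tumor
ROI means.  Expected behavior: gated values sit at the ground truth while
non-gated values read high (motion during diffusion encoding destroys
coherent signal preferentially at high b, steepening the apparent decay).
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

import raddwi as rd

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(parents=True, exist_ok=True)

maps = rd.rasterize(rd.default_phantom(), 64)
params = rd.radial_params()
calib = (rd.roi_masks(maps, erode=1)["water"]
         | rd.roi_masks(maps, erode=1)["tumor"])
rois = rd.roi_masks(maps, erode=2)

rows = []
for gated in (True, False):
    p = dataclasses.replace(params, gated=gated)
    for seed in range(10):
        motion = rd.RespirationModel(seed=700 + seed)
        ks = rd.simulate_radial_kspace(maps, p, motion, seed)
        pm = rd.fit_stack(rd.fbp_reconstruct(rd.correct_radial_stack(ks)),
                          mask=calib)
        for tissue in ("water", "tumor"):
            rows.append({"gated": gated, "seed": seed, "tissue": tissue,
                         "adc": rd.roi_stats(pm, rois[tissue])[0] * 1e3})

df = pd.DataFrame(rows)
df.to_csv(OUT / "gating_comparison.csv", index=False)
for tissue in ("water", "tumor"):
    g = df.query("tissue == @tissue and gated")["adc"]
    ng = df.query("tissue == @tissue and not gated")["adc"]
    print(f"{tissue}: gated {g.mean():.2f} +- {g.std():.2f}, "
          f"non-gated {ng.mean():.2f} +- {ng.std():.2f} x1e-3 mm^2/s")
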