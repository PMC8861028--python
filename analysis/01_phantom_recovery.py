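#!/usr/bin/env python
"""Quantify the study-scale tarsal phantom against its exact ground truth.

Renders the noiseless default phantom plus noisy replicates, runs the full
reorient -> VOI -> segment -> measure pipeline, and tabulates recovered
vs true volumes.  Expected finding: noiseless BV is recovered *exactly*
(zero voxel disagreement), STV within ~3% (discrepancies are smoothing
shells at tissue interfaces), and 50 AU noise leaves BV unchanged because
the tissue intensity steps sit tens of noise SDs from the thresholds.

Writes results/phantom_recovery.csv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from tarsalct import VOISpec, default_tarsal_spec, make_phantom, mask_volume, quantify

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--n-noise-seeds", type=int, default=5)
args = parser.parse_args()

rows = []
spec0 = dataclasses.replace(default_tarsal_spec(), noise_sd=0.0)
for label, noise, seed in [("noiseless", 0.0, args.seed)] + [
    (f"noise50_seed{k}", 50.0, args.seed + k) for k in range(args.n_noise_seeds)
]:
    spec = dataclasses.replace(spec0, noise_sd=noise)
    vol, truth = make_phantom(spec, seed=seed)
    res = quantify(vol, VOISpec())
    v = res.voi_used
    gt_stv = mask_volume(
        truth.soft_mask[:, :, v.start_slice : v.start_slice + v.n_slices], vol.spacing
    )
    rows.append(
        {
            "condition": label,
            "bv_mm3": res.bone_volume_mm3,
            "gt_bv_mm3": truth.bone_volume_mm3,
            "bv_error_pct": abs(res.bone_volume_mm3 - truth.bone_volume_mm3)
            / truth.bone_volume_mm3
            * 100,
            "stv_mm3": res.soft_volume_mm3,
            "gt_stv_mm3": gt_stv,
            "stv_error_pct": abs(res.soft_volume_mm3 - gt_stv) / gt_stv * 100,
            "voi_start": v.start_slice,
        }
    )

table = pd.DataFrame(rows)
out = Path(__file__).resolve().parents[1] / "results" / "phantom_recovery.csv"
out.parent.mkdir(exist_ok=True)
table.to_csv(out, index=False)
print(table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print(f"\nmax BV error {table.bv_error_pct.max():.3f}% | "
      f"max STV error {table.stv_error_pct.max():.3f}% -> {out}")
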