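#!/usr/bin/env python
"""Collapse both modalities to longitudinal profiles, cluster with exact 1-D
2-means, threshold at the cluster-center midpoint, and compare the resulting
WM/GM tissue barcodes.

Writes barcodes.json and agreement.json and prints the transition positions
along the trajectory.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import WORKDIR, desk_config

from catheter_psoct.pipeline import run_stage


def main():
    cfg = desk_config()
    for stage in ("barcode", "compare"):
        entry = run_stage(stage, cfg, WORKDIR)
        print(f"stage {entry['stage']}: {entry['elapsed_s']}s")
    report = json.loads((WORKDIR / "agreement.json").read_text())
    print(f"PS-OCT/MRI barcode agreement: {report['agreement']:.3f} "
          f"over {report['n_rows']} rows")
    print(f"Dice (WM): {report['dice']['wm']:.3f}  Dice (GM): {report['dice']['gm']:.3f}")
    print("transitions (mm from cortical entry):")
    print(f"  PS-OCT: {[round(t, 2) for t in report['transitions_psoct_mm']]}")
    print(f"  MRI:    {[round(t, 2) for t in report['transitions_mri_mm']]}")


if __name__ == "__main__":
    main()
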