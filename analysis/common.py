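"""Shared desk-scale configuration for the numbered analysis scripts.

The full default phantom (23 mm GM/WM/deep-GM stack with an internal-capsule-
like tract) is imaged at 64 A-lines per frame — enough azimuth sampling for
the en-face views and barcodes while keeping each script in the tens of
seconds on one CPU.  Outputs accumulate under results/pipeline/.
"""

from pathlib import Path

from catheter_psoct.config import PipelineConfig, apply_overrides

WORKDIR = Path(__file__).resolve().parent.parent / "results" / "pipeline"


def desk_config(seed: int = 1) -> PipelineConfig:
    return apply_overrides(
        PipelineConfig(),
        {
            "seed": seed,
            "acquisition.alines_per_frame": 64,
            "acquisition.depth_range_mm": 0.55,
            "reconstruction.offset_smoothing_window_pairs": 5,
        },
    )
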