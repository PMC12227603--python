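#!/usr/bin/env python
"""Derive the HER2 positivity cutoff from the control cell-line Gaussians.

The HER2-negative control (KATOIII: mean 50, SD 23.7) and the weakest
HER2-positive control (NUGC4: mean 76, SD 46.1) define the decision
boundary: the variance-weighted crossover of the two Gaussians, rounded up
to the next integer.  Writes results/threshold.json.
"""

import json
from pathlib import Path

from ctcflow.her2 import CELL_LINE_REFERENCES, ThresholdModel

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    model = ThresholdModel()
    print(
        f"raw crossover T = {model.t_raw:.4f} -> positivity cutoff "
        f"> {model.cutoff}"
    )
    for ref in CELL_LINE_REFERENCES:
        call = model.classify(ref.mean_her2_intensity)
        marker = "ok" if call == ref.her2_class else "MISMATCH"
        print(
            f"  {ref.name:8s} intensity {ref.mean_her2_intensity:6.0f} "
            f"-> {call:8s} (known {ref.her2_class}) [{marker}]"
        )
    OUT.mkdir(exist_ok=True)
    (OUT / "threshold.json").write_text(
        json.dumps(
            {
                "mu_neg": model.mu_neg,
                "sigma_neg": model.sigma_neg,
                "mu_pos": model.mu_pos,
                "sigma_pos": model.sigma_pos,
                "t_raw": model.t_raw,
                "cutoff": model.cutoff,
            },
            indent=2,
        )
        + "\n"
    )
    print(f"wrote {OUT / 'threshold.json'}")


if __name__ == "__main__":
    main()
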