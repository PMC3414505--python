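"""Build the block-design timeline and the expected BOLD response.

Writes the FSL-style three-column event table and the noiseless activation
time-course (boxcar convolved with the canonical HRF) used as ground truth
throughout the simulation study.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from iscval import DesignSpec, HRFParams, design_events, make_boxcar, make_hrf_kernel, make_signal
from iscval.io import write_three_column

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    design = DesignSpec()
    hrf = HRFParams()

    events = design_events(design)
    write_three_column(RESULTS / "design_events.txt", events)

    kernel = make_hrf_kernel(hrf, design.tr)
    signal = make_signal(design, hrf)
    pd.DataFrame(
        {
            "t_s": np.arange(design.n_volumes) * design.tr,
            "boxcar": make_boxcar(design),
            "expected_bold": signal,
        }
    ).to_csv(RESULTS / "expected_signal.csv", index=False)

    lag = float(np.sum(np.arange(kernel.size) * design.tr * kernel))
    print(f"design: {design.n_blocks} blocks x {design.vols_per_block} volumes, TR {design.tr:g} s")
    print(f"retained volumes: {design.n_volumes}; run duration {design.total_duration:g} s "
          f"(incl. {design.n_stabilization} stabilisation volumes)")
    print(f"'on' onsets (s): {events[:, 0].astype(int).tolist()}")
    print(f"HRF: gamma shape {hrf.gamma_shape:g}, scale {hrf.gamma_scale:g} s; "
          f"discrete mean lag {lag:.2f} s")
    print(f"expected signal: plateau {signal.max():.3f}, variance {signal.var():.3f}")
    print(f"wrote {RESULTS/'design_events.txt'} and {RESULTS/'expected_signal.csv'}")


if __name__ == "__main__":
    main()
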