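#!/usr/bin/env python
"""Condition every recording and extract the per-session NIRS parameters.

For each subject-session: order-10 zero-phase low-pass (0.8 Hz), baseline
normalization over the central ten minutes of rest (150–750 s), per-cycle
segmentation (10% curve bounds, 63% time constants, hyperemia spike,
pre-spike zero-crossing, 63% post-spike decay) and averaging of the three
cycles.  Writes results/session_summary.csv (one row per subject-session,
one column per parameter).
"""
from pathlib import Path

from nirsvot.pipeline import run_extract

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "sim_cohort", Path(__file__).with_name("01_simulate_cohort.py"))
_mod = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
CONFIG = _mod.CONFIG


def main() -> None:
    summary = run_extract(CONFIG)
    key_params = ["tsi_min", "tsi_auc", "hhb_tau", "tsi_slope_reoxy",
                  "tsi_max_porh"]
    means = summary.groupby("group")[key_params].mean().round(3)
    print(f"Extracted {len(summary)} subject-sessions -> "
          f"{CONFIG.output_dir}/session_summary.csv")
    print("\nGroup means of headline parameters:")
    print(means.to_string())
    print("\nExpected pattern: G1 shows shallow deoxygenation (small |TSI"
          "\nAUC|) and no hyperemia spike; G2 and G3 deoxygenate deeply and"
          "\novershoot ~10% TSI after deflation.  The generator varies the"
          "\nresponse amplitude with pressure, not its rate, so the 63%"
          "\ntime constants are similar across groups.")


if __name__ == "__main__":
    main()
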