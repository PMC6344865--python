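#!/usr/bin/env python
"""Folding/unfolding rate constants from simulated immobilized traces.

Simulates 30 surface-attached molecules x 120 s at the neat-buffer two-state
rates (k_f = 7.5, k_u = 3.13 s^-1, emission means 0.3/0.8), runs the HMM +
dwell-time pipeline over 10 seeds and reports the recovered rates and the
BIC-selected state count.  Writes results/two_state_rates.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from hpfret import experiments as ex  # noqa: E402

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = ex.two_state_rate_recovery(master_seed=2024)
    df = pd.DataFrame(
        {
            "seed_index": range(len(res.k_fold_per_seed)),
            "k_fold_per_s": res.k_fold_per_seed,
            "k_unfold_per_s": res.k_unfold_per_seed,
        }
    )
    out = RESULTS / "two_state_rates.tsv"
    df.to_csv(out, sep="\t", index=False, float_format="%.4f")
    print(
        f"k_f = {res.k_fold_mean:.3f} s^-1 (truth {ex.NEAT_K_FOLD}), "
        f"k_u = {res.k_unfold_mean:.3f} s^-1 (truth {ex.NEAT_K_UNFOLD})"
    )
    print(f"BIC-selected state counts over seeds: {res.k_selected}")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
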