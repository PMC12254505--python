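#!/usr/bin/env python
"""Monte-Carlo calibration of the nearest-row noise estimator.

The estimator averages d/sqrt(m) over each row's q-1 nearest rows, which is
biased two ways: pair differences carry sqrt(2) times the per-pixel noise,
and picking the *nearest* rows selects the lower tail of the distance
distribution.  This script measures the net expectation on groups of i.i.d.
Gaussian rows at the default operating point (n=64, m=16, q=4); the frozen
result is `pnss.noise_estimation.C_CAL` = 0.9719.

Note this deliberately isolates the row-selection bias: the full pipeline
additionally selects the m most similar *patches* per group, which depresses
the estimate further (see docs/methods.md).

Usage: python scripts/calibrate_noise_estimator.py [--groups 20000] [--seed 2024]
"""

from __future__ import annotations

import argparse

import numpy as np

from pnss.grouping import batch_row_select
from pnss.noise_estimation import sigma_from_row_distances


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--groups", type=int, default=20000)
    ap.add_argument("--seed", type=int, default=2024)
    ap.add_argument("--n", type=int, default=64)
    ap.add_argument("--m", type=int, default=16)
    ap.add_argument("--q", type=int, default=4)
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    vals = np.empty(args.groups)
    batch = 200
    done = 0
    while done < args.groups:
        k = min(batch, args.groups - done)
        groups = rng.normal(0.0, 1.0, size=(k, args.n, args.m))
        _, row_dist = batch_row_select(groups, args.q)
        vals[done : done + k] = sigma_from_row_distances(row_dist, args.m)
        done += k
    c = vals.mean()
    se = vals.std(ddof=1) / np.sqrt(args.groups)
    print(f"c_cal = {c:.6f} +/- {se:.6f}  (n={args.n}, m={args.m}, q={args.q})")


if __name__ == "__main__":
    main()
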