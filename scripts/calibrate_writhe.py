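"""Regenerate the writhe-variance calibration behind wlc_model.writhe_variance.

Simulates closed wormlike rings over a grid of reduced lengths L/P, fits
the smooth curve ln<Wr^2> = a + b ln(L/P) + c (L/P) by weighted least
squares, and prints the coefficients frozen in
``dnamech.wlc_model._WRITHE_COEFFS``.

    python scripts/calibrate_writhe.py [--fast]

The full grid takes ~10 minutes on one CPU; --fast runs a reduced grid for
a quick consistency check.
"""
import argparse

import numpy as np

from dnamech.ring_mc import ring_writhe_variance


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fast", action="store_true")
    ap.add_argument("--seed", type=int, default=1234)
    args = ap.parse_args()
    if args.fast:
        grid = [1.2, 1.8, 2.6]
        n_seg, n_samp = 40, 600
    else:
        grid = [1.0, 1.2, 1.35, 1.5, 1.7, 1.9, 2.2, 2.6, 3.0]
        n_seg, n_samp = 64, 4000
    means, ses = [], []
    for l in grid:
        m, se = ring_writhe_variance(l, n_segments=n_seg, n_samples=n_samp, seed=args.seed)
        means.append(m)
        ses.append(se)
        print(f"L/P = {l:4.2f}  <Wr^2> = {m:.5f} +- {se:.5f}")
    l = np.array(grid)
    w = np.array(means)
    sig = np.array(ses) / w
    A = np.column_stack([np.ones_like(l), np.log(l), l])
    coef, *_ = np.linalg.lstsq(A / sig[:, None], np.log(w) / sig, rcond=None)
    print(f"ln<Wr^2> = {coef[0]:.4f} + {coef[1]:.4f} ln(L/P) + {coef[2]:.4f} (L/P)")


if __name__ == "__main__":
    main()
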