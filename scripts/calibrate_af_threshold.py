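"""Derive the default AF disorganization-index threshold.

Scores 200 sinus and 200 AF-like synthetic 75 s RR segments (heart rate
drawn uniformly in 50-110 bpm for sinus; AF RR i.i.d. uniform on
[0.4, 1.0] s) and picks the cut maximizing Youden's J = sens + spec - 1.
When the classes are fully separated, the cut is placed midway between the
highest sinus index and the lowest AF index.

The resulting value is frozen as ``AnalysisConfig.af_threshold``.

Run:  python scripts/calibrate_af_threshold.py [--seed 12345]
"""

import argparse

import numpy as np

from ecgpipe import AnalysisConfig, RRSeries, SynthSpec
from ecgpipe.rhythm import disorganization_index, fence_outliers, poincare_grid


def segment_index(rr: np.ndarray, cfg: AnalysisConfig) -> float:
    series = RRSeries(rr=rr, fs=250.0)
    series = fence_outliers(series, cfg.fence_multiplier)
    grid = poincare_grid(
        series, cfg.af_bins_per_axis, cfg.rr_axis_range_s, cfg.drr_axis_range_s
    )
    return disorganization_index(grid, cfg.af_full_bin_min_count)


def simulate_indices(n_each: int, seed: int, cfg: AnalysisConfig):
    rng = np.random.default_rng(seed)
    sinus, af = [], []
    for _ in range(n_each):
        hr = rng.uniform(50.0, 110.0)
        spec = SynthSpec(mean_hr_bpm=hr)
        n = int(np.ceil(cfg.af_segment_s / (60.0 / hr)))
        rr = np.maximum(rng.normal(60.0 / hr, spec.hrv_sd_s, size=n), 0.3)
        sinus.append(segment_index(rr, cfg))
        spec_af = SynthSpec()
        n_af = int(
            np.ceil(cfg.af_segment_s / (0.5 * (spec_af.af_min_rr_s + spec_af.af_max_rr_s)))
        )
        rr_af = rng.uniform(spec_af.af_min_rr_s, spec_af.af_max_rr_s, size=n_af)
        af.append(segment_index(rr_af, cfg))
    return np.array(sinus), np.array(af)


def youden_threshold(sinus: np.ndarray, af: np.ndarray) -> tuple[float, float]:
    cuts = np.unique(np.concatenate([sinus, af]))
    best_j, best_cut = -1.0, 0.0
    for c in cuts:
        sens = float(np.mean(af > c))
        spec = float(np.mean(sinus <= c))
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut = j, float(c)
    if sinus.max() < af.min():  # fully separated: put the cut mid-gap
        best_cut = 0.5 * (sinus.max() + af.min())
    return best_cut, best_j


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=12345)
    ap.add_argument("--n", type=int, default=200)
    args = ap.parse_args()
    cfg = AnalysisConfig()
    sinus, af = simulate_indices(args.n, args.seed, cfg)
    cut, j = youden_threshold(sinus, af)
    print(f"sinus index: median {np.median(sinus):.4f}  max {sinus.max():.4f}")
    print(f"af    index: median {np.median(af):.4f}  min {af.min():.4f}")
    print(f"Youden-optimal threshold: {cut:.4f} (J={j:.3f})")
    print(f"currently configured default: {cfg.af_threshold}")


if __name__ == "__main__":
    main()
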