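"""Independent brute-force oracles used to cross-check the pipeline.

These deliberately share no code with the package: Pearson correlation via
the textbook sum formula in pure Python, block means and moving windows via
explicit loops.
"""

from __future__ import annotations

import math

import numpy as np


def pearson_bruteforce(x, y) -> float:
    """Textbook sum-formula Pearson correlation, pure Python."""
    n = len(x)
    assert n == len(y) and n >= 2
    sx = sy = sxx = syy = sxy = 0.0
    for xi, yi in zip(x, y):
        sx += xi
        sy += yi
        sxx += xi * xi
        syy += yi * yi
        sxy += xi * yi
    num = n * sxy - sx * sy
    den = math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
    return num / den


def block_means_bruteforce(x, mask, fs, block_len_s=10.0, min_valid_frac=0.5):
    """Explicit-loop block means over unmasked samples.

    Returns (start_times, means, valid) for full blocks anchored at sample 0.
    """
    blk = int(round(fs * block_len_s))
    n_blocks = len(x) // blk
    starts, means, valid = [], [], []
    for b in range(n_blocks):
        vals = [x[i] for i in range(b * blk, (b + 1) * blk) if not mask[i]]
        starts.append(b * block_len_s)
        if vals:
            means.append(sum(vals) / len(vals))
        else:
            means.append(float("nan"))
        valid.append(len(vals) / blk >= min_valid_frac and len(vals) > 0)
    return starts, means, valid


def nmxa_bruteforce(
    abp, fv, mask_abp, mask_fv, fs,
    block_len_s=10.0, window_s=300.0, step_s=10.0, min_blocks=25,
    min_valid_frac=0.5,
):
    """From-scratch moving-window correlation summary for one side.

    Independent of the package's block/correlation/summary code paths.
    """
    t_a, m_a, v_a = block_means_bruteforce(abp, mask_abp, fs, block_len_s,
                                           min_valid_frac)
    t_f, m_f, v_f = block_means_bruteforce(fv, mask_fv, fs, block_len_s,
                                           min_valid_frac)
    assert t_a == t_f
    span = len(t_a) * block_len_s
    rs = []
    w0 = 0.0
    while w0 + window_s <= span + 1e-9:
        xs, ys = [], []
        for i, t in enumerate(t_a):
            if w0 - 1e-9 <= t < w0 + window_s - 1e-9 and v_a[i] and v_f[i]:
                xs.append(m_a[i])
                ys.append(m_f[i])
        if len(xs) >= min_blocks:
            if max(xs) > min(xs) and max(ys) > min(ys):
                rs.append(pearson_bruteforce(xs, ys))
        w0 += step_s
    if not rs:
        return None
    return sum(rs) / len(rs)


def thrr_exclude_first_oracle(baseline_peaks, post_peaks, baseline_n=5) -> float:
    """Hand implementation of the ratio: drop peak 1, average peaks 2-4."""
    base = baseline_peaks[-baseline_n:]
    baseline = sum(base) / len(base)
    resp = (post_peaks[1] + post_peaks[2] + post_peaks[3]) / 3.0
    return resp / baseline


def closed_form_r(g, slow_waves, intrinsic_amp, intrinsic_freq, noise_sd,
                  fv_mean=55.0, abp_mean=90.0, fs=125.0, block_len_s=10.0):
    """Expected block-level Pearson correlation for the generator's model.

    sigma values are SDs of the 10-s block-mean series: each sinusoid is
    attenuated by sinc(f * block_len) and white noise by sqrt(samples/block).
    """
    k = fv_mean / abp_mean
    var_a = sum((a * np.sinc(f * block_len_s)) ** 2 / 2.0
                for f, a, _ in slow_waves)
    sa = g * k * math.sqrt(var_a)
    si = (1.0 - g) * intrinsic_amp * np.sinc(intrinsic_freq * block_len_s) / math.sqrt(2.0)
    sn = noise_sd / math.sqrt(fs * block_len_s)
    return sa / math.sqrt(sa * sa + si * si + sn * sn)
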