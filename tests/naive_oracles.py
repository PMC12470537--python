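"""Independent naive-loop oracles for every metric.

Each function re-derives its metric with plain Python loops straight from
the defining formula, sharing no code with the package implementation.
They are deliberately slow and only ever run on small arrays.
"""

from __future__ import annotations

import math


def _reflect(i: int, n: int) -> int:
    while i < 0 or i >= n:
        i = -i - 1 if i < 0 else 2 * n - i - 1
    return i


def _mean(vals) -> float:
    vals = list(vals)
    return sum(vals) / len(vals)


def _var(vals) -> float:
    vals = list(vals)
    m = _mean(vals)
    return sum((v - m) ** 2 for v in vals) / len(vals)


def _cov(a, b) -> float:
    a, b = list(a), list(b)
    ma, mb = _mean(a), _mean(b)
    return sum((x - ma) * (y - mb) for x, y in zip(a, b)) / len(a)


def naive_snr(signal_pixels, background_pixels) -> float:
    M = _mean(signal_pixels)
    beta = math.sqrt(_var(background_pixels))
    return 10.0 * math.log10(M ** 2 / beta ** 2)


def naive_psnr(A, B, L: float) -> float:
    rows, cols = len(A), len(A[0])
    E = sum((A[i][j] - B[i][j]) ** 2 for i in range(rows) for j in range(cols)) / (rows * cols)
    return 20.0 * math.log10(L / math.sqrt(E))


def naive_nrmse(T, P) -> float:
    rows, cols = len(T), len(T[0])
    rmse = math.sqrt(
        sum((T[i][j] - P[i][j]) ** 2 for i in range(rows) for j in range(cols)) / (rows * cols))
    flat = [T[i][j] for i in range(rows) for j in range(cols)]
    return rmse / (max(flat) - min(flat))


def naive_cnr(lesion_pixels, background_pixels) -> float:
    It, Ib = _mean(lesion_pixels), _mean(background_pixels)
    return abs(It - Ib) / math.sqrt(_var(lesion_pixels) + _var(background_pixels))


def naive_ssim(R, S, c1: float, c2: float) -> float:
    r = [v for row in R for v in row]
    s = [v for row in S for v in row]
    mu_r, mu_s = _mean(r), _mean(s)
    var_r, var_s = _var(r), _var(s)
    cov = _cov(r, s)
    return (((2 * mu_r * mu_s + c1) * (2 * cov + c2))
            / ((mu_r ** 2 + mu_s ** 2 + c1) * (var_r + var_s + c2)))


def naive_uqi(X, Y) -> float:
    x = [v for row in X for v in row]
    y = [v for row in Y for v in row]
    xm, ym = _mean(x), _mean(y)
    return ((2 * xm * ym / (xm ** 2 + ym ** 2))
            * (2 * _cov(x, y) / (_var(x) + _var(y))))


def naive_convolve(F, K):
    """True 2-D convolution (kernel flipped) with symmetric edge reflection,
    matching scipy.ndimage.convolve(mode='reflect') for odd kernels."""
    rows, cols = len(F), len(F[0])
    kr, kc = len(K), len(K[0])
    cr, cc = kr // 2, kc // 2
    out = [[0.0] * cols for _ in range(rows)]
    for i in range(rows):
        for j in range(cols):
            acc = 0.0
            for u in range(kr):
                for v in range(kc):
                    ii = _reflect(i - (u - cr), rows)
                    jj = _reflect(j - (v - cc), cols)
                    acc += K[u][v] * F[ii][jj]
            out[i][j] = acc
    return out


def naive_gradient_map(F, hx, hy):
    gx = naive_convolve(F, hx)
    gy = naive_convolve(F, hy)
    rows, cols = len(F), len(F[0])
    return [[math.sqrt(gx[i][j] ** 2 + gy[i][j] ** 2) for j in range(cols)] for i in range(rows)]


def naive_gm_score(F, hx, hy) -> float:
    flat = [v for row in F for v in row]
    lo, hi = min(flat), max(flat)
    if hi == lo:
        return 0.0
    norm = sum(abs(v) for row in hx for v in row)
    hxn = [[v / norm for v in row] for row in hx]
    hyn = [[v / norm for v in row] for row in hy]
    Fn = [[(v - lo) / (hi - lo) for v in row] for row in F]
    gm = naive_gradient_map(Fn, hxn, hyn)
    return _mean(v for row in gm for v in row)


def naive_gmsd(X, Y, hx, hy, eps: float) -> float:
    gx = naive_gradient_map(X, hx, hy)
    gy = naive_gradient_map(Y, hx, hy)
    rows, cols = len(X), len(X[0])
    sim = [
        (2.0 * gx[i][j] * gy[i][j] + eps) / (gx[i][j] ** 2 + gy[i][j] ** 2 + eps)
        for i in range(rows) for j in range(cols)
    ]
    mean_s = _mean(sim)
    return math.sqrt(sum((s - mean_s) ** 2 for s in sim) / len(sim))


def naive_fsim_pool(pc1, pc2, g1, g2, eps1: float, eps2: float) -> float:
    """FSIM pooling given the two feature-map pairs (PC maps are shared
    inputs; the pooling and similarity formulas are re-derived by loops)."""
    rows, cols = len(pc1), len(pc1[0])
    num = 0.0
    den = 0.0
    for i in range(rows):
        for j in range(cols):
            sp = (2 * pc1[i][j] * pc2[i][j] + eps1) / (pc1[i][j] ** 2 + pc2[i][j] ** 2 + eps1)
            sg = (2 * g1[i][j] * g2[i][j] + eps2) / (g1[i][j] ** 2 + g2[i][j] ** 2 + eps2)
            w = max(pc1[i][j], pc2[i][j])
            num += w * sp * sg
            den += w
    return num / den
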