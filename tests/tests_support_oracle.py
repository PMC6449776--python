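"""Loop-based 1-D convolution/deconvolution oracle shared by test modules.

Independent of the package's scipy-based path: the kernel is evaluated
explicitly, boundaries are handled by symmetric padding, and the Van
Cittert recursion is written out step by step.
"""

import numpy as np


def oracle_blur_1d(signal: np.ndarray, sigma: float, truncate: float = 4.0) -> np.ndarray:
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-(x**2) / (2.0 * sigma**2))
    kernel /= kernel.sum()
    padded = np.pad(signal, radius, mode="symmetric")
    return np.convolve(padded, kernel, mode="valid")


def oracle_van_cittert_1d(g, sigma, alpha, tol_percent, max_iter):
    f = g.copy()
    n = 0
    for _ in range(max_iter):
        residual = g - oracle_blur_1d(f, sigma)
        f_new = f + alpha * oracle_blur_1d(residual, sigma)
        change = 100.0 * np.abs(f_new - f).sum() / np.abs(f).sum()
        f = f_new
        n += 1
        if change < tol_percent:
            break
    return f, n
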