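"""Fractional-Brownian surfaces by spectral synthesis.

A 2-D fBm surface with Hurst exponent H has power spectrum
P(f) ∝ f^-(2H + 2) and theoretical fractal dimension FD = 3 - H. These
surfaces serve as the independent calibration standard for the blanket-method
estimator: their FD is known in closed form without running any blanket code.
"""
from __future__ import annotations

import numpy as np

__all__ = ["fbm_surface"]


def fbm_surface(n: int, hurst: float, seed: int) -> np.ndarray:
    """Synthesize an n-by-n fractional Brownian surface with Hurst exponent H.

    Gaussian spectral amplitudes are shaped as f^-(H+1) (hence power
    f^-(2H+2)) with random phases; the inverse FFT's real part is returned,
    normalized to zero mean and unit variance.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    fx = np.fft.fftfreq(n)[None, :]
    fy = np.fft.fftfreq(n)[:, None]
    f = np.hypot(fx, fy)
    f[0, 0] = np.inf  # zero out the DC component
    amp = f ** (-(hurst + 1.0))
    spectrum = amp * (rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n)))
    surf = np.fft.ifft2(spectrum).real
    surf -= surf.mean()
    sd = surf.std()
    return surf / sd if sd > 0 else surf
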