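"""Shared decay-convolution kernel.

Expected counts per TCSPC channel are the continuous convolution of the
IRF with a causal exponential, integrated over each time bin. The
exponential is represented by its bin-integrated kernel

    K[m] = (τ/Δt) · (e^{-a/τ} - e^{-b/τ}),  a = max(0, (m-½)Δt), b = (m+½)Δt,

which handles the step discontinuity at lag zero exactly (a plain
point-sampled kernel is biased by O(Δt/τ) there). The convolution with a
sampled IRF reduces to an O(n) cumulative sum:

    conv[k] = c · e^{-kΔt/τ} · Σ_{j≤k} irf[j] e^{jΔt/τ} + (K[0] - c) · irf[k]

with c = (2τ/Δt) · sinh(Δt/2τ).
"""

from __future__ import annotations

import numpy as np


def exp_irf_conv(tau_ps: float, irf_samples: np.ndarray, bin_width_ps: float) -> np.ndarray:
    """IRF ⊛ (bin-integrated causal exponential), unnormalized, length n."""
    if tau_ps <= 0:
        raise ValueError("tau_ps must be positive")
    n = irf_samples.size
    dt = bin_width_ps
    x = dt / tau_ps
    c = (2.0 / x) * np.sinh(x / 2.0)
    k0 = (1.0 / x) * (1.0 - np.exp(-x / 2.0))
    idx = np.arange(n)
    grow = irf_samples * np.exp(idx * x)
    conv = c * np.exp(-idx * x) * np.cumsum(grow) + (k0 - c) * irf_samples
    return conv
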