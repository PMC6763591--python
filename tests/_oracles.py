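"""Independent brute-force oracles shared across test modules."""

import numpy as np
from scipy import ndimage

EIGHT = np.ones((3, 3), int)


def brute_force_chi(mask: np.ndarray) -> int:
    """8-connected components minus 4-connected holes, by labeling."""
    mask = mask.astype(bool)
    _, n_comp = ndimage.label(mask, structure=EIGHT)
    padded = np.pad(~mask, 1, constant_values=True)
    _, n_bg = ndimage.label(padded)  # 4-connectivity; one component is outside
    return n_comp - (n_bg - 1)


def spectral_fbm2d(h: float, n: int, rng) -> np.ndarray:
    """Fractional field via spectral synthesis, power spectrum ~ f^-(2H+2)."""
    fx = np.fft.fftfreq(n)[:, None]
    fy = np.fft.fftfreq(n)[None, :]
    f2 = fx**2 + fy**2
    with np.errstate(divide="ignore"):
        amp = np.where(f2 == 0, 0.0, f2 ** (-(2 * h + 2) / 4))
    phase = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
    field = np.fft.ifft2(amp * phase).real
    return (field - field.mean()) / field.std()
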