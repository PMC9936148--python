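"""Orthogonal Daubechies wavelet transforms.

Implements the Mallat pyramid (multilevel DWT, soft thresholding and
reconstruction) with periodized boundary handling, for the ``dbN`` family.
Filters are generated numerically by spectral factorization of the
Daubechies polynomial, so any order (db1 = Haar up to db20 and beyond) is
available without tabulated coefficients.

Conventions: the scaling (lowpass reconstruction) filter ``h`` satisfies
``sum(h) == sqrt(2)``; the wavelet filter is the quadrature mirror
``g[k] = (-1)^k h[L-1-k]``. With periodization, a signal of even length n
decomposes into two length-n/2 coefficient arrays and reconstructs exactly.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = [
    "daubechies_filters",
    "dwt_max_level",
    "wavedec",
    "waverec",
    "soft_threshold",
]


@lru_cache(maxsize=32)
def daubechies_filters(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (scaling, wavelet) filters for dbN with ``order`` vanishing moments.

    The extremal-phase solution: the 2*order filter taps come from the roots
    of the Daubechies polynomial P(y) that lie inside the unit circle after
    the y -> z substitution, together with ``order`` zeros at z = -1.
    """
    if order < 1:
        raise ValueError("wavelet order must be >= 1")
    if order == 1:  # Haar, exact
        h = np.array([1.0, 1.0]) / np.sqrt(2.0)
    else:
        n = order
        # P(y) = sum_k C(n-1+k, k) y^k, k = 0..n-1
        from math import comb

        p = np.array([comb(n - 1 + k, k) for k in range(n)], dtype=float)
        y_roots = np.roots(p[::-1])
        z_roots = []
        for y in y_roots:
            # y = (2 - z - 1/z)/4  =>  z^2 + (4y - 2) z + 1 = 0
            zz = np.roots([1.0, 4.0 * y - 2.0, 1.0])
            z_roots.append(zz[np.argmin(np.abs(zz))])  # minimal-phase root
        roots = np.concatenate([np.full(n, -1.0 + 0j), np.asarray(z_roots)])
        h = np.real(np.poly(roots))
        h = h / np.sum(h) * np.sqrt(2.0)
    g = ((-1.0) ** np.arange(h.size)) * h[::-1]
    h.setflags(write=False)
    g.setflags(write=False)
    return h, g


def dwt_max_level(n_samples: int, filter_len: int) -> int:
    """Deepest useful decomposition level for a length-n signal."""
    if n_samples < filter_len:
        return 0
    return int(np.floor(np.log2(n_samples / (filter_len - 1.0))))


def _dwt_step(x: np.ndarray, h: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One periodized analysis step: x (even length) -> (approx, detail)."""
    n = x.size
    if n % 2:  # periodization pads odd signals with the last sample
        x = np.concatenate([x, x[-1:]])
        n += 1
    L = h.size
    # circular extension so that 'valid' correlation covers every output phase
    reps = int(np.ceil(L / n)) + 1
    ext = np.concatenate([np.tile(x, reps)[-(L - 1):], x] if L > 1 else [x])
    # a_i = sum_k h[k] x[2i + 1 - k  (mod n)]
    full = np.correlate(ext, h[::-1], mode="valid")
    idx = (np.arange(n // 2) * 2 + 1) % n
    a = full[idx]
    full_g = np.correlate(ext, g[::-1], mode="valid")
    d = full_g[idx]
    return a, d


def _idwt_step(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Inverse of :func:`_dwt_step` (periodized synthesis)."""
    n = 2 * a.size
    L = h.size
    x = np.zeros(n)
    # transpose of the analysis operator: x[m] += h[k] a[i] at m = (2i+1-k) mod n
    for k in range(L):
        pos = (np.arange(a.size) * 2 + 1 - k) % n
        np.add.at(x, pos, h[k] * a + g[k] * d)
    return x


def wavedec(x: np.ndarray, wavelet: str, level: int) -> list[np.ndarray]:
    """Multilevel DWT: returns [A_level, D_level, ..., D_2, D_1]."""
    h, g = _filters_for(wavelet)
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("wavedec expects a 1-D signal")
    max_lvl = dwt_max_level(x.size, h.size)
    if level < 1:
        raise ValueError("level must be >= 1")
    if level > max_lvl:
        raise ValueError(
            f"signal of length {x.size} supports at most level {max_lvl} "
            f"for {wavelet} (requested {level})"
        )
    coeffs: list[np.ndarray] = []
    a = x
    for _ in range(level):
        a, d = _dwt_step(a, h, g)
        coeffs.append(d)
    coeffs.append(a)
    return coeffs[::-1]


def waverec(coeffs: list[np.ndarray], wavelet: str) -> np.ndarray:
    h, g = _filters_for(wavelet)
    a = coeffs[0]
    for d in coeffs[1:]:
        if a.size != d.size:  # periodization keeps sizes equal per level
            a = a[: d.size]
        a = _idwt_step(a, d, h, g)
    return a


def soft_threshold(c: np.ndarray, thr: float) -> np.ndarray:
    """Shrink coefficients toward zero: sign(c) * max(|c| - thr, 0)."""
    return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)


def _filters_for(wavelet: str) -> tuple[np.ndarray, np.ndarray]:
    name = wavelet.lower().strip()
    if not name.startswith("db"):
        raise ValueError(f"unsupported wavelet {wavelet!r}; use 'dbN'")
    try:
        order = int(name[2:])
    except ValueError as exc:
        raise ValueError(f"unsupported wavelet {wavelet!r}") from exc
    return daubechies_filters(order)
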