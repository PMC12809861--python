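"""Vectorised bivariate standard-normal rectangle probabilities.

Implements the Gauss–Legendre quadrature scheme of Drezner & Wesolowsky
as refined by Genz (the TVPACK ``BVND`` routine), always using the
20-point rule, which gives absolute errors well below 1e-13 for
|rho| < 0.925 and below ~1e-11 in the near-singular regime.  All inputs
broadcast; |rho| = 1 is handled exactly.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

__all__ = ["bvn_upper", "bvn_cdf"]

# 20-point Gauss-Legendre rule on (-1, 1), positive half
_X = np.array([
    0.9931285991850949, 0.9639719272779138, 0.9122344282513259,
    0.8391169718222188, 0.7463319064601508, 0.6360536807265150,
    0.5108670019508271, 0.3737060887154195, 0.2277858511416451,
    0.0765265211334973,
])
_W = np.array([
    0.0176140071391521, 0.0406014298003869, 0.0626720483341091,
    0.0832767415767048, 0.1019301198172404, 0.1181945319615184,
    0.1316886384491766, 0.1420961093183820, 0.1491729864726037,
    0.1527533871307258,
])

_TWOPI = 2.0 * np.pi


def _bvnu_mid(h, k, r):
    """|r| < 0.925 branch: P(X > h, Y > k)."""
    hk = h * k
    hs = (h * h + k * k) / 2.0
    asr = np.arcsin(r)
    total = np.zeros_like(h)
    for s in (-1.0, 1.0):
        sn = np.sin(asr[None, :] * (1.0 + s * _X[:, None]) / 2.0)
        total = total + np.einsum(
            "i,ij->j", _W, np.exp((sn * hk[None, :] - hs[None, :]) / (1.0 - sn * sn))
        )
    return total * asr / (2.0 * _TWOPI) + ndtr(-h) * ndtr(-k)


def _bvnu_tail(h, k, r):
    """0.925 <= |r| < 1 branch: P(X > h, Y > k)."""
    neg = r < 0
    k = np.where(neg, -k, k)
    hk = h * k
    bvn = np.zeros_like(h)

    a2 = (1.0 - r) * (1.0 + r)
    a = np.sqrt(a2)
    bs = (h - k) ** 2
    c = (4.0 - hk) / 8.0
    d = (12.0 - hk) / 16.0
    asr = -(bs / a2 + hk) / 2.0
    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        term = a * np.exp(asr) * (
            1.0 - c * (bs - a2) * (1.0 - d * bs / 5.0) / 3.0 + c * d * a2 * a2 / 5.0
        )
    bvn = np.where(asr > -100.0, term, 0.0)

    with np.errstate(over="ignore", under="ignore", invalid="ignore"):
        b = np.sqrt(bs)
        sp = np.sqrt(_TWOPI) * ndtr(-b / np.where(a > 0, a, 1.0))
        term2 = np.exp(-hk / 2.0) * sp * b * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0)
    bvn = bvn - np.where((-hk < 100.0) & (a > 0), term2, 0.0)

    ah = a / 2.0
    for s in (-1.0, 1.0):
        xs = (ah[None, :] * (1.0 + s * _X[:, None])) ** 2
        rs = np.sqrt(np.maximum(1.0 - xs, 0.0))
        asr1 = -(np.divide(bs[None, :], np.where(xs > 0, xs, 1.0)) + hk[None, :]) / 2.0
        with np.errstate(over="ignore", under="ignore", invalid="ignore"):
            ep = np.exp(-hk[None, :] * (1.0 - rs) / (2.0 * (1.0 + rs))) / np.where(
                rs > 0, rs, 1.0
            )
            spq = 1.0 + c[None, :] * xs * (1.0 + d[None, :] * xs)
            contrib = ah[None, :] * np.exp(asr1) * (ep - spq)
        contrib = np.where((asr1 > -100.0) & (xs > 0), contrib, 0.0)
        bvn = bvn + np.einsum("i,ij->j", _W, contrib)
    bvn = -bvn / _TWOPI

    pos = bvn + ndtr(-np.maximum(h, k))
    negv = -bvn + np.where(k > h, ndtr(k) - ndtr(h), 0.0)
    return np.where(neg, negv, pos)


def bvn_upper(h, k, rho):
    """P(X > h, Y > k) for standard bivariate normal with correlation rho."""
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, float), np.asarray(k, float), np.asarray(rho, float)
    )
    shape = h.shape
    h, k, rho = h.ravel(), k.ravel(), rho.ravel()
    if np.any(np.abs(rho) > 1.0):
        raise ValueError("correlation outside [-1, 1]")
    out = np.empty_like(h)

    mid = np.abs(rho) < 0.925
    if mid.any():
        out[mid] = _bvnu_mid(h[mid], k[mid], rho[mid])
    tail = (~mid) & (np.abs(rho) < 1.0)
    if tail.any():
        out[tail] = _bvnu_tail(h[tail], k[tail], rho[tail])
    one = rho == 1.0
    if one.any():
        out[one] = ndtr(-np.maximum(h[one], k[one]))
    mone = rho == -1.0
    if mone.any():  # Y = -X: need X > h and X < -k
        out[mone] = np.maximum(ndtr(-k[mone]) - ndtr(h[mone]), 0.0)

    return np.clip(out, 0.0, 1.0).reshape(shape)


def bvn_cdf(x, y, rho):
    """P(X <= x, Y <= y) for standard bivariate normal with correlation rho."""
    return bvn_upper(-np.asarray(x, float), -np.asarray(y, float), rho)
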