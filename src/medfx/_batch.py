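"""Batched closed-form OLS for many small mediation fits at once.

The bootstrap and the Monte Carlo harness each need on the order of 10^5-10^6
tiny regressions (n of 10-1000, 2-4 columns).  Fitting them one at a time is
the bottleneck, so the path coefficients are computed here from centered
cross-product matrices for a whole batch in a handful of vectorised numpy
calls.  Slopes from centered data are identical to with-intercept OLS.
"""

from __future__ import annotations

import numpy as np

__all__ = ["batched_single_paths", "batched_two_paths"]

# Relative determinant threshold below which a normal-equations matrix is
# treated as rank deficient (constant X resample, collinear mediators).
_DET_RTOL = 1e-12


def _center(arr: np.ndarray) -> np.ndarray:
    return arr - arr.mean(axis=-1, keepdims=True)


def batched_single_paths(xb: np.ndarray, mb: np.ndarray, yb: np.ndarray) -> dict:
    """Path coefficients for a batch of single-mediator datasets.

    Parameters are arrays of shape (B, n).  Returns a dict of length-B arrays
    ``a``, ``b``, ``c``, ``c_prime``, ``s_x``, ``s_y`` and a boolean ``ok``
    mask that is False where any design was rank deficient (entries of the
    other arrays are NaN there).
    """
    n = xb.shape[-1]
    xc, mc, yc = _center(xb), _center(mb), _center(yb)
    sxx = np.einsum("bi,bi->b", xc, xc)
    smm = np.einsum("bi,bi->b", mc, mc)
    sxm = np.einsum("bi,bi->b", xc, mc)
    sxy = np.einsum("bi,bi->b", xc, yc)
    smy = np.einsum("bi,bi->b", mc, yc)
    syy = np.einsum("bi,bi->b", yc, yc)

    det = sxx * smm - sxm**2
    ok = (sxx > 0) & (det > _DET_RTOL * np.maximum(sxx * smm, 1e-300))
    safe_sxx = np.where(ok, sxx, 1.0)
    safe_det = np.where(ok, det, 1.0)

    a = sxm / safe_sxx
    c = sxy / safe_sxx
    c_prime = (smm * sxy - sxm * smy) / safe_det
    b = (sxx * smy - sxm * sxy) / safe_det

    out = {
        "a": a,
        "b": b,
        "c": c,
        "c_prime": c_prime,
        "s_x": np.sqrt(sxx / (n - 1)),
        "s_y": np.sqrt(syy / (n - 1)),
        "ok": ok,
    }
    for k in ("a", "b", "c", "c_prime"):
        out[k] = np.where(ok, out[k], np.nan)
    return out


def batched_two_paths(
    xb: np.ndarray, m1b: np.ndarray, m2b: np.ndarray, yb: np.ndarray
) -> dict:
    """Path coefficients for a batch of two-mediator datasets.

    Same contract as :func:`batched_single_paths`, with slopes ``a1``, ``b1``,
    ``a2``, ``b2``, ``c``, ``c_prime``.
    """
    n = xb.shape[-1]
    xc, m1c, m2c, yc = _center(xb), _center(m1b), _center(m2b), _center(yb)
    Z = np.stack([xc, m1c, m2c], axis=1)  # (B, 3, n)
    S = np.einsum("bpi,bqi->bpq", Z, Z)  # (B, 3, 3)
    t = np.einsum("bpi,bi->bp", Z, yc)  # (B, 3)
    sxx = S[:, 0, 0]
    syy = np.einsum("bi,bi->b", yc, yc)

    det = np.linalg.det(S)
    scale = np.maximum(S[:, 0, 0] * S[:, 1, 1] * S[:, 2, 2], 1e-300)
    ok = (sxx > 0) & (det > _DET_RTOL * scale)

    S_safe = np.where(ok[:, None, None], S, np.eye(3))
    coefs = np.linalg.solve(S_safe, t[..., None])[..., 0]  # (B, 3): c', b1, b2

    safe_sxx = np.where(sxx > 0, sxx, 1.0)
    out = {
        "a1": np.einsum("bi,bi->b", xc, m1c) / safe_sxx,
        "a2": np.einsum("bi,bi->b", xc, m2c) / safe_sxx,
        "c": t[:, 0] / safe_sxx,
        "c_prime": coefs[:, 0],
        "b1": coefs[:, 1],
        "b2": coefs[:, 2],
        "s_x": np.sqrt(sxx / (n - 1)),
        "s_y": np.sqrt(syy / (n - 1)),
        "ok": ok,
    }
    for k in ("a1", "a2", "b1", "b2", "c", "c_prime"):
        out[k] = np.where(ok, out[k], np.nan)
    return out
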