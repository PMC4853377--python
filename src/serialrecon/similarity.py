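"""Intensity similarity measures used for registration bookkeeping.

These are the *reported* metrics (stage provenance, degradation guards,
optimizer contracts in tests); the iterative optimizers inside the
registration engine evaluate their own internal versions.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

__all__ = ["ssd", "mutual_information", "normalized_mutual_information"]


def _masked(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray]):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("images must share shape")
    if mask is not None:
        m = np.asarray(mask).ravel().astype(bool)
        a, b = a[m], b[m]
    if a.size == 0:
        raise ValueError("empty sample after masking")
    return a, b


def ssd(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Mean squared intensity difference (lower is better)."""
    x, y = _masked(a, b, mask)
    return float(np.mean((x - y) ** 2))


def _joint_hist(a: np.ndarray, b: np.ndarray, bins: int) -> np.ndarray:
    h, _, _ = np.histogram2d(a, b, bins=bins)
    return h / h.sum()


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def mutual_information(a, b, bins: int = 32, mask=None) -> float:
    """Shannon mutual information of the joint intensity histogram (nats)."""
    x, y = _masked(a, b, mask)
    pxy = _joint_hist(x, y, bins)
    return _entropy(pxy.sum(axis=1)) + _entropy(pxy.sum(axis=0)) - _entropy(pxy)


def normalized_mutual_information(a, b, bins: int = 32, mask=None) -> float:
    """NMI = (H(A) + H(B)) / H(A, B); 1 for independent images, up to 2."""
    x, y = _masked(a, b, mask)
    pxy = _joint_hist(x, y, bins)
    hxy = _entropy(pxy)
    if hxy < 1e-12:
        return 2.0
    return (_entropy(pxy.sum(axis=1)) + _entropy(pxy.sum(axis=0))) / hxy
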