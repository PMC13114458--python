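"""Multiple-testing corrections: BH step-up (optionally padded) and Holm.

The padded variant inflates the BH family size to a fixed total by
appending p = 1.0 placeholders for untested hypotheses (e.g. pathways
with no surviving features), a deliberately conservative policy that is
not a formal FDR guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CorrectionResult:
    raw: np.ndarray
    adjusted: np.ndarray
    method: str
    m: int
    n_padded: int = 0


def _validate(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bh_adjust(p, m_override: int | None = None) -> CorrectionResult:
    """Benjamini–Hochberg step-up adjusted p-values.

    With ``m_override`` larger than ``len(p)`` the family is padded with
    1.0 entries before adjustment; only the original entries are returned
    (padding entries adjust to 1.0 by construction).
    """
    p = _validate(p)
    n = p.size
    if m_override is None:
        m_override = n
    if m_override < n:
        raise ValueError("m_override must be >= len(p)")
    n_pad = m_override - n
    full = np.concatenate([p, np.ones(n_pad)])
    m = full.size
    order = np.argsort(full, kind="stable")
    scaled = full[order] * m / np.arange(1, m + 1)
    stepped = np.minimum.accumulate(scaled[::-1])[::-1]  # cumulative min from the top
    adj = np.empty(m)
    adj[order] = np.minimum(stepped, 1.0)
    return CorrectionResult(p, adj[:n], "bh_padded" if n_pad else "bh", m_override, n_pad)


def holm_adjust(p) -> CorrectionResult:
    """Holm step-down adjusted p-values."""
    p = _validate(p)
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(p[order] * (m - np.arange(m)), 1.0)
    stepped = np.maximum.accumulate(scaled)
    adj = np.empty(m)
    adj[order] = stepped
    return CorrectionResult(p, adj, "holm", m)
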