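"""Small angle utilities shared across the package.

Orientations are stored *unwrapped* along a trajectory (no artificial
±2π jumps between consecutive samples) so that plain arithmetic means
and absolute differences are meaningful.
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle", "unwrap"]


def wrap_angle(a):
    """Wrap angle(s) to the interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = np.mod(-a + np.pi, 2.0 * np.pi)
    out = -(w - np.pi)
    return out if out.ndim else float(out)


def unwrap(theta: np.ndarray) -> np.ndarray:
    """Unwrap a 1-D angle signal (radians)."""
    return np.unwrap(np.asarray(theta, dtype=float))
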