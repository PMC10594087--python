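"""Optional numba acceleration.

The numerical cores (graphical-lasso coordinate descent, spinglass
annealer) are written in a loop-heavy style that numba can compile.
When numba is unavailable the same functions run as plain Python,
producing bit-identical results, only slower.
"""
from __future__ import annotations

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def maybe_njit(fn):
        return _njit(cache=True)(fn)

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def maybe_njit(fn):
        return fn

    HAVE_NUMBA = False
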