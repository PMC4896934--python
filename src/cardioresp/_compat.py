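"""Optional numba acceleration.

Every numerical kernel is written as plain scalar Python and decorated with
:func:`maybe_jit`; with numba present the closed-loop engine runs in seconds,
without it the same code runs unmodified (slowly).
"""
from __future__ import annotations

try:  # pragma: no cover - exercised implicitly by every kernel call
    from numba import njit as _njit

    HAVE_NUMBA = True

    def maybe_jit(func=None, **kw):
        kw.setdefault("cache", True)
        if func is None:
            return lambda f: _njit(**kw)(f)
        return _njit(**kw)(func)

except Exception:  # pragma: no cover
    HAVE_NUMBA = False

    def maybe_jit(func=None, **kw):
        if func is None:
            return lambda f: f
        return func
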