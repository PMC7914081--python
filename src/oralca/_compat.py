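"""Optional numba acceleration.

Inner loops are written in nopython-compatible NumPy scalar code and wrapped
with ``numba.njit`` when numba imports cleanly; otherwise the pure-Python
function is used unchanged (slower, identical results).
"""

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit

    def maybe_njit(func=None, **kwargs):
        if func is None:
            return lambda f: _njit(f, **kwargs)
        return _njit(func, **kwargs)

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def maybe_njit(func=None, **kwargs):
        if func is None:
            return lambda f: f
        return func

    HAVE_NUMBA = False
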