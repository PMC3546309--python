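"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np

#: gamete-code values used throughout: 0 = "a", 1 = "b", -1 = missing
CODE_A = 0
CODE_B = 1
CODE_MISSING = -1

CODE_CHARS = {CODE_A: "a", CODE_B: "b", CODE_MISSING: "-"}
CHAR_CODES = {v: k for k, v in CODE_CHARS.items()}


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent child generators from one master seed."""
    ss = np.random.SeedSequence(int(seed))
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def weighted_isotonic(y: np.ndarray, w: np.ndarray | None = None) -> np.ndarray:
    """Pool-adjacent-violators: weighted non-decreasing fit to ``y``."""
    y = np.asarray(y, dtype=float)
    n = y.size
    if w is None:
        w = np.ones(n)
    w = np.asarray(w, dtype=float)
    # blocks as (value, weight, count)
    vals: list[float] = []
    wts: list[float] = []
    cnts: list[int] = []
    for i in range(n):
        vals.append(y[i])
        wts.append(w[i])
        cnts.append(1)
        while len(vals) > 1 and vals[-2] > vals[-1]:
            v = (vals[-2] * wts[-2] + vals[-1] * wts[-1]) / (wts[-2] + wts[-1])
            wts[-2] += wts[-1]
            cnts[-2] += cnts[-1]
            vals[-2] = v
            del vals[-1], wts[-1], cnts[-1]
    out = np.empty(n)
    pos = 0
    for v, c in zip(vals, cnts):
        out[pos : pos + c] = v
        pos += c
    return out


def codes_to_strings(codes: np.ndarray) -> np.ndarray:
    """int8 gamete codes -> 'a'/'b'/'-' array."""
    out = np.full(codes.shape, "-", dtype="<U1")
    out[codes == CODE_A] = "a"
    out[codes == CODE_B] = "b"
    return out


def strings_to_codes(chars) -> np.ndarray:
    arr = np.asarray(chars, dtype="<U1")
    out = np.full(arr.shape, CODE_MISSING, dtype=np.int8)
    out[arr == "a"] = CODE_A
    out[arr == "b"] = CODE_B
    return out
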