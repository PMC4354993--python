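"""Brute-force reference implementations used only as test oracles.

These deliberately use plain Python dict/loop arithmetic (no numpy) so they
share no code path with the package implementation they check.
"""

import math


def brute_spec(values, cutoff, labels):
    """Two-state Spec score per tissue by direct enumeration."""
    tissues = sorted(set(labels))
    n = len(tissues)
    state = ["high" if v > cutoff else "low" for v in values]
    size = {t: sum(1 for lab in labels if lab == t) for t in tissues}
    q = {}
    for t in tissues:
        for b in ("low", "high"):
            q[(t, b)] = (
                sum(1 for s, lab in zip(state, labels) if lab == t and s == b) / size[t]
            )
    info = {}
    for b in ("low", "high"):
        tot = sum(q[(t, b)] for t in tissues)
        if tot == 0:
            info[b] = 0.0
            continue
        h = 0.0
        for t in tissues:
            p = q[(t, b)] / tot
            if p > 0:
                h += p * math.log(p)
        info[b] = 1.0 + h / math.log(n)
    return {
        t: q[(t, "high")] * info["high"] - q[(t, "low")] * info["low"] for t in tissues
    }


def brute_ici(expression, weights):
    """Identity index by direct arithmetic on paired lists."""
    n = len(weights)
    weighted_mean = sum(e * w for e, w in zip(expression, weights)) / n
    detected = sum(1 for e in expression if e > 0) / n
    return weighted_mean * detected
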