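"""Independent step-by-step oracles, coded from the printed formulas only.

These deliberately use plain Python arithmetic (no numpy, no shared code
with the package) so they can serve as an independent check of the
DerSimonian-Laird pooling and the indirect-combination arithmetic.
"""

import math


def log_or_oracle(a, n1, c, n2):
    """Log-OR and SE from a 2x2 table, +0.5 to all cells if any is zero."""
    b, d = n1 - a, n2 - c
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a / b) / (c / d))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return log_or, se


def dl_oracle(ys, ses):
    """Classic DL pooling: returns (pooled, pooled_se, tau2, q)."""
    k = len(ys)
    w = [1.0 / s**2 for s in ses]
    sw = sum(w)
    y_fe = sum(wi * yi for wi, yi in zip(w, ys)) / sw
    q = sum(wi * (yi - y_fe) ** 2 for wi, yi in zip(w, ys))
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom)
    ws = [1.0 / (s**2 + tau2) for s in ses]
    sws = sum(ws)
    pooled = sum(wi * yi for wi, yi in zip(ws, ys)) / sws
    return pooled, 1.0 / math.sqrt(sws), tau2, q


def bucher_oracle(y_ba, se_ba, y_ca, se_ca):
    """Indirect combination: returns (log_or_bc, se, ci_low_or, ci_high_or)."""
    y = y_ba - y_ca
    se = math.sqrt(se_ba**2 + se_ca**2)
    return y, se, math.exp(y - 1.96 * se), math.exp(y + 1.96 * se)
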