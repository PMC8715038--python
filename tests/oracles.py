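"""Independent brute-force oracles used only by the tests.

Kept deliberately separate from the package: plain-Python dynamic
programming with no seeding, no windowing and no shared code with
isforge.align, so agreement between the two is a real cross-check.
"""

from __future__ import annotations

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2  # first gap base
GAP_EXTEND = -1  # each further gap base

NEG = float("-inf")


def gotoh_local_score(a: str, b: str) -> float:
    """Best local alignment score under the affine scheme above."""
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND)
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def weighted_site_score(window: str, site: str, weights) -> float:
    """Exhaustive per-position weighted match score for attB scanning."""
    return sum(w for w, x, y in zip(weights, window, site) if x == y)
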