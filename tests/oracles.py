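"""Independent brute-force oracles used to validate the optimised code.

Everything here is deliberately naive pure-Python O(N^2) double loops
so the oracles share no code path (and no vectorisation strategy) with
the package implementations they check.
"""

import math


def chebyshev(x, i, j, m):
    return max(abs(x[i + k] - x[j + k]) for k in range(m))


def apen_bruteforce(x, m, r):
    """Approximate entropy: self-matches included, counts per template."""
    x = list(map(float, x))
    n = len(x)

    def phi(mm):
        big_m = n - mm + 1
        total = 0.0
        for i in range(big_m):
            c = 0
            for j in range(big_m):
                if chebyshev(x, i, j, mm) <= r:
                    c += 1
            total += math.log(c / big_m)
        return total / big_m

    return phi(m) - phi(m + 1)


def sampen_counts_bruteforce(x, m, r):
    """(A, B) ordered-pair counts over the first n - m template positions,
    self-matches excluded (Richman-Moorman convention)."""
    x = list(map(float, x))
    n = len(x)
    big_m = n - m
    a = b = 0
    for i in range(big_m):
        for j in range(big_m):
            if i == j:
                continue
            if chebyshev(x, i, j, m) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
            elif chebyshev(x, i, j, m + 1) <= r:  # pragma: no cover - impossible
                a += 1
    return a, b


def sampen_bruteforce(x, m, r):
    a, b = sampen_counts_bruteforce(x, m, r)
    return -math.log(a / b)
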