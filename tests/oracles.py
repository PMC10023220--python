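"""Independent reference implementations used only as test oracles."""

import math
from fractions import Fraction


def exact_hypergeom_ccdf(N: int, K: int, n: int, k: int) -> Fraction:
    """P(X >= k) by exact rational enumeration of the urn sum."""
    total = math.comb(N, n)
    upper = sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    )
    return Fraction(upper, total)


def decorated_sort(rows, key_index, descending):
    """Reference stable sort: decorate with the original position so
    stability is explicit, sort on (key, position)."""
    sign = -1 if descending else 1
    decorated = [((sign * row[key_index]), pos, row) for pos, row in enumerate(rows)]
    decorated.sort(key=lambda t: (t[0], t[1]))
    return [row for _, _, row in decorated]
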