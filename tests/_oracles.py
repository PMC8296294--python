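"""Independent step-by-step oracles, deliberately written with plain
loops and ``math`` only, so they share no code path with the package."""

import math


def topsis_oracle(matrix, weights):
    """Step-by-step TOPSIS on an already-positivised matrix.

    ``matrix`` is a list of rows; ``weights`` a list per criterion.
    Returns (d_best, d_worst, closeness) lists.
    """
    n = len(matrix)
    m = len(matrix[0])
    # column-wise Euclidean normalisation
    norms = [math.sqrt(sum(matrix[i][j] ** 2 for i in range(n))) for j in range(m)]
    z = [[matrix[i][j] / norms[j] for j in range(m)] for i in range(n)]
    z_best = [max(z[i][j] for i in range(n)) for j in range(m)]
    z_worst = [min(z[i][j] for i in range(n)) for j in range(m)]
    d_best, d_worst, close = [], [], []
    for i in range(n):
        dp = math.sqrt(sum(weights[j] * (z_best[j] - z[i][j]) ** 2 for j in range(m)))
        dm = math.sqrt(sum(weights[j] * (z_worst[j] - z[i][j]) ** 2 for j in range(m)))
        d_best.append(dp)
        d_worst.append(dm)
        close.append(dm / (dp + dm))
    return d_best, d_worst, close
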