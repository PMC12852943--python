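"""Independent brute-force reference implementations used by the tests.

Written as plain nested loops straight from the definitions, with no shared
code or vectorised shortcuts, so they can serve as oracles for the package's
array implementations.
"""

import numpy as np

from revbandit.observer import MODEL1, MODEL2


def brute_force_observer_run(grid, model, outcomes):
    """Posterior joint pmf of one option after alternating update/transition
    steps over ``outcomes``, starting from a uniform belief."""
    n_v, n_h = grid.n_v, grid.n_aux
    pmf = [[1.0 / (n_v * n_h)] * n_h for _ in range(n_v)]
    kernels = None
    if model == MODEL1:
        kernels = []
        for j in range(n_h):
            sigma = grid.aux_values[j]
            mat = [[0.0] * n_v for _ in range(n_v)]
            for k in range(n_v):
                col = []
                for i in range(n_v):
                    if sigma == 0:
                        col.append(1.0 if i == k else 0.0)
                    else:
                        d = grid.v_values[i] - grid.v_values[k]
                        col.append(np.exp(-0.5 * (d / sigma) ** 2))
                tot = sum(col)
                for i in range(n_v):
                    mat[i][k] = col[i] / tot
            kernels.append(mat)
    for x in outcomes:
        # Bayes update with the Bernoulli likelihood
        new = [[0.0] * n_h for _ in range(n_v)]
        for i in range(n_v):
            lik = grid.v_values[i] if x == 1 else 1.0 - grid.v_values[i]
            for j in range(n_h):
                new[i][j] = pmf[i][j] * lik
        tot = sum(sum(r) for r in new)
        pmf = [[c / tot for c in row] for row in new]
        # trial transition
        new = [[0.0] * n_h for _ in range(n_v)]
        if model == MODEL2:
            for j in range(n_h):
                h = grid.aux_values[j]
                p_h = sum(pmf[i][j] for i in range(n_v))
                for i in range(n_v):
                    new[i][j] = (1.0 - h) * pmf[i][j] + h * p_h / n_v
        else:
            for j in range(n_h):
                for i in range(n_v):
                    new[i][j] = sum(kernels[j][i][k] * pmf[k][j]
                                    for k in range(n_v))
        tot = sum(sum(r) for r in new)
        pmf = [[c / tot for c in row] for row in new]
    return np.array(pmf)
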