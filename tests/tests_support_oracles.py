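"""Independent oracles shared by acceptance tests.

Kept free of any import from the implementation's estimation routines: the
bivariate-normal CDF here is scipy's numerical integrator, not the Owen's-T
identity the package uses.
"""

import numpy as np
from scipy import stats


def grid_search_tetrachoric(table, step=1e-3):
    """Maximum-likelihood tetrachoric correlation by brute-force grid search."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    a = stats.norm.ppf(table.sum(axis=1).cumsum()[0] / n)
    b = stats.norm.ppf(table.sum(axis=0).cumsum()[0] / n)
    grid = np.arange(-0.995, 0.995 + step / 2, step)
    best_rho, best_ll = 0.0, -np.inf
    for rho in grid:
        p00 = stats.multivariate_normal(
            mean=[0, 0], cov=[[1, rho], [rho, 1]]
        ).cdf([a, b])
        pa = stats.norm.cdf(a)
        pb = stats.norm.cdf(b)
        probs = np.clip(
            np.array(
                [[p00, pa - p00], [pb - p00, 1 - pa - pb + p00]]
            ),
            1e-12,
            1,
        )
        ll = float((table * np.log(probs)).sum())
        if ll > best_ll:
            best_rho, best_ll = rho, ll
    return best_rho
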