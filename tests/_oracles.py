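"""Independent brute-force oracles shared by the test modules."""

import numpy as np
from scipy import stats


def residual_partials(cov):
    """Partial correlations by explicit residualisation on the covariance."""
    p = cov.shape[0]
    out = np.zeros((p, p))
    for i in range(p - 1):
        for j in range(i + 1, p):
            rest = [k for k in range(p) if k not in (i, j)]
            if rest:
                Srr = cov[np.ix_(rest, rest)]
                Sir = cov[i, rest]
                Sjr = cov[j, rest]
                beta_i = np.linalg.solve(Srr, Sir)
                beta_j = np.linalg.solve(Srr, Sjr)
                vii = cov[i, i] - Sir @ beta_i
                vjj = cov[j, j] - Sjr @ beta_j
                vij = cov[i, j] - Sir @ beta_j
            else:
                vii, vjj, vij = cov[i, i], cov[j, j], cov[i, j]
            out[i, j] = out[j, i] = vij / np.sqrt(vii * vjj)
    return out


def hittner_oracle(r_jk, r_jh, r_kh, n):
    """Back-transformed-z test for two dependent correlations, coded directly."""
    z1, z2 = np.arctanh(r_jk), np.arctanh(r_jh)
    rm = np.tanh((z1 + z2) / 2)
    num = r_kh * (1 - rm**2 - rm**2) - (rm**2 * (1 - rm**2 - rm**2 - r_kh**2)) / 2
    c = num / (1 - rm**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2 - 2 * c))
    return 2 * (1 - stats.norm.cdf(abs(z)))
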