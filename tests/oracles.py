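"""Independent brute-force oracles used by several test modules."""

import numpy as np
from scipy import integrate
from scipy import stats as sps


def rm_anova_oracle(X):
    """Within-subject sums of squares by explicit loops (no vectorisation)."""
    X = np.asarray(X, float)
    n, k = X.shape
    grand = X.sum() / (n * k)
    ss_effect = sum(n * (X[:, j].sum() / n - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (X[i, :].sum() / k - grand) ** 2 for i in range(n))
    ss_total = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_error = ss_total - ss_effect - ss_subj
    F = (ss_effect / (k - 1)) / (ss_error / ((k - 1) * (n - 1)))
    ges = ss_effect / (ss_effect + ss_subj + ss_error)
    return ss_effect, ss_subj, ss_error, F, ges


def ncf_power_oracle(f, n, m, alpha=0.05, rho=0.5):
    """RM-ANOVA power by numerical integration, conditioning the
    noncentral-chi-square numerator tail on the central denominator."""
    df1, df2 = m - 1, (n - 1) * (m - 1)
    lam = f**2 * n * m / (1 - rho)
    fcrit = sps.f.ppf(1 - alpha, df1, df2)

    def integrand(x):
        return sps.ncx2.sf(fcrit * df1 * x / df2, df1, lam) * sps.chi2.pdf(x, df2)

    val, _ = integrate.quad(integrand, 0, np.inf, limit=200)
    return val
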