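"""Independent brute-force oracles for cross-checking the implementation.

Everything here is written as plain scalar loops straight from the
defining formulas, deliberately sharing no code with the package.
"""

import math


def levin_paf_oracle(P, beta, dose):
    """Direct transcription of the dose-modified Levin formula."""
    x = P * (math.exp(beta * dose) - 1.0)
    return x / (x + 1.0)


def dl_pool_oracle(betas, ses):
    """Step-by-step DerSimonian-Laird pooling with scalar arithmetic.

    Returns (pooled beta, pooled se, Q, tau2, I2).
    """
    k = len(betas)
    w = [1.0 / s**2 for s in ses]
    sw = sum(w)
    beta_fe = sum(wi * bi for wi, bi in zip(w, betas)) / sw
    Q = sum(wi * (bi - beta_fe) ** 2 for wi, bi in zip(w, betas))
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = [1.0 / (s**2 + tau2) for s in ses]
    sw_star = sum(w_star)
    beta = sum(wi * bi for wi, bi in zip(w_star, betas)) / sw_star
    se = 1.0 / math.sqrt(sw_star)
    i2 = max(0.0, 100.0 * (Q - (k - 1)) / Q) if Q > 0 else 0.0
    return beta, se, Q, tau2, i2
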