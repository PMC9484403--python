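"""Independent numerical oracles shared across test modules."""

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def penalized_objective(beta, Fp, Fb, reg):
    """The penalized presence log-likelihood, written directly."""
    return (
        float(np.mean(Fp @ beta))
        - (logsumexp(Fb @ beta) - np.log(Fb.shape[0]))
        - float(np.sum(reg * np.abs(beta)))
    )


def solve_with_generic_optimizer(Fp, Fb, reg):
    """Maximize the penalized objective with a generic convex optimizer.

    The L1 term is handled by the standard positive/negative split
    (beta = u - v, u,v >= 0), turning the problem into smooth
    bound-constrained maximization solved by L-BFGS-B — a completely
    different algorithm from the package's proximal-gradient ascent.
    """
    k = Fp.shape[1]

    def neg(ab):
        b = ab[:k] - ab[k:]
        return -(
            np.mean(Fp @ b)
            - (logsumexp(Fb @ b) - np.log(Fb.shape[0]))
            - np.sum(reg * (ab[:k] + ab[k:]))
        )

    res = minimize(
        neg,
        np.zeros(2 * k),
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * k),
        options={"maxiter": 20000, "ftol": 1e-15, "gtol": 1e-12},
    )
    return -res.fun, res.x[:k] - res.x[k:]
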