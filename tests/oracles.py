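"""Independent brute-force solvers used to cross-check the package.

The projected-gradient minimizer here shares no code with the package's
QP path: it is a FISTA iteration with an exact Euclidean projection onto
{theta >= 0, C theta <= 1}, exploiting that the survival-sum constraint
rows have disjoint support (projection decouples into per-column capped
simplexes).
"""

import numpy as np


def project_capped_simplex(x, cap=1.0):
    """Euclidean projection of x onto {z >= 0, sum z <= cap}."""
    z = np.clip(x, 0.0, None)
    if z.sum() <= cap:
        return z
    # project onto the simplex {z >= 0, sum z = cap} (sort-based)
    u = np.sort(x)[::-1]
    css = np.cumsum(u) - cap
    rho = np.nonzero(u - css / (np.arange(len(x)) + 1) > 0)[0][-1]
    tau = css[rho] / (rho + 1)
    return np.clip(x - tau, 0.0, None)


def project_feasible(theta, C):
    out = np.clip(theta, 0.0, None)
    for row in C:
        sup = row > 0
        if sup.any():
            out[sup] = project_capped_simplex(theta[sup], 1.0)
    return out


def projected_gradient_solve(A, y, C, max_iter=300_000, tol=1e-13):
    """Minimize ||A theta - y||^2 s.t. theta >= 0, C theta <= 1.

    Accelerated projected gradient (FISTA) with gradient-based adaptive
    restart; stops when the projected-gradient residual is negligible.
    """
    norm = np.linalg.norm(A)
    if norm == 0:
        return np.zeros(A.shape[1])
    A = A / norm
    y = y / norm
    H = A.T @ A
    g = A.T @ y
    L = float(np.linalg.eigvalsh(H).max())
    theta = project_feasible(np.zeros(A.shape[1]), C)
    z = theta.copy()
    t_mom = 1.0
    for _ in range(max_iter):
        grad = H @ z - g
        theta_new = project_feasible(z - grad / L, C)
        if np.max(np.abs(theta_new - project_feasible(
                theta_new - (H @ theta_new - g) / L, C))) < tol:
            return theta_new
        if grad @ (theta_new - theta) > 0:  # adaptive restart
            t_mom = 1.0
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom ** 2))
        z = theta_new + ((t_mom - 1.0) / t_new) * (theta_new - theta)
        theta, t_mom = theta_new, t_new
    return theta


def rss(A, y, theta):
    return float(np.sum((A @ theta - y) ** 2))
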