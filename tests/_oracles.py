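"""Independent reference implementations used as test oracles.

Everything here is deliberately written from first principles (brute force,
closed forms, generic QP solving) and must stay independent of the code paths
it checks.
"""
from __future__ import annotations

import numpy as np
from scipy.optimize import minimize


def brute_force_auc(y_true, scores) -> float:
    """All-pairs concordance AUC: P(score+ > score-), ties counted 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == -1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def _fresnel_unpolarised(ct: np.ndarray, n_i: float, n_t: float) -> np.ndarray:
    st = np.sqrt(np.clip(1.0 - ct ** 2, 0.0, 1.0))
    stt = n_i / n_t * st
    out = np.ones_like(ct)
    ok = stt < 1.0
    ctt = np.sqrt(1.0 - stt[ok] ** 2)
    rs = (n_i * ct[ok] - n_t * ctt) / (n_i * ct[ok] + n_t * ctt)
    rp = (n_i * ctt - n_t * ct[ok]) / (n_i * ctt + n_t * ct[ok])
    out[ok] = 0.5 * (rs ** 2 + rp ** 2)
    return out


def dipole_reflectance(mu_a: float, mu_s_prime: float, rho_mm: float,
                       n_rel: float = 1.4) -> float:
    """Extrapolated-boundary diffusion-dipole reflectance, written out fresh.

    Hybrid fluence + flux form with boundary coefficients obtained here by
    direct Gauss-style quadrature of the unpolarised Fresnel transmission.
    """
    mu_tr = mu_a + mu_s_prime
    D = 1.0 / (3.0 * mu_tr)
    mu_eff = np.sqrt(3.0 * mu_a * mu_tr)
    z0 = 1.0 / mu_tr
    r_d = -1.440 / n_rel ** 2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
    zb = 2.0 * D * (1.0 + r_d) / (1.0 - r_d)
    zp = z0 + 2.0 * zb
    r1 = np.sqrt(z0 ** 2 + rho_mm ** 2)
    r2 = np.sqrt(zp ** 2 + rho_mm ** 2)
    # boundary coefficients via midpoint quadrature over the internal angle
    theta = (np.arange(20000) + 0.5) * (np.pi / 2.0) / 20000
    ct = np.cos(theta)
    st = np.sin(theta)
    trans = 1.0 - _fresnel_unpolarised(ct, n_rel, 1.0)
    dtheta = (np.pi / 2.0) / 20000
    c_phi = 0.5 * np.sum(trans * ct * st) * dtheta
    c_j = 1.5 * np.sum(trans * ct ** 2 * st) * dtheta
    phi = (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * np.pi * D)
    flux = (z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1 ** 2
            + zp * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2 ** 2
            ) / (4.0 * np.pi)
    return c_phi * phi + c_j * flux


def dipole_reflectance_annulus(mu_a: float, mu_s_prime: float,
                               r_in: float, r_out: float,
                               n_rel: float = 1.4, n_sub: int = 41) -> float:
    """Dipole reflectance averaged over an annulus (matches MC binning)."""
    rs = np.linspace(r_in, r_out, n_sub)
    vals = np.array([dipole_reflectance(mu_a, mu_s_prime, r, n_rel) for r in rs])
    integral = np.trapezoid(vals * 2.0 * np.pi * rs, rs)
    return integral / (np.pi * (r_out ** 2 - r_in ** 2))


def crossfade_points(vis_wl, vis_refl, nir_wl, nir_refl, lo=1095.0, hi=1130.0):
    """Brute-force evaluation of the 101-point overlap cross-fade."""
    out = []
    for i in range(101):
        lam = lo + (hi - lo) * i / 100.0
        v = np.interp(lam, vis_wl, vis_refl)
        n = np.interp(lam, nir_wl, nir_refl)
        out.append(((100 - i) * v + i * n) / 100.0)
    return np.array(out)


def qp_svm_decision(kernel_fn, X, y, Xq, C: float = 1.0) -> np.ndarray:
    """Reference soft-margin kernel SVM decision values via a generic QP solve.

    Solves the standard dual with SLSQP, polishes the solution by solving the
    KKT equality system on the detected active set, and (when every dual
    coefficient sits at a bound) sets the bias to the midpoint of its feasible
    interval — the libsvm convention.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    K = np.array([[kernel_fn(X[i], X[j]) for j in range(n)] for i in range(n)])
    Q = (y[:, None] * y[None, :]) * K
    cons = [{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}]
    res = minimize(lambda a: 0.5 * a @ Q @ a - a.sum(), np.full(n, 0.1),
                   jac=lambda a: Q @ a - np.ones(n), bounds=[(0.0, C)] * n,
                   constraints=cons, method="SLSQP",
                   options={"maxiter": 5000, "ftol": 1e-16})
    a = res.x
    w0 = None
    for _ in range(8):
        tol = 1e-7 * C
        free = (a > tol) & (a < C - tol)
        at_c = a >= C - tol
        if free.sum() == 0:
            break
        F = np.nonzero(free)[0]
        U = np.nonzero(at_c)[0]
        A = np.zeros((len(F) + 1, len(F) + 1))
        A[:len(F), :len(F)] = Q[np.ix_(F, F)]
        A[:len(F), -1] = y[F]
        A[-1, :len(F)] = y[F]
        b = np.concatenate([
            np.ones(len(F)) - Q[np.ix_(F, U)] @ (C * np.ones(len(U))),
            [-(y[U] * C).sum()],
        ])
        sol = np.linalg.lstsq(A, b, rcond=None)[0]
        a_f, w0 = sol[:-1], float(sol[-1])
        a_new = np.zeros(n)
        a_new[U] = C
        a_new[F] = np.clip(a_f, 0.0, C)
        done = (np.all(a_f > -1e-10) and np.all(a_f < C + 1e-10)
                and np.allclose(a_new, a, atol=1e-12))
        a = a_new
        if done:
            break
    coef = a * y
    if w0 is None:
        g = K @ coef
        t = y - g
        lower = [t[i] for i in range(n)
                 if (y[i] == 1 and a[i] < 1e-7) or (y[i] == -1 and a[i] > C - 1e-7)]
        upper = [t[i] for i in range(n)
                 if (y[i] == 1 and a[i] > C - 1e-7) or (y[i] == -1 and a[i] < 1e-7)]
        w0 = 0.5 * (max(lower) + min(upper)) if lower and upper else 0.0
    Kq = np.array([[kernel_fn(xq, X[i]) for i in range(n)] for xq in np.atleast_2d(Xq)])
    return Kq @ coef + w0


def minmax_scale(X: np.ndarray) -> np.ndarray:
    """Direct [-1, 1] min-max scaling (used to prepare oracle inputs)."""
    X = np.asarray(X, dtype=float)
    mx, mn = X.max(axis=0), X.min(axis=0)
    half = (mx - mn) / 2.0
    out = X - (mx + mn) / 2.0
    nz = half > 0
    out[:, nz] /= half[nz]
    out[:, ~nz] = 0.0
    return out
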