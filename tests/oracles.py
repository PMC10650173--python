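"""Independent brute-force oracles for the viscoelastic indentation model.

These deliberately avoid the package's analytic per-segment integration:
the hereditary integral is evaluated with adaptive quadrature using an
algebraic endpoint weight for the singular kernel, on the *analytic*
triangular indentation history, and the unloading auxiliary time is found
by plain bisection on that integral.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma as _gamma


class TriangularHistory:
    """Analytic triangular ramp: delta rises at v_app for t_m seconds, then
    falls at v_ret (positive numbers, m/s)."""

    def __init__(self, v_app, t_m, v_ret=None):
        self.v_app = v_app
        self.t_m = t_m
        self.v_ret = v_app if v_ret is None else v_ret
        self.delta_peak = v_app * t_m

    def delta(self, t):
        t = np.asarray(t, float)
        d = np.where(t <= self.t_m, self.v_app * t,
                     self.delta_peak - self.v_ret * (t - self.t_m))
        return np.clip(d, 0.0, None)

    def vel(self, t):
        return np.where(np.asarray(t) <= self.t_m, self.v_app, -self.v_ret)

    def g(self, t):
        """d(delta^{3/2})/dt = 1.5 sqrt(delta) * vel."""
        return 1.5 * np.sqrt(self.delta(t)) * self.vel(t)


def _kernel_integral(fun, a, b, t, alpha):
    """integral_a^b (t-xi)^(-alpha) * fun(xi) dxi with the algebraic
    singularity at xi = t handled by quad's weighted rule when b == t."""
    if b <= a:
        return 0.0
    if alpha == 0.0:
        val, _ = quad(fun, a, b, limit=200)
        return val
    if np.isclose(b, t):
        val, _ = quad(fun, a, b, weight="alg", wvar=(0.0, -alpha), limit=200)
        return val
    val, _ = quad(lambda x: (t - x) ** (-alpha) * fun(x), a, b, limit=200)
    return val


def oracle_phi(t, s, hist: TriangularHistory, E0, alpha, eta):
    """E0 * integral_s^t kernel * vel + eta * vel(t): the t1 condition."""
    tm = hist.t_m
    parts = 0.0
    if s < tm:
        parts += _kernel_integral(lambda x: hist.v_app + 0.0 * x, s, min(tm, t), t, alpha)
    if t > tm:
        parts += _kernel_integral(lambda x: -hist.v_ret + 0.0 * x, max(s, tm), t, t, alpha)
    return E0 * parts + eta * float(hist.vel(t))


def oracle_t1(t, hist: TriangularHistory, E0, alpha, eta, tol_factor=1e-9):
    """Bisection root of the vanishing rate-integral condition on [0, t_m]."""
    tm = hist.t_m
    if oracle_phi(t, 0.0, hist, E0, alpha, eta) < 0:
        return 0.0
    lo, hi = 0.0, tm
    while hi - lo > tol_factor * tm:
        mid = 0.5 * (lo + hi)
        if oracle_phi(t, mid, hist, E0, alpha, eta) >= 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def oracle_force(
    t_eval, hist: TriangularHistory, E0, alpha, eta, R, nu=0.5
) -> np.ndarray:
    """Direct numerical convolution of the PLR kernel with the analytic
    triangular history; returns force in N."""
    C = 4.0 * np.sqrt(R) / (3.0 * (1.0 - nu**2))
    tm = hist.t_m
    out = np.zeros(len(t_eval))
    for i, t in enumerate(t_eval):
        if t <= 0:
            continue
        up = t if t <= tm else oracle_t1(t, hist, E0, alpha, eta)
        if up <= 0:
            continue
        val = _kernel_integral(hist.g, 0.0, min(up, tm), t, alpha)
        if up > tm:
            val += _kernel_integral(hist.g, tm, up, t, alpha)
        F = C * E0 * val
        if t <= tm and eta > 0:
            F += C * eta * float(hist.g(t))
        out[i] = F
    return out


def hertz_closed_form_N(delta_m, E_Pa, R_m, nu=0.5):
    """Hertz force in N for a spherical indenter on a half-space."""
    return 4.0 * np.sqrt(R_m) / (3.0 * (1.0 - nu**2)) * E_Pa * delta_m**1.5


def plr_constant_speed_closed_form_N(t, E0, alpha, v, R_m, nu=0.5):
    """Approach force for delta = v*t on a PLR half-space (exact Beta-function
    convolution of the power-law kernel)."""
    pref = 4.0 * np.sqrt(R_m) / (3.0 * (1.0 - nu**2))
    shape = _gamma(2.5) * _gamma(1.0 - alpha) / _gamma(2.5 - alpha)
    return pref * E0 * v**1.5 * shape * np.asarray(t) ** (1.5 - alpha)


def brute_force_kruskal_H(groups):
    """Textbook Kruskal-Wallis H with tie correction, computed from scratch."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    r = np.arange(1, pooled.size + 1, dtype=float)
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        r[i : j + 1] = r[i : j + 1].mean()
        i = j + 1
    ranks[order] = r
    N = pooled.size
    H = 0.0
    pos = 0
    for g in groups:
        rg = ranks[pos : pos + len(g)]
        H += rg.sum() ** 2 / len(g)
        pos += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie if tie > 0 else 0.0
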