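"""Independent reference implementations used as oracles by the tests.

Everything here is written as a direct, naive transcription of the model
equations — explicit loops over nodes and compartments, a monolithic
method-of-lines integration with one small fixed step — deliberately
avoiding the vectorised assembly and the operator splitting used by the
package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import numpy as np


def naive_laplacian(weights: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Double-loop evaluation of the row-normalised graph Laplacian."""
    n = weights.shape[0]
    out = np.zeros(n)
    for m in range(n):
        pi = weights[m].sum()
        acc = 0.0
        for j in range(n):
            acc += (g[m] - g[j]) * weights[m, j]
        out[m] = acc / pi
    return out


def naive_gain(c, rate):
    """Brute-force enumeration of ordered coalescence pairs into 5 compartments."""
    gain = np.zeros(5)
    for j in range(1, 5):
        for k in range(1, 5):
            target = j + k if j + k < 5 else 5
            gain[target - 1] += 0.5 * rate * c[j - 1] * c[k - 1]
    return gain


def naive_loss(c, rate):
    loss = np.zeros(5)
    total = sum(c)
    for i in range(4):
        loss[i] = rate * c[i] * total
    return loss


def naive_abeta_rhs(u, w_prox, params, production):
    """Triple-loop transcription of the amyloid-beta equations."""
    n = u.shape[0]
    du = np.zeros_like(u)
    for m in range(n):
        gain = naive_gain(u[m], params.alpha)
        loss = naive_loss(u[m], params.alpha)
        for i in range(5):
            val = gain[i] - loss[i]
            if i < 4:
                lap = naive_laplacian(w_prox, u[:, i])[m]
                val += -params.d[i] * lap - params.sigma[i] * u[m, i]
            if i == 0:
                val += production[m]
            du[m, i] = val / params.epsilon
    return du


def naive_tau_rhs(tau, u, w_conn, params, t, seed):
    """Triple-loop transcription of the misfolded-tau equations."""
    n = tau.shape[0]
    dtau = np.zeros_like(tau)
    s = (t / params.lambda_) * np.exp(-t / params.lambda_)
    for m in range(n):
        gain = naive_gain(tau[m], params.gamma)
        loss = naive_loss(tau[m], params.gamma)
        for i in range(5):
            val = gain[i] - loss[i]
            if i < 4:
                lap = naive_laplacian(w_conn, tau[:, i])[m]
                val += -params.d_tilde[i] * lap
            if i == 0:
                val += params.c * s * seed[m]
                olig = u[m, 1] + u[m, 2] + u[m, 3]
                val += params.C_tau * max(olig - params.U_bar, 0.0)
            dtau[m, i] = val
    return dtau


class MonolithicReference:
    """Method-of-lines integration of the full coupled system.

    All state variables (u, tau and the health density f) are advanced
    together by classical RK4 with one small fixed step; the production
    functional, the deterioration rate and the upwind flux are re-evaluated
    inside every stage (no operator splitting, nothing frozen).
    """

    def __init__(self, w_conn, w_prox, params, seed, n_cells):
        self.w_conn = np.asarray(w_conn, dtype=float)
        self.w_prox = np.asarray(w_prox, dtype=float)
        self.params = params
        self.seed = np.asarray(seed, dtype=float)
        self.M = n_cells
        self.da = 1.0 / n_cells
        self.centers = (np.arange(n_cells) + 0.5) * self.da
        self.edges = np.arange(n_cells + 1) * self.da
        self.pi_conn = self.w_conn.sum(axis=1)
        self.pi_prox = self.w_prox.sum(axis=1)

    def _rhs(self, t, u, tau, f):
        p = self.params
        n = u.shape[0]
        # health functionals, re-evaluated every stage
        prod_w = (p.mu0 + self.centers) * (1.0 - self.centers)
        F = p.C_F * (f * prod_w).sum(axis=1) * self.da
        du = naive_abeta_rhs(u, self.w_prox, p, F)
        dtau = naive_tau_rhs(tau, u, self.w_conn, p, t, self.seed)
        df = np.zeros_like(f)
        for m in range(n):
            olig = u[m, 1] + u[m, 2] + u[m, 3]
            tsum = tau[m].sum()
            v = np.zeros(self.M + 1)
            for q in range(self.M + 1):
                prion = 0.0
                for k in range(self.M):
                    prion += max(self.centers[k] - self.edges[q], 0.0) * f[m, k] * self.da
                v[q] = (
                    p.C_G * prion
                    + p.C_S * (1.0 - self.edges[q]) * max(olig - p.U_bar_abeta, 0.0)
                    + p.C_T * (1.0 - self.edges[q]) * max(tsum - p.U_bar_tau, 0.0)
                )
            flux = np.zeros(self.M + 1)
            for q in range(1, self.M + 1):
                flux[q] = v[q] * f[m, q - 1]  # upwind, v >= 0
            for k in range(self.M):
                df[m, k] = -(flux[k + 1] - flux[k]) / self.da
        return du, dtau, df

    def integrate(self, u0, tau0, f0, t_end, dt):
        u = u0.copy().astype(float)
        tau = tau0.copy().astype(float)
        f = f0.copy().astype(float)
        t = 0.0
        while t < t_end - 1e-12:
            h = min(dt, t_end - t)
            ku1, kt1, kf1 = self._rhs(t, u, tau, f)
            ku2, kt2, kf2 = self._rhs(
                t + h / 2, u + h / 2 * ku1, tau + h / 2 * kt1, f + h / 2 * kf1
            )
            ku3, kt3, kf3 = self._rhs(
                t + h / 2, u + h / 2 * ku2, tau + h / 2 * kt2, f + h / 2 * kf2
            )
            ku4, kt4, kf4 = self._rhs(t + h, u + h * ku3, tau + h * kt3, f + h * kf3)
            u = u + h / 6 * (ku1 + 2 * ku2 + 2 * ku3 + ku4)
            tau = tau + h / 6 * (kt1 + 2 * kt2 + 2 * kt3 + kt4)
            f = f + h / 6 * (kf1 + 2 * kf2 + 2 * kf3 + kf4)
            t += h
        return u, tau, f
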