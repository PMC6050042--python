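"""Cox proportional-hazards partial likelihood with Efron tie handling.

This is the numerical core behind both the grouped hazard-ratio fits and
the penalized-spline relative-hazard models. Single-cell survival data
observed on a fixed imaging schedule are heavily tied (every death is
recorded at a frame time), so the Efron correction is used throughout.

The log partial likelihood for coefficients ``beta`` with an optional
quadratic roughness penalty ``(lam/2) * beta' P beta`` is maximized by
Newton-Raphson with step-halving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CoxPartialLikelihood", "newton_fit", "CoxNewtonResult"]


class CoxPartialLikelihood:
    """Efron-tie-corrected Cox partial likelihood on fixed data.

    Parameters
    ----------
    time : (n,) array
        Observed exit times (any positive scale).
    event : (n,) array of {0, 1}
        1 for an observed death, 0 for censoring.
    X : (n, p) array
        Covariate design matrix (no intercept; the baseline hazard absorbs
        any constant).
    """

    def __init__(self, time, event, X):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=int)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != time.shape[0]:
            X = X.T
        n = time.shape[0]
        if event.shape[0] != n or X.shape[0] != n:
            raise ValueError("time, event and X must have matching length")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event flags must be 0 or 1")
        order = np.argsort(time, kind="stable")
        self.time = time[order]
        self.event = event[order]
        self.X = X[order]
        self.n, self.p = self.X.shape
        self.n_events = int(self.event.sum())
        if self.n_events == 0:
            raise ValueError("no information: no events observed")
        # distinct event times and, for each, [start, stop) of the risk set
        # (all subjects with time >= t) and the indices of tied events.
        self._event_times = np.unique(self.time[self.event == 1])
        self._risk_start = np.searchsorted(self.time, self._event_times, "left")
        self._tie_idx = [
            np.flatnonzero((self.time == t) & (self.event == 1))
            for t in self._event_times
        ]

    def logpdf_grad_hess(self, beta):
        """Return (log PL, gradient, Hessian) at ``beta`` (unpenalized)."""
        beta = np.asarray(beta, dtype=float)
        eta = self.X @ beta
        eta = eta - eta.max()  # guard overflow; PL is invariant to shifts
        w = np.exp(eta)
        wX = w[:, None] * self.X
        wXX = np.einsum("i,ij,ik->ijk", w, self.X, self.X)
        # suffix sums over the risk sets
        S0 = np.concatenate([np.cumsum(w[::-1])[::-1], [0.0]])
        S1 = np.concatenate([np.cumsum(wX[::-1], axis=0)[::-1], np.zeros((1, self.p))])
        S2 = np.concatenate(
            [np.cumsum(wXX[::-1], axis=0)[::-1], np.zeros((1, self.p, self.p))]
        )
        loglik = 0.0
        grad = np.zeros(self.p)
        hess = np.zeros((self.p, self.p))
        for start, ties in zip(self._risk_start, self._tie_idx):
            d = len(ties)
            s0r, s1r, s2r = S0[start], S1[start], S2[start]
            s0d = w[ties].sum()
            s1d = wX[ties].sum(axis=0)
            s2d = wXX[ties].sum(axis=0)
            loglik += eta[ties].sum()
            grad += self.X[ties].sum(axis=0)
            # Efron weights eta_l = S0(risk) - (l/d) S0(ties); the sums over
            # l = 0..d-1 collapse to moments of 1/eta_l and l/d.
            frac = np.arange(d) / d
            e0 = s0r - frac * s0d
            inv = 1.0 / e0
            inv2 = inv * inv
            c0, c1 = inv.sum(), (frac * inv).sum()
            q0, q1, q2 = inv2.sum(), (frac * inv2).sum(), (frac**2 * inv2).sum()
            loglik -= np.log(e0).sum()
            grad -= s1r * c0 - s1d * c1
            outer_rr = np.outer(s1r, s1r)
            outer_rd = np.outer(s1r, s1d)
            outer_dd = np.outer(s1d, s1d)
            hess -= (
                s2r * c0
                - s2d * c1
                - (outer_rr * q0 - (outer_rd + outer_rd.T) * q1 + outer_dd * q2)
            )
        return loglik, grad, hess

    def loglik(self, beta):
        return self.logpdf_grad_hess(beta)[0]


@dataclass
class CoxNewtonResult:
    beta: np.ndarray
    loglik: float  # unpenalized log partial likelihood at beta
    grad_norm: float
    hessian: np.ndarray  # unpenalized Hessian at beta (negative definite)
    n_iter: int
    converged: bool


def newton_fit(
    pl: CoxPartialLikelihood,
    penalty: np.ndarray | None = None,
    lam: float = 0.0,
    beta0: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> CoxNewtonResult:
    """Maximize the (optionally penalized) log partial likelihood.

    Newton-Raphson with step-halving; convergence when the max-norm of the
    Newton step falls below ``tol``.
    """
    p = pl.p
    P = np.zeros((p, p)) if penalty is None else np.asarray(penalty, dtype=float)
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, dtype=float).copy()

    def objective(b):
        return pl.loglik(b) - 0.5 * lam * b @ P @ b

    obj = objective(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, grad, hess = pl.logpdf_grad_hess(beta)
        pgrad = grad - lam * P @ beta
        phess = hess - lam * P
        try:
            step = np.linalg.solve(-phess, pgrad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-phess, pgrad, rcond=None)[0]
        if np.max(np.abs(step)) < tol:
            converged = True
            break
        # step-halving; accept any step within the objective's noise floor
        noise = 1e-10 * (1.0 + abs(obj))
        scale = 1.0
        accepted = False
        for _ in range(30):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if np.isfinite(cand_obj) and cand_obj >= obj - noise:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            # no measurable improvement left: treat as converged
            converged = True
            break
        beta = beta + scale * step
        obj = objective(beta)
    ll, grad, hess = pl.logpdf_grad_hess(beta)
    return CoxNewtonResult(
        beta=beta,
        loglik=ll,
        grad_norm=float(np.max(np.abs(grad - lam * P @ beta))),
        hessian=hess,
        n_iter=it,
        converged=converged or np.max(np.abs(grad - lam * P @ beta)) < 1e-4,
    )
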