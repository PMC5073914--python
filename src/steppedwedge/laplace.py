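"""Laplace-approximated marginal likelihood for the nested random intercepts.

The random-effect vector stacks one intercept per site-quarter cell
(r_0jk, variance ``var_t``) and one per site (u_00k, variance
``var_s``). Conditional on the fixed effects, the joint negative log
posterior over all effects is strictly convex (log-concave ordinal
likelihood plus Gaussian priors), so a damped Newton iteration finds
the joint mode; the marginal likelihood is then approximated by the
Gaussian integral around it.

The Newton system is block arrowhead per site — cells only couple
through their site's intercept — so each step reduces to a diagonal
solve plus a scalar Schur complement per site. Everything is
vectorized across sites; cost per objective evaluation is independent
of the number of respondents (the design is count-aggregated).
"""

from __future__ import annotations

import numpy as np

from .model import ModelDesign, _nll_d1_d2

_LOG2PI = np.log(2.0 * np.pi)


class LaplaceObjective:
    """Profile marginal NLL with warm-started random-effect modes."""

    def __init__(self, design: ModelDesign, inner_tol: float = 1e-10, max_inner: int = 100):
        self.design = design
        self.inner_tol = inner_tol
        self.max_inner = max_inner
        self.r = np.zeros(design.n_cells)
        self.u = np.zeros(design.n_sites)
        # site-of-cell segment bookkeeping
        self.cell_site = design.cell_site
        self.n_cells = design.n_cells
        self.n_sites = design.n_sites

    def reset(self) -> None:
        self.r[:] = 0.0
        self.u[:] = 0.0

    def _joint_nll(self, lp, r, u, var_t, var_s, d2, d3):
        s = lp + u[self.cell_site][self.design.cell_idx] + r[self.design.cell_idx]
        nll, d1, d2w = _nll_d1_d2(s, self.design.counts, d2, d3)
        pen = 0.5 * np.sum(r**2) / var_t + 0.5 * np.sum(u**2) / var_s
        return nll + pen, d1, d2w

    def marginal_nll(self, beta, d2, d3, var_t, var_s) -> float:
        """Laplace marginal NLL at the given parameters.

        Inner Newton iterations (analytic gradient and Hessian, global
        step halving) converge the 117-dimensional joint mode; the mode
        is cached between calls so successive evaluations during outer
        optimization warm-start.
        """
        design = self.design
        lp = design.X @ beta
        var_t = max(float(var_t), 1e-12)
        var_s = max(float(var_s), 1e-12)
        r, u = self.r.copy(), self.u.copy()

        obj, d1, d2w = self._joint_nll(lp, r, u, var_t, var_s, d2, d3)
        for _ in range(self.max_inner):
            g_cell = np.bincount(design.cell_idx, weights=d1, minlength=self.n_cells)
            W = np.bincount(design.cell_idx, weights=d2w, minlength=self.n_cells)
            g_r = g_cell + r / var_t
            g_u = np.bincount(self.cell_site, weights=g_cell, minlength=self.n_sites) + u / var_s
            gmax = max(np.max(np.abs(g_r)), np.max(np.abs(g_u)))
            if gmax < self.inner_tol * max(1.0, design.n_obs / (self.n_cells + self.n_sites)):
                break
            D = W + 1.0 / var_t
            huu = np.bincount(self.cell_site, weights=W, minlength=self.n_sites) + 1.0 / var_s
            WD = W / D
            S = huu - np.bincount(self.cell_site, weights=W * WD, minlength=self.n_sites)
            xu = (g_u - np.bincount(self.cell_site, weights=WD * g_r, minlength=self.n_sites)) / S
            xr = (g_r - W * xu[self.cell_site]) / D
            # damped Newton: halve the global step until the objective drops
            alpha = 1.0
            for _ls in range(30):
                r_new = r - alpha * xr
                u_new = u - alpha * xu
                obj_new, d1_new, d2w_new = self._joint_nll(lp, r_new, u_new, var_t, var_s, d2, d3)
                if obj_new <= obj + 1e-12 * abs(obj):
                    break
                alpha *= 0.5
            r, u, obj, d1, d2w = r_new, u_new, obj_new, d1_new, d2w_new

        # final curvature at the mode for the Gaussian integral
        W = np.bincount(design.cell_idx, weights=d2w, minlength=self.n_cells)
        D = W + 1.0 / var_t
        huu = np.bincount(self.cell_site, weights=W, minlength=self.n_sites) + 1.0 / var_s
        S = huu - np.bincount(self.cell_site, weights=W * (W / D), minlength=self.n_sites)
        logdet = np.sum(np.log(D)) + np.sum(np.log(S))

        self.r, self.u = r, u  # warm start for the next evaluation
        # prior normalizers + Laplace correction; the (2*pi) factors cancel
        return float(
            obj
            + 0.5 * (self.n_cells * np.log(var_t) + self.n_sites * np.log(var_s))
            + 0.5 * logdet
        )
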