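"""Polak-Ribiere conjugate gradient with Armijo backtracking.

Shared by the 2D surrogate registration and the 3D model fit.  The line
search only accepts steps that decrease the objective, so the objective is
non-increasing across accepted iterations by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class CGResult:
    x: np.ndarray
    fun: float
    n_iter: int
    converged: bool
    history: list = field(default_factory=list)
    message: str = ""


def minimize_cg(
    fun_grad,
    x0: np.ndarray,
    max_iter: int = 50,
    grad_tol: float = 1e-5,
    armijo_c1: float = 1e-4,
    max_backtracks: int = 25,
    grad_norm_ref: float | None = None,
    fun_only=None,
    precond=None,
    callback=None,
) -> CGResult:
    """Minimise ``fun_grad(x) -> (f, g)``.

    ``grad_tol`` is relative to ``grad_norm_ref`` (default: the gradient
    norm at ``x0``).  Pass an explicit reference when warm-starting close
    to an optimum, otherwise the relative threshold is met trivially.
    ``fun_only(x) -> f`` (optional) evaluates the objective without its
    gradient; the line search uses it for trial points, with the gradient
    computed once at the accepted point.
    ``precond`` (optional) is a positive diagonal preconditioner: an array
    approximating the objective's curvature per coordinate; search
    directions use the preconditioned gradient ``g / precond``.
    """
    x = np.asarray(x0, dtype=np.float64).copy()
    f, g = fun_grad(x)
    g0_norm = float(grad_norm_ref) if grad_norm_ref else np.linalg.norm(g)
    history = [f]
    if g0_norm == 0.0:
        return CGResult(x=x, fun=f, n_iter=0, converged=True, history=history, message="zero gradient")
    if np.linalg.norm(g) <= grad_tol * g0_norm:
        return CGResult(x=x, fun=f, n_iter=0, converged=True, history=history, message="already converged")

    def apply_m(v):
        return v / precond if precond is not None else v

    z = apply_m(g)
    d = -z
    # initial step guess: unit-ish displacement change
    alpha = 1.0 if precond is not None else 1.0 / max(np.max(np.abs(g)), 1e-30)
    for it in range(1, max_iter + 1):
        gd = float(g @ d)
        if gd >= 0.0:  # restart on a non-descent direction
            d = -z
            gd = float(g @ d)
        accepted = False
        have_grad = False
        a = alpha
        for trial in range(max_backtracks):
            x_new = x + a * d
            # first trial computes the gradient too (usually accepted and
            # reused); backtracked trials evaluate the objective only
            if trial == 0 or fun_only is None:
                f_new, g_new = fun_grad(x_new)
                have_grad = True
            else:
                f_new = fun_only(x_new)
                have_grad = False
            if f_new <= f + armijo_c1 * a * gd:
                accepted = True
                break
            a *= 0.5
        if accepted and not have_grad:
            f_new, g_new = fun_grad(x_new)
        if not accepted:
            return CGResult(
                x=x, fun=f, n_iter=it - 1, converged=False, history=history,
                message="line search failed; returning best-so-far",
            )
        alpha = a * 2.0  # mild step growth for the next iteration
        g_prev, z_prev = g, z
        x, f, g = x_new, f_new, g_new
        history.append(f)
        if callback is not None:
            callback(it, x, f, g)
        if np.linalg.norm(g) <= grad_tol * g0_norm:
            return CGResult(x=x, fun=f, n_iter=it, converged=True, history=history)
        z = apply_m(g)
        beta = max(0.0, float(z @ (g - g_prev)) / float(z_prev @ g_prev))
        d = -z + beta * d
    return CGResult(x=x, fun=f, n_iter=max_iter, converged=False, history=history,
                    message="max iterations reached")
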