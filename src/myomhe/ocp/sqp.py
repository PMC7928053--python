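"""Gauss-Newton SQP for bound-constrained nonlinear least squares with
equality (shooting-defect) constraints.

The solver is tailored to the structure every problem in this package
shares: cost = 0.5 ||r(z)||^2, equality constraints c(z) = 0, simple
bounds lb <= z <= ub (equalities where lb == ub).  Each iteration builds
the Gauss-Newton Hessian H = Jr' Jr + damping, solves the convex QP

    min  0.5 p'Hp + g'p   s.t.  Jc p = -c,  lb - z <= p <= ub - z

by a primal active-set method on the bounds (sparse LU of the reduced,
equilibrated KKT system), then globalizes with a filter line search
(feasibility/cost dominance) plus adaptive Levenberg damping.  Warm
starts reuse both the primal iterate and the bound active set, which is
what makes the moving-horizon loop cheap: consecutive windows differ by
one measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class SqpOptions:
    max_iter: int = 60
    tol_feas: float = 1e-8          # max-norm on defects
    tol_stat: float = 1e-4          # projected-gradient max-norm (scaled)
    ls_max: int = 12
    damping: float = 1e-7           # relative Levenberg damping floor on H
    damping_init: float | None = None  # starting damping (default: floor)
    max_active_set_passes: int = 30
    dual_reg: float = 1e-11
    trust_radius: float = 50.0      # inf-norm step cap (loose safeguard:
    #                                 a hard cap risks making the equality
    #                                 constraints of the QP infeasible)
    trust_max: float = 100.0
    trust_min: float = 2.0
    theta_growth: float = 1.2       # allowed per-step growth of the
    theta_growth_abs: float = 1e-3  # constraint violation (rel, abs)
    jac_every: int = 1              # recompute the defect Jacobian every
    #                                 n-th iteration (1 = exact SQP); the
    #                                 complex-step pass dominates runtime
    track_best_feasibility: bool = False  # return the most feasible
    #                                       iterate on failure (pure
    #                                       restoration solves only)
    verbose: bool = False


@dataclass
class ActiveSet:
    lower: np.ndarray
    upper: np.ndarray


@dataclass
class SqpResult:
    z: np.ndarray
    success: bool
    iterations: int
    feas: float
    stat: float
    cost: float
    message: str
    active_set: ActiveSet | None = None
    n_factorizations: int = 0
    multipliers: np.ndarray | None = None


def _solve_qp(H, g, Jc, c, lo, hi, fixed, act: ActiveSet, opts: SqpOptions):
    """Primal active-set solve of the bound+equality QP; returns p, nu."""
    n = len(g)
    m = len(c)
    act_lo = act.lower | fixed
    act_hi = act.upper & ~act_lo
    n_fact = 0
    p = np.zeros(n)
    nu = np.zeros(m)
    n_release = 0
    for _ in range(opts.max_active_set_passes):
        pin = act_lo | act_hi
        p = np.where(act_lo, lo, 0.0) + np.where(act_hi, hi, 0.0)
        free = ~pin
        nf = int(free.sum())
        Hf = H[free][:, free]
        Jf = Jc[:, free].tocsr()
        # constraint rows whose variables are all pinned are redundant
        # (the transcription keeps activation-state bounds slack for
        # exactly this reason); drop them to keep the KKT nonsingular
        row_live = np.asarray(
            np.abs(Jf).sum(axis=1)).ravel() > 1e-12
        Jf_l = Jf[row_live]
        ml = int(row_live.sum())
        rhs = np.concatenate([
            -(g[free] + H[free][:, pin] @ p[pin]),
            -(c + Jc[:, pin] @ p[pin])[row_live],
        ])
        if nf + ml == 0:
            nu = np.zeros(m)
            break
        K = sp.bmat([[Hf, Jf_l.T],
                     [Jf_l, -opts.dual_reg * sp.identity(ml)]], format="csc")
        # symmetric equilibration + iterative refinement: the cost
        # weights span ~10 orders of magnitude (printed marker weight
        # 1e9 vs 1e-4 regularization), far beyond what a raw LU solve
        # can absorb
        row_inf = np.asarray(np.abs(K).max(axis=1).todense()).ravel()
        d = 1.0 / np.sqrt(np.maximum(row_inf, 1e-12))
        D = sp.diags(d)
        Ks = (D @ K @ D).tocsc()
        lu = spla.splu(Ks)
        rhs_s = d * rhs
        sol = lu.solve(rhs_s)
        for _ in range(2):
            resid = rhs_s - Ks @ sol
            sol = sol + lu.solve(resid)
        sol = d * sol
        n_fact += 1
        p[free] = sol[:nf]
        nu = np.zeros(m)
        nu[row_live] = sol[nf:]
        viol_lo = free & (p < lo - 1e-12)
        viol_hi = free & (p > hi + 1e-12)
        if viol_lo.any() or viol_hi.any():
            act_lo |= viol_lo
            act_hi |= viol_hi
            continue
        # multiplier (sign) check on non-fixed active bounds; release all
        # wrong-signed bounds at once, but only a few times per QP
        # (cycling guard) -- the outer SQP warm-starts the set anyway
        grad_l = H @ p + g + Jc.T @ nu
        scale = 1.0 + np.abs(g).max()
        rel_lo = act_lo & ~fixed & (grad_l < -1e-8 * scale)
        rel_hi = act_hi & ~fixed & (grad_l > 1e-8 * scale)
        if (rel_lo.any() or rel_hi.any()) and n_release < 3:
            act_lo &= ~rel_lo
            act_hi &= ~rel_hi
            n_release += 1
            continue
        break
    # safety: clip into the box (active-set pass cap may leave violations)
    p = np.clip(p, lo, hi)
    return p, nu, ActiveSet(act_lo & ~fixed, act_hi & ~fixed), n_fact


def _projected_stat(grad_l, z, lb, ub, fixed):
    at_lo = (z - lb < 1e-10) & ~fixed
    at_hi = (ub - z < 1e-10) & ~fixed
    free = ~(at_lo | at_hi | fixed)
    stat = 0.0
    if free.any():
        stat = np.abs(grad_l[free]).max()
    if at_lo.any():
        stat = max(stat, -min(0.0, grad_l[at_lo].min()))
    if at_hi.any():
        stat = max(stat, max(0.0, grad_l[at_hi].max()))
    return stat


def newton_restoration(problem, z: np.ndarray, target: float = 1e-9,
                       max_iter: int = 10) -> tuple[np.ndarray, float]:
    """Minimum-norm Newton projection onto the constraint manifold.

    Solves J J' y = -c and steps along J' y over the non-fixed,
    non-bound-active variables only (a clipped step would destroy the
    quadratic contraction).  A perfectly scaled subproblem, so it
    converges to machine-level defects where the cost-laden KKT stalls.
    Returns the projected point and its max-norm violation.
    """
    z = np.asarray(z, float).copy()
    lb, ub = problem.lb, problem.ub
    fixed = (ub - lb) < 1e-14
    c = problem.constraints(z)
    feas = float(np.abs(c).max())
    norm2 = float(np.linalg.norm(c))
    for _ in range(max_iter):
        if feas <= target:
            break
        c, Jc = problem.constraint_jacobian(z)
        Jc = sp.csr_matrix(Jc)
        # two passes: bound-active variables participate unless the
        # projection step would push them outside the box (a clipped
        # step destroys the Newton contraction)
        pinned = fixed.copy()
        for _pass in range(2):
            Jf = Jc[:, ~pinned]
            JJt = (Jf @ Jf.T).tocsc() + 1e-12 * sp.identity(Jc.shape[0])
            y = spla.splu(JJt).solve(-c)
            p = np.zeros_like(z)
            p[~pinned] = Jf.T @ y
            outward = ((z + p < lb - 1e-12) | (z + p > ub + 1e-12))
            if not outward.any():
                break
            pinned = pinned | outward
        accepted = False
        for alpha in (1.0, 0.5, 0.25, 0.125):
            z_new = np.clip(z + alpha * p, lb, ub)
            c_new = problem.constraints(z_new)
            if float(np.linalg.norm(c_new)) < 0.999 * norm2:
                z = z_new
                feas = float(np.abs(c_new).max())
                norm2 = float(np.linalg.norm(c_new))
                accepted = True
                break
        if not accepted:
            break
    return z, feas


def solve_sqp(problem, z0: np.ndarray, options: SqpOptions | None = None,
              active_set: ActiveSet | None = None) -> SqpResult:
    """Solve one transcribed NLP; ``problem`` is a MultipleShootingNLP."""
    opts = options or SqpOptions()
    lb, ub = problem.lb, problem.ub
    fixed = (ub - lb) < 1e-14
    z = np.clip(np.asarray(z0, float).copy(), lb, ub)
    n = len(z)
    act = active_set or ActiveSet(np.zeros(n, bool), np.zeros(n, bool))
    act = ActiveSet(act.lower.copy(), act.upper.copy())
    mu = opts.damping_init if opts.damping_init is not None else opts.damping
    delta = opts.trust_radius
    n_fact_total = 0
    message = "max iterations reached"
    success = False
    feas = np.inf
    stat = np.inf
    cost = np.inf
    it = 0
    prev_cost = None
    stall_count = 0
    best_cost_seen = np.inf
    best_feas_seen = np.inf
    last_improve_it = 0
    filt: list[tuple[float, float]] = []  # (theta, f) pairs, filter method
    theta_max = None                      # feasibility envelope

    def _filter_ok(theta_t, f_t):
        return all(theta_t <= 0.99 * th or f_t <= fv - 1e-5 * th
                   for th, fv in filt)

    best = None  # (feas, cost, z) of the most feasible iterate seen

    Jc_cache = None
    accepted_last = True
    while it < opts.max_iter:
        it += 1
        if opts.jac_every <= 1 or Jc_cache is None \
                or (it - 1) % opts.jac_every == 0 or not accepted_last:
            r, Jr, c, Jc = problem.eval_all(z)
            Jc_cache = Jc
        else:
            r, Jr, c = problem.eval_cost_jac(z)
            Jc = Jc_cache
        cost = 0.5 * float(r @ r)
        theta0 = float(np.abs(c).sum()) if len(c) else 0.0
        feas = float(np.abs(c).max()) if len(c) else 0.0
        if best is None or feas < best[0]:
            best = (feas, cost, z.copy())
        progressed = False
        if cost < best_cost_seen - 1e-9 * (1.0 + abs(cost)):
            best_cost_seen = cost
            progressed = True
        if feas < 0.7 * best_feas_seen:
            best_feas_seen = feas
            progressed = True
        if progressed:
            last_improve_it = it
        elif (it - last_improve_it >= 25
                and not opts.track_best_feasibility):
            success = feas <= max(opts.tol_feas, 1e-7)
            message = "cost and feasibility plateau"
            break
        g = Jr.T @ r
        H = (Jr.T @ Jr).tocsr()
        d = H.diagonal()
        H = H + sp.diags(mu * (d + 1e-3 * (d.mean() + 1.0)))

        p, nu, act, nf = _solve_qp(H, g, Jc, c,
                                   np.maximum(lb - z, -delta),
                                   np.minimum(ub - z, delta), fixed,
                                   act, opts)
        n_fact_total += nf
        grad_l = g + Jc.T @ nu
        g_scale = 1.0 + float(np.abs(g).max())
        stat = _projected_stat(grad_l, z, lb, ub, fixed) / g_scale
        if feas <= opts.tol_feas and stat <= opts.tol_stat:
            success = True
            message = "KKT tolerances met"
            break
        # secondary stop: feasible and the cost has stopped moving
        # (weakly-determined directions can keep the projected gradient
        # above tol while the solution is numerically converged)
        if feas <= opts.tol_feas and prev_cost is not None and \
                abs(prev_cost - cost) <= 1e-11 * (1.0 + abs(cost)):
            stall_count += 1
            if stall_count >= 2:
                success = True
                message = "cost stationary at feasible point"
                break
        else:
            stall_count = 0
        prev_cost = cost if feas <= opts.tol_feas else None

        # filter line search with a feasibility envelope and a switching
        # condition: pure cost steps are only allowed near the feasible
        # manifold; otherwise the constraint violation must contract
        if theta_max is None:
            theta_max = 1e3 * max(1.0, theta0)
        deriv = float(g @ p)
        theta_small = max(100.0 * opts.tol_feas, 1e-8 * theta_max)
        alpha = 1.0
        accepted = False
        add_to_filter = False
        for _ in range(opts.ls_max):
            zt = np.clip(z + alpha * p, lb, ub)
            rt, ct = problem.eval_vals(zt)
            f_t = 0.5 * float(rt @ rt)
            theta_t = float(np.abs(ct).sum()) if len(ct) else 0.0
            if (not np.isfinite(f_t) or not np.isfinite(theta_t)
                    or theta_t > theta_max):
                alpha *= 0.5
                continue
            if not _filter_ok(theta_t, f_t):
                alpha *= 0.5
                continue
            switching = deriv < 0 and theta0 <= theta_small
            if switching:
                armijo = (f_t <= cost + 1e-4 * alpha * deriv
                          + 1e-12 * (1 + cost))
                suff = theta_t <= max((1 - 1e-5) * theta0,
                                      0.1 * opts.tol_feas)
                if armijo or suff:
                    accepted = True
                    add_to_filter = not armijo
                    break
            else:
                suff = (theta_t <= (1 - 1e-5) * theta0
                        or f_t <= cost - 1e-5 * theta0)
                if suff and theta_t <= (opts.theta_growth * theta0
                                        + opts.theta_growth_abs):
                    accepted = True
                    add_to_filter = True
                    break
            alpha *= 0.5
        accepted_last = accepted
        if accepted:
            if add_to_filter:
                filt.append((max(0.999 * theta0, 0.0),
                             cost - 1e-6 * theta0))
            step = float(np.abs(alpha * p).max())
            z = zt
            # Levenberg-Marquardt style damping: relax only on full
            # steps, stiffen when the line search truncates them
            if alpha == 1.0:
                mu = max(mu * 0.3, opts.damping)
                delta = min(delta * 1.5, opts.trust_max)
            elif alpha < 0.25:
                mu = min(mu * 5.0, 1e6)
                delta = max(delta * 0.5, opts.trust_min)
            theta_max = max(0.5 * theta_max,
                            10.0 * max(theta0, opts.tol_feas))
            if step < 1e-11:
                success = feas <= max(opts.tol_feas, 1e-7)
                message = ("stationary point (step stall)" if success
                           else "step size collapsed")
                break
        else:
            delta = max(delta * 0.5, opts.trust_min)
            mu = max(mu * 10.0, 1e-6)
            filt = filt[-40:]
            if mu > 1e10:
                message = "line search failed (damping exhausted)"
                break
        if opts.verbose:
            print(f"  it {it:3d} cost {cost:.6e} feas {feas:.2e} "
                  f"stat {stat:.2e} alpha {alpha:.4f} mu {mu:.1e} "
                  f"acc {accepted}")

    if (opts.track_best_feasibility and not success
            and best is not None and best[0] < feas):
        feas, cost, z = best
        message += " (returning best-feasibility iterate)"
    return SqpResult(z=z, success=success, iterations=it, feas=feas,
                     stat=stat, cost=cost, message=message,
                     active_set=act, n_factorizations=n_fact_total,
                     multipliers=nu if "nu" in locals() else None)
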