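"""Flux-inference models and their results object.

Three estimators share one interface:

``Pheflux``
    Maximize the Shannon entropy of fluxes per mRNA over the steady-state
    polytope, at a fixed total flux ``sum(v) = V``; equivalently (selectable
    through ``formulation="kl"``) minimize the forward KL divergence between
    the normalized fluxome and transcriptome.  Strictly concave at fixed V,
    so the fluxome is unique.
``Spot``
    Maximize the inner product of flux and expression on the unit-norm ball
    intersected with the polytope (the flux/transcriptome correlation
    baseline); the reported fluxes are rescaled to ``sum(v) = V`` for
    comparability.
``FBAMinL2``
    Flux balance analysis maximizing biomass, followed by minimization of
    the sum of squared fluxes at the fixed biomass optimum; ignores
    expression entirely.

Every ``fit()`` returns a :class:`FluxSolution` carrying the split and net
fluxes, the objective value, solver diagnostics and a ``summary()`` table.
Functional wrappers (``solve_pheflux``, ``solve_pheflux_kl``, ``solve_spot``,
``solve_fba_min_l2``) expose the same computations as plain calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import (Bounds, LinearConstraint, NonlinearConstraint,
                            linprog, minimize)

from .exceptions import UnboundedProblemError, ValidationError
from .expression import ExpressionProfile, ReactionExpression, map_expression
from .network import MetabolicNetwork, SplitNetwork, split_reversible

__all__ = [
    "FluxSolution",
    "Pheflux",
    "Spot",
    "FBAMinL2",
    "solve_pheflux",
    "solve_pheflux_kl",
    "solve_spot",
    "solve_fba_min_l2",
]

#: Relative tolerance (times V_total) on steady state / bounds for a
#: solution to be reported as optimal.
FEASIBILITY_RTOL = 1e-6


@dataclass
class FluxSolution:
    """Result of a flux-inference fit.

    Attributes
    ----------
    method : {"pheflux", "spot", "fba_min_l2"}
    status : {"optimal", "infeasible", "iteration_limit", "numerical_failure"}
    v : pandas.Series or None
        Nonnegative flux per split reaction (mmol/gDW/h).
    net : pandas.Series or None
        Net flux per original reaction, ``v_f - v_r``.
    V_total : float
        Total split flux of the returned vector.
    objective_value : float
        Entropy (nats) for pheflux, correlation objective for SPOT, sum of
        squared fluxes for FBA+min-l2; NaN when not optimal.
    diagnostics : dict
        Solver iterations, residuals, and method-specific extras.
    """

    method: str
    status: str
    v: pd.Series | None
    net: pd.Series | None
    V_total: float
    objective_value: float
    diagnostics: dict = field(default_factory=dict)
    expression: ReactionExpression | None = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def to_frame(self) -> pd.DataFrame:
        """Flux table: one row per original reaction."""
        if self.net is None:
            return pd.DataFrame(columns=[
                "reaction_id", "net_flux", "forward_flux", "reverse_flux",
                "expression_g", "imputed",
            ])
        rows = []
        split = self.diagnostics.get("pairing", {})
        gmap = {}
        imputed = frozenset()
        if self.expression is not None:
            gmap = dict(zip(self.expression.split_reaction_ids,
                            self.expression.g))
            imputed = self.expression.imputed
        for rid, netv in self.net.items():
            fwd = self.v.get(rid, np.nan) if self.v is not None else np.nan
            rev = self.v.get(rid + "__rev", 0.0) if self.v is not None else np.nan
            rows.append({
                "reaction_id": rid,
                "net_flux": netv,
                "forward_flux": fwd,
                "reverse_flux": rev,
                "expression_g": gmap.get(rid, np.nan),
                "imputed": rid in imputed,
            })
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self, top: int = 10) -> str:
        """Plain-text fit report in the style of statistical model results."""
        lines = [
            "Flux inference results",
            "=" * 58,
            f"{'method:':<24}{self.method}",
            f"{'status:':<24}{self.status}",
            f"{'objective value:':<24}{self.objective_value:.6g}",
            f"{'total flux V:':<24}{self.V_total:.6g}",
        ]
        for key in ("n_iterations", "steady_state_residual",
                    "total_flux_residual", "biomass_flux"):
            if key in self.diagnostics:
                val = self.diagnostics[key]
                val = f"{val:.6g}" if isinstance(val, float) else str(val)
                lines.append(f"{key + ':':<24}{val}")
        if self.net is not None:
            lines.append("-" * 58)
            lines.append(f"largest |net flux| ({min(top, len(self.net))} of "
                         f"{len(self.net)} reactions):")
            ordered = self.net.reindex(
                self.net.abs().sort_values(ascending=False).index)
            for rid, val in ordered.head(top).items():
                lines.append(f"  {rid:<28}{val:>14.6g}")
        lines.append("=" * 58)
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# shared solver plumbing
# ---------------------------------------------------------------------------

def _feasible_point(A_eq, b_eq, lb, ub):
    """A point of {A_eq x = b_eq, lb <= x <= ub}, or None if empty."""
    res = linprog(np.zeros(A_eq.shape[1]), A_eq=A_eq, b_eq=b_eq,
                  bounds=np.column_stack([lb, ub]), method="highs")
    return res.x if res.status == 0 else None


_STATUS_MAP = {0: "iteration_limit", 1: "optimal", 2: "optimal",
               3: "numerical_failure", 4: "numerical_failure"}


def _empty_solution(method: str, status: str, diagnostics=None) -> FluxSolution:
    return FluxSolution(method=method, status=status, v=None, net=None,
                        V_total=np.nan, objective_value=np.nan,
                        diagnostics=diagnostics or {})


def _package(method, split, x, objective_value, status, diagnostics,
             expression=None) -> FluxSolution:
    v = pd.Series(x, index=split.split_reaction_ids)
    net = pd.Series(split.net_flux(x), index=split.base.reaction_ids)
    V = float(np.sum(x))
    resid = float(np.abs(split.S_split @ x).max())
    diagnostics = dict(diagnostics)
    diagnostics["steady_state_residual"] = resid
    if status == "optimal" and resid > FEASIBILITY_RTOL * max(V, 1.0):
        status = "numerical_failure"
    return FluxSolution(method=method, status=status, v=v, net=net,
                        V_total=V, objective_value=objective_value,
                        diagnostics=diagnostics, expression=expression)


class _SplitModelBase:
    """Common constructor: accept a network or split, and raw or mapped
    expression; map through GPRs when needed."""

    def __init__(self, network, expression, epsilon: float = 1e-8,
                 or_mode: str = "sum"):
        if isinstance(network, SplitNetwork):
            self.split = network
        elif isinstance(network, MetabolicNetwork):
            self.split = split_reversible(network)
        else:
            raise TypeError("network must be MetabolicNetwork or SplitNetwork")
        if isinstance(expression, ReactionExpression):
            self.rx = expression
        elif isinstance(expression, ExpressionProfile):
            self.rx = map_expression(self.split, expression, epsilon=epsilon,
                                     or_mode=or_mode)
        else:
            raise TypeError(
                "expression must be ExpressionProfile or ReactionExpression"
            )
        if len(self.rx.g) != self.split.n_split:
            raise ValidationError(
                "expression vector not aligned to split network"
            )
        self.epsilon = float(epsilon)


class Pheflux(_SplitModelBase):
    """Maximum-entropy fluxome inference conditioned on a transcriptome.

    Parameters
    ----------
    network : MetabolicNetwork or SplitNetwork
    expression : ExpressionProfile or ReactionExpression
        Gene-level profile (mapped through GPRs) or an already-mapped
        per-reaction vector.
    V_total : float
        Fixed total split flux ``sum(v) = V`` (default 1000, chosen large so
        no reaction is forced against its bound).
    epsilon : float
        Smoothing inside the logarithm (default 1e-8).
    formulation : {"entropy", "kl"}
        Optimize -H_g(v) directly, or the equivalent linearized KL form
        ``sum v_i log(v_i/g_i)``; both return the same fluxome.
    """

    method = "pheflux"

    def __init__(self, network, expression, V_total: float = 1000.0,
                 epsilon: float = 1e-8, formulation: str = "entropy",
                 or_mode: str = "sum"):
        super().__init__(network, expression, epsilon=epsilon, or_mode=or_mode)
        if V_total <= 0:
            raise ValueError("V_total must be positive")
        if formulation not in ("entropy", "kl"):
            raise ValueError("formulation must be 'entropy' or 'kl'")
        self.V_total = float(V_total)
        self.formulation = formulation

    # objective callables -------------------------------------------------
    def _objective(self):
        g = self.rx.g
        eps = self.epsilon
        V = self.V_total
        ge = g + eps
        if self.formulation == "kl":
            # minimize f(v) = sum v_i log((v_i+eps)/(g_i+eps))
            def f(v):
                vp = np.maximum(v, 0.0) + eps
                return float(vp @ np.log(vp / ge))

            def grad(v):
                vp = np.maximum(v, 0.0) + eps
                return np.log(vp / ge) + 1.0

            def hess(v):
                vp = np.maximum(v, 0.0) + eps
                return sp.diags(1.0 / vp)
        else:
            # minimize -H_g(v) with V held at the constraint value
            geV = ge * V

            def f(v):
                vp = np.maximum(v, 0.0) + eps
                return float(v @ np.log(vp / geV)) / V

            def grad(v):
                vp = np.maximum(v, 0.0) + eps
                return (np.log(vp / geV) + v / vp) / V

            def hess(v):
                vp = np.maximum(v, 0.0) + eps
                return sp.diags((1.0 / vp + eps / vp ** 2) / V)
        return f, grad, hess

    def fit(self, x0=None, solver_options: dict | None = None) -> FluxSolution:
        """Solve the entropy program; returns a :class:`FluxSolution`.

        ``x0`` overrides the default start (the expression-proportional
        point ``V * g / sum(g)`` clipped to bounds); the optimum is unique,
        so the start only affects iteration counts.
        """
        split, g, V = self.split, self.rx.g, self.V_total
        M, N = split.S_split.shape
        opts = dict(gtol=1e-9, xtol=1e-11, maxiter=3000)
        opts.update(solver_options or {})
        A = np.vstack([split.S_split, np.ones((1, N))])
        b = np.r_[np.zeros(M), V]
        feas = _feasible_point(A, b, split.lb_split, split.ub_split)
        if feas is None:
            return _empty_solution(self.method, "infeasible")
        if x0 is None:
            x0 = np.clip(V * g / g.sum(), split.lb_split, split.ub_split)
        else:
            x0 = np.clip(np.asarray(x0, dtype=float),
                         split.lb_split, split.ub_split)
        f, grad, hess = self._objective()
        cons = LinearConstraint(sp.csr_matrix(A), b, b)
        res = minimize(f, x0, jac=grad, hess=hess, method="trust-constr",
                       constraints=[cons],
                       bounds=Bounds(split.lb_split, split.ub_split),
                       options=opts)
        status = _STATUS_MAP.get(res.status, "numerical_failure")
        if status != "optimal" and res.constr_violation < FEASIBILITY_RTOL * V:
            # retry once from the interior feasible point
            res2 = minimize(f, feas, jac=grad, hess=hess,
                            method="trust-constr", constraints=[cons],
                            bounds=Bounds(split.lb_split, split.ub_split),
                            options=opts)
            if _STATUS_MAP.get(res2.status) == "optimal":
                res, status = res2, "optimal"
        x = np.maximum(res.x, 0.0)
        total_resid = abs(x.sum() - V)
        if status == "optimal" and total_resid > FEASIBILITY_RTOL * V:
            status = "numerical_failure"
        from .objectives import entropy_objective

        H = entropy_objective(x, g, V, self.epsilon)
        diagnostics = {
            "n_iterations": int(res.nit),
            "constraint_violation": float(res.constr_violation),
            "total_flux_residual": float(total_resid),
            "formulation": self.formulation,
            "epsilon": self.epsilon,
        }
        return _package(self.method, split, x, H, status, diagnostics,
                        expression=self.rx)


class Spot(_SplitModelBase):
    """SPOT baseline: maximize flux/expression alignment on the unit ball.

    Solves ``max g.v`` subject to ``S v = 0``, bounds rescaled onto the
    unit-norm ball, and ``||v||_2 <= 1``; the returned fluxes are rescaled
    to ``sum(v) = V_total`` (Pearson-based comparisons are scale-invariant,
    so this only aids readability).
    """

    method = "spot"

    def __init__(self, network, expression, V_total: float = 1000.0,
                 epsilon: float = 1e-8, or_mode: str = "sum"):
        super().__init__(network, expression, epsilon=epsilon, or_mode=or_mode)
        self.V_total = float(V_total)

    def fit(self, x0=None, solver_options: dict | None = None) -> FluxSolution:
        split, g = self.split, self.rx.g
        M, N = split.S_split.shape
        opts = dict(gtol=1e-10, xtol=1e-12, maxiter=3000,
                    sparse_jacobian=True)
        opts.update(solver_options or {})
        scale = max(float(np.max(split.ub_split[np.isfinite(split.ub_split)]),
                          ), 1.0)
        lb = split.lb_split / scale
        ub = split.ub_split / scale
        A = np.vstack([split.S_split])
        feas = _feasible_point(A, np.zeros(M), lb, ub)
        if feas is None:
            return _empty_solution(self.method, "infeasible")
        gn = g / np.linalg.norm(g)

        def f(v):
            return -float(gn @ v)

        def grad(v):
            return -gn

        def hess(v):
            return sp.csr_matrix((N, N))

        ball = NonlinearConstraint(
            lambda v: float(v @ v), -np.inf, 1.0,
            jac=lambda v: sp.csr_matrix(2.0 * v),
            hess=lambda v, p: 2.0 * p[0] * sp.eye(N),
        )
        if x0 is None:
            nrm = np.linalg.norm(feas)
            x0 = feas / (2.0 * nrm) if nrm > 0 else feas
        cons = [LinearConstraint(sp.csr_matrix(split.S_split),
                                 np.zeros(M), np.zeros(M)), ball]
        res = minimize(f, x0, jac=grad, hess=hess, method="trust-constr",
                       constraints=cons, bounds=Bounds(lb, ub), options=opts)
        status = _STATUS_MAP.get(res.status, "numerical_failure")
        x = np.maximum(res.x, 0.0)
        nrm = np.linalg.norm(x)
        objective = float(g @ x / nrm) if nrm > 0 else 0.0
        total = x.sum()
        if total > 1e-12:
            x = x * (self.V_total / total)
        diagnostics = {
            "n_iterations": int(res.nit),
            "constraint_violation": float(res.constr_violation),
            "norm_before_rescale": float(nrm),
        }
        return _package(self.method, split, x, objective, status,
                        diagnostics, expression=self.rx)


def _polish_qp(x, A, b, lb, ub, rtol: float = 1e-3) -> np.ndarray:
    """Active-set polish for ``min ||x||^2 s.t. Ax=b, lb<=x<=ub``.

    Interior-point iterates stall a small distance away from active bounds;
    snap near-bound coordinates onto their bound, solve the remaining
    minimum-norm system exactly (lstsq), and keep the polished point only if
    it is feasible and no worse.  By strong convexity an objective decrease
    can only move the point closer to the unique optimum.
    """
    scale = max(1.0, float(np.abs(x).max()))
    tol = rtol * scale
    snapped = x.copy()
    active_lo = np.abs(x - lb) <= tol
    active_hi = np.abs(x - ub) <= tol
    snapped[active_lo] = lb[active_lo]
    snapped[active_hi] = ub[active_hi]
    free = ~(active_lo | active_hi)
    if free.any():
        rhs = b - A[:, ~free] @ snapped[~free]
        sol, *_ = np.linalg.lstsq(A[:, free], rhs, rcond=None)
        snapped[free] = sol
    feas = (np.abs(A @ snapped - b).max(initial=0.0) <= 1e-9 * scale
            and np.all(snapped >= lb - 1e-12)
            and np.all(snapped <= ub + 1e-12))
    if feas and snapped @ snapped <= x @ x + 1e-9 * scale ** 2:
        return snapped
    return x


class FBAMinL2:
    """Biomass-maximizing FBA followed by l2 flux minimization.

    Stage 1 maximizes the biomass flux (linear program); stage 2 fixes
    biomass at its optimum and minimizes ``sum v_i^2`` (strictly convex, so
    the flux vector is unique).  Expression data is never read.
    """

    method = "fba_min_l2"

    def __init__(self, network: MetabolicNetwork,
                 biomass_reaction: str | None = None):
        if not isinstance(network, MetabolicNetwork):
            raise TypeError("network must be a MetabolicNetwork")
        self.network = network
        self.biomass_reaction = biomass_reaction or network.biomass_reaction
        if self.biomass_reaction is None:
            raise ValidationError(
                "FBA requires a biomass reaction; none set on the model"
            )

    def fit(self, solver_options: dict | None = None) -> FluxSolution:
        net = self.network
        j = net.reaction_index(self.biomass_reaction)
        M, N = net.S.shape
        opts = dict(gtol=1e-9, xtol=1e-12, maxiter=3000)
        opts.update(solver_options or {})
        c = np.zeros(N)
        c[j] = -1.0
        bounds = np.column_stack([net.lower_bound, net.upper_bound])
        lp = linprog(c, A_eq=net.S, b_eq=np.zeros(M), bounds=bounds,
                     method="highs")
        if lp.status == 3:
            raise UnboundedProblemError(
                "biomass flux is unbounded; review the exchange bounds"
            )
        if lp.status != 0:
            return _empty_solution(self.method, "infeasible",
                                   {"lp_status": int(lp.status)})
        biomass_opt = float(lp.x[j])
        # stage 2: min ||v||^2 with biomass pinned at its optimum.  The
        # pinned variable is eliminated (moved to the RHS) so the equality
        # Jacobian keeps full column rank.
        keep = np.arange(N) != j
        S_red = net.S[:, keep]
        b_red = -net.S[:, j] * biomass_opt

        def f(v):
            return float(v @ v)

        def grad(v):
            return 2.0 * v

        def hess(v):
            return 2.0 * sp.eye(N - 1)

        cons = LinearConstraint(sp.csr_matrix(S_red), b_red, b_red)
        res = minimize(f, lp.x[keep], jac=grad, hess=hess,
                       method="trust-constr", constraints=[cons],
                       bounds=Bounds(net.lower_bound[keep],
                                     net.upper_bound[keep]),
                       options=opts)
        status = _STATUS_MAP.get(res.status, "numerical_failure")
        x_red = _polish_qp(res.x, S_red, b_red,
                           net.lower_bound[keep], net.upper_bound[keep])
        x = np.empty(N)
        x[keep] = x_red
        x[j] = biomass_opt
        resid = float(np.abs(net.S @ x).max())
        vnorm = max(float(np.abs(x).sum()), 1.0)
        if status == "optimal" and resid > FEASIBILITY_RTOL * vnorm:
            status = "numerical_failure"
        netflux = pd.Series(x, index=net.reaction_ids)
        split_v, split_ids = [], []
        for rid, val in netflux.items():
            split_ids.append(rid)
            split_v.append(max(val, 0.0))
            if val < 0:
                split_ids.append(rid + "__rev")
                split_v.append(-val)
        diagnostics = {
            "n_iterations": int(res.nit),
            "biomass_flux": biomass_opt,
            "steady_state_residual": resid,
        }
        return FluxSolution(
            method=self.method, status=status,
            v=pd.Series(split_v, index=split_ids),
            net=netflux, V_total=float(np.sum(np.abs(x))),
            objective_value=float(x @ x), diagnostics=diagnostics,
        )


# ---------------------------------------------------------------------------
# functional surface
# ---------------------------------------------------------------------------

def solve_pheflux(split: SplitNetwork, rx: ReactionExpression,
                  V_total: float = 1000.0, epsilon: float = 1e-8,
                  solver_options: dict | None = None,
                  x0=None) -> FluxSolution:
    """Entropy-formulation Pheflux solve (see :class:`Pheflux`)."""
    return Pheflux(split, rx, V_total=V_total, epsilon=epsilon,
                   formulation="entropy").fit(x0=x0,
                                              solver_options=solver_options)


def solve_pheflux_kl(split: SplitNetwork, rx: ReactionExpression,
                     V_total: float = 1000.0, epsilon: float = 1e-8,
                     solver_options: dict | None = None,
                     x0=None) -> FluxSolution:
    """KL-formulation Pheflux solve; same fluxome as :func:`solve_pheflux`."""
    return Pheflux(split, rx, V_total=V_total, epsilon=epsilon,
                   formulation="kl").fit(x0=x0, solver_options=solver_options)


def solve_spot(split: SplitNetwork, rx: ReactionExpression,
               V_total: float = 1000.0,
               solver_options: dict | None = None) -> FluxSolution:
    """SPOT baseline solve (see :class:`Spot`)."""
    return Spot(split, rx, V_total=V_total).fit(solver_options=solver_options)


def solve_fba_min_l2(network: MetabolicNetwork,
                     biomass_reaction: str | None = None,
                     solver_options: dict | None = None) -> FluxSolution:
    """FBA + minimum-l2 baseline solve (see :class:`FBAMinL2`)."""
    return FBAMinL2(network, biomass_reaction=biomass_reaction).fit(
        solver_options=solver_options)
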