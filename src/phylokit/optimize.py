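"""Parameter optimization: Newton-Raphson branch lengths, Brent for the
Gamma shape, linked substitution rates, ML frequencies and PSR rates, and
a round-robin driver.

Branch lengths use the eigenbasis "sumtable": with the virtual root on the
edge being optimised, the site likelihood is a finite exponential mixture

    L_s(t) = sum_j w_j sum_k a_{sjk} exp(lambda_k r_j t)

whose coefficients a depend only on the two endpoint CLVs, so L, dL/dt and
d2L/dt2 are cheap to evaluate at any trial t without re-traversing the
tree.  Newton iterates on d(logL)/dt and falls back to bounded Brent search
whenever the curvature is not negative or an iterate leaves the bounds.
All other parameters are optimised coordinate-wise by Brent with the
affected partition re-evaluated per trial (a model-parameter change always
forces a full traversal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .likelihood import (LOG_SCALE, AUTO, DegenerateError, LikelihoodError,
                         LikelihoodResult, TreeLikelihood,
                         pair_log_likelihood)
from .models import FREQ_FLOOR, PartitionModel
from .tree import HalfEdge


@dataclass
class OptimizerSettings:
    epsilon_logl: float = 0.1          # convergence tolerance on total logL
    newton_tol: float = 1e-8           # branch-length tolerance
    max_newton_iters: int = 32
    brent_tol: float = 1e-6
    branch_bounds: tuple[float, float] = (1e-8, 100.0)
    alpha_bounds: tuple[float, float] = (0.02, 100.0)
    rate_bounds: tuple[float, float] = (1e-4, 1e4)
    freq_floor: float = FREQ_FLOOR
    smoothing_passes: int = 32
    max_rounds: int = 50

    def as_dict(self) -> dict:
        return {
            "epsilon_logl": self.epsilon_logl,
            "newton_tol": self.newton_tol,
            "max_newton_iters": self.max_newton_iters,
            "brent_tol": self.brent_tol,
            "branch_min": self.branch_bounds[0],
            "branch_max": self.branch_bounds[1],
            "alpha_min": self.alpha_bounds[0],
            "alpha_max": self.alpha_bounds[1],
            "rate_min": self.rate_bounds[0],
            "rate_max": self.rate_bounds[1],
            "freq_floor": self.freq_floor,
            "smoothing_passes": self.smoothing_passes,
            "max_rounds": self.max_rounds,
        }


# ---------------------------------------------------------------------------
# Branch-length objective from eigenbasis sumtables

class _PartTable:
    __slots__ = ("a", "lam_r", "counts", "weights", "psr_assign",
                 "cat_weights", "n_obs", "asc", "sum_w")

    def __init__(self, ps, clv_u, clv_v, counts):
        sub = ps.model.subst
        pi = sub.freqs
        rates = ps.model.category_rates()
        left = (clv_u * pi) @ sub.U              # (c|-, pat, k)
        right = clv_v @ sub.Uinv.T
        a = left * right
        if a.ndim == 2:                          # both endpoints tips cannot
            a = a[None, :, :]                    # happen, but stay safe
        c = len(rates)
        if a.shape[0] == 1 and c > 1:
            a = np.broadcast_to(a, (c,) + a.shape[1:])
        self.a = a                               # (c, pat, k)
        self.lam_r = np.multiply.outer(rates, sub.eigenvalues)  # (c, k)
        self.counts = counts
        self.weights = ps.weights
        self.sum_w = float(ps.weights.sum())
        self.psr_assign = ps.psr_assign
        self.cat_weights = ps.model.category_weights()
        self.n_obs = ps.n_obs
        self.asc = ps.asc

    def _mixture(self, t: float):
        e = np.exp(self.lam_r * t)               # (c, k)
        l0 = np.einsum("cpk,ck->cp", self.a, e)
        l1 = np.einsum("cpk,ck->cp", self.a, e * self.lam_r)
        l2 = np.einsum("cpk,ck->cp", self.a, e * self.lam_r ** 2)
        return l0, l1, l2

    def logl_terms(self, t: float):
        """(logL, dlogL/dt, d2logL/dt2) for this partition at branch t."""
        l0, l1, l2 = self._mixture(t)
        if self.psr_assign is not None:
            idx = (self.psr_assign, np.arange(self.n_obs))
            L, D1, D2 = l0[idx], l1[idx], l2[idx]
            cnt = self.counts[:self.n_obs]
        else:
            w = self.cat_weights
            L = w @ l0
            D1 = w @ l1
            D2 = w @ l2
            cnt = self.counts
            L, D1, D2 = L[:self.n_obs], D1[:self.n_obs], D2[:self.n_obs]
            cnt_obs = cnt[:self.n_obs]
            cnt = cnt_obs
        if np.any(L <= 0):
            raise LikelihoodError("branch objective: site likelihood <= 0")
        wts = self.weights
        f = float(wts @ (np.log(L) - LOG_SCALE * cnt))
        r = D1 / L
        d1 = float(wts @ r)
        d2 = float(wts @ (D2 / L - r ** 2))
        if self.asc:
            w = self.cat_weights
            l0a, l1a, l2a = (w @ x for x in self._mixture(t))
            scale = np.exp(-LOG_SCALE * self.counts[self.n_obs:])
            v = float(l0a[self.n_obs:] @ scale)
            v1 = float(l1a[self.n_obs:] @ scale)
            v2 = float(l2a[self.n_obs:] @ scale)
            if v >= 1.0 - 1e-6:
                raise DegenerateError("ascertainment term degenerate (V >= 1)")
            f -= self.sum_w * np.log1p(-v)
            d1 += self.sum_w * v1 / (1.0 - v)
            d2 += self.sum_w * (v2 * (1.0 - v) + v1 ** 2) / (1.0 - v) ** 2
        return f, d1, d2


class BranchObjective:
    """Total logL along one edge as a function of that edge's length."""

    def __init__(self, tl: TreeLikelihood, edge_id: int):
        tl.evaluate(edge_id, mode=AUTO)
        root = tl.tree.root_records(edge_id)[0]
        self.tables: list[_PartTable] = []
        for ps in tl.parts:
            clv_u, sc_u = tl._root_clv_and_scaler(ps, root)
            clv_v, sc_v = tl._root_clv_and_scaler(ps, root.back)
            counts = np.zeros(ps.n_pat)
            for sc in (sc_u, sc_v):
                if sc is not None:
                    counts += sc.counts(ps.n_pat)
            self.tables.append(_PartTable(ps, clv_u, clv_v, counts))

    def value(self, t: float) -> float:
        return sum(tab.logl_terms(t)[0] for tab in self.tables)

    def derivatives(self, t: float):
        f = d1 = d2 = 0.0
        for tab in self.tables:
            fi, a, b = tab.logl_terms(t)
            f, d1, d2 = f + fi, d1 + a, d2 + b
        return f, d1, d2


def _brent_max(fun, bounds, xatol):
    res = minimize_scalar(lambda x: -fun(x), bounds=bounds, method="bounded",
                          options={"xatol": xatol})
    return float(res.x)


def _brent_max_log(fun, bounds, xatol):
    """Bounded Brent over a positive variable, searched in log space
    (branch lengths and shape parameters span many decades; a linear
    search collapses onto the flat large-value plateau)."""
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    res = minimize_scalar(lambda u: -fun(np.exp(u)), bounds=(lo, hi),
                          method="bounded", options={"xatol": xatol})
    return float(np.exp(res.x))


def optimize_branch(tl: TreeLikelihood, edge_id: int,
                    settings: OptimizerSettings | None = None) -> float:
    """Maximise logL over one edge's length; sets and returns the new
    length.  The accepted value never decreases logL by more than 1e-9."""
    settings = settings or OptimizerSettings()
    lo, hi = settings.branch_bounds
    obj = BranchObjective(tl, edge_id)
    t0 = tl.tree.edge_records(edge_id)[0].length
    f0 = obj.value(t0)

    t = min(max(t0, lo), hi)
    newton_ok = False
    hit_bound = 0
    for _ in range(settings.max_newton_iters):
        f, d1, d2 = obj.derivatives(t)
        if not (np.isfinite(d1) and np.isfinite(d2)):
            raise LikelihoodError("non-finite branch-length derivative")
        if d2 >= 0.0:
            break  # not concave here: hand over to Brent
        tn = t - d1 / d2
        if tn < lo or tn > hi:
            tn = lo if tn < lo else hi
            hit_bound += 1
            if hit_bound >= 2:
                t, newton_ok = tn, True
                break
        else:
            hit_bound = 0
        if abs(tn - t) < settings.newton_tol:
            t, newton_ok = tn, True
            break
        t = tn
    if not newton_ok:
        t = _brent_max_log(obj.value, (lo, hi), settings.newton_tol)
    if obj.value(t) < f0 - 1e-9:
        t = t0  # keep the incumbent rather than accept a worse value
    tl.set_branch_length(edge_id, t)
    return t


def _edge_smoothing_order(tl: TreeLikelihood) -> list[int]:
    """Edges in depth-first order so consecutive optimisations are local
    and partial traversals stay short."""
    tree = tl.tree
    start = tree.tips[min(tree.tips)]
    order: list[int] = []
    stack = [start.back]  # record at the inner node, pointing to start tip
    seen = set()
    order.append(start.edge_id)
    while stack:
        rec = stack.pop()
        if rec.is_tip:
            continue
        for r in (rec.nxt, rec.nxt.nxt):
            if r.edge_id not in seen and r.edge_id != order[0]:
                seen.add(r.edge_id)
                order.append(r.edge_id)
                stack.append(r.back)
    return order


def optimize_all_branches(tl: TreeLikelihood,
                          settings: OptimizerSettings | None = None
                          ) -> LikelihoodResult:
    """Smoothing passes over all edges until a pass gains < epsilon_logl."""
    settings = settings or OptimizerSettings()
    order = _edge_smoothing_order(tl)
    last = tl.evaluate(order[0], mode=AUTO).total
    for _ in range(settings.smoothing_passes):
        for eid in order:
            optimize_branch(tl, eid, settings)
        res = tl.evaluate(order[0], mode=AUTO)
        if res.total - last < settings.epsilon_logl:
            return res
        last = res.total
    return tl.evaluate(order[0], mode=AUTO)


# ---------------------------------------------------------------------------
# Brent optimisation of model parameters

def _partition_logl(tl: TreeLikelihood, partition: int, root_edge: int) -> float:
    return tl.evaluate(root_edge, mode=AUTO).per_partition[partition]


def optimize_alpha(tl: TreeLikelihood, partition: int, root_edge: int | None = None,
                   settings: OptimizerSettings | None = None) -> float:
    """Brent-maximise the Gamma shape of one partition; returns alpha-hat."""
    settings = settings or OptimizerSettings()
    root_edge = _default_root(tl, root_edge)
    model = tl.models[partition]
    if model.het.mode != "GAMMA":
        raise LikelihoodError("partition does not use the Gamma model")
    a0 = model.het.alpha
    f0 = _partition_logl(tl, partition, root_edge)

    def fun(a: float) -> float:
        model.het.set_alpha(a)
        return _partition_logl(tl, partition, root_edge)

    best = _brent_max_log(fun, settings.alpha_bounds, settings.brent_tol)
    if fun(best) < f0:
        best = a0
        fun(best)
    model.het.set_alpha(best)
    return best


def optimize_rates(tl: TreeLikelihood, partition: int, root_edge: int | None = None,
                   settings: OptimizerSettings | None = None) -> np.ndarray:
    """Coordinate-wise Brent over the free linked exchangeability classes
    (reference class pinned at 1); cycles until the gain < epsilon_logl."""
    settings = settings or OptimizerSettings()
    root_edge = _default_root(tl, root_edge)
    model = tl.models[partition]
    sub = model.subst
    if sub.linkage is None:
        raise LikelihoodError("partition's model has no rate linkage")
    free = sub.linkage.free_classes
    if not free:
        return sub.class_rates
    lo, hi = np.log(settings.rate_bounds[0]), np.log(settings.rate_bounds[1])
    last = _partition_logl(tl, partition, root_edge)
    for _ in range(settings.max_rounds):
        for k in free:
            rates = sub.class_rates

            def fun(u: float) -> float:
                r = rates.copy()
                r[k] = np.exp(u)
                sub.set_class_rates(r)
                return _partition_logl(tl, partition, root_edge)

            u0 = np.log(rates[k])
            f0 = fun(u0)
            best = _brent_max(fun, (lo, hi), settings.brent_tol)
            if fun(best) < f0:
                best = u0
            rates[k] = np.exp(best)
            sub.set_class_rates(rates)
        now = _partition_logl(tl, partition, root_edge)
        if now - last < settings.epsilon_logl:
            break
        last = now
    return sub.class_rates


def optimize_frequencies(tl: TreeLikelihood, partition: int,
                         root_edge: int | None = None,
                         settings: OptimizerSettings | None = None) -> np.ndarray:
    """ML state frequencies by coordinate-wise Brent in log-ratio
    coordinates (last state is the reference)."""
    settings = settings or OptimizerSettings()
    root_edge = _default_root(tl, root_edge)
    model = tl.models[partition]
    sub = model.subst
    n = sub.n_states

    def set_from_z(z: np.ndarray) -> None:
        raw = np.exp(np.concatenate([z, [0.0]]))
        f = raw / raw.sum()
        f = np.maximum(f, settings.freq_floor)
        sub.set_frequencies(f / f.sum())

    z = np.log(sub.freqs[:-1] / sub.freqs[-1])
    last = _partition_logl(tl, partition, root_edge)
    for _ in range(settings.max_rounds):
        for i in range(n - 1):

            def fun(zi: float) -> float:
                zz = z.copy()
                zz[i] = zi
                set_from_z(zz)
                return _partition_logl(tl, partition, root_edge)

            f0 = fun(z[i])
            best = _brent_max(fun, (-14.0, 14.0), settings.brent_tol)
            if fun(best) < f0:
                best = z[i]
            z[i] = best
            set_from_z(z)
        now = _partition_logl(tl, partition, root_edge)
        if now - last < settings.epsilon_logl:
            break
        last = now
    set_from_z(z)
    return sub.freqs


def optimize_psr(tl: TreeLikelihood, partition: int, root_edge: int | None = None,
                 settings: OptimizerSettings | None = None) -> np.ndarray:
    """PSR round: Brent each category rate, then reassign site categories
    and renormalise to weighted mean rate one."""
    settings = settings or OptimizerSettings()
    root_edge = _default_root(tl, root_edge)
    model = tl.models[partition]
    if model.het.mode != "PSR":
        raise LikelihoodError("partition does not use the PSR model")
    lo, hi = np.log(settings.rate_bounds[0]), np.log(settings.rate_bounds[1])
    for j in range(model.het.n_categories):
        rates = model.het.rates().copy()

        def fun(u: float) -> float:
            r = rates.copy()
            r[j] = np.exp(u)
            model.het.psr_rates = r
            return _partition_logl(tl, partition, root_edge)

        f0 = fun(np.log(rates[j]))
        best = _brent_max(fun, (lo, hi), settings.brent_tol)
        if fun(best) < f0:
            best = np.log(rates[j])
        rates[j] = np.exp(best)
        model.het.psr_rates = rates
    tl.assign_psr_categories(partition, root_edge)
    return model.het.rates()


def _default_root(tl: TreeLikelihood, root_edge: int | None) -> int:
    return root_edge if root_edge is not None else min(tl.tree.edges)


def optimize_model(tl: TreeLikelihood,
                   settings: OptimizerSettings | None = None,
                   optimize_branches: bool = True,
                   callback=None, start_round: int = 0,
                   last_logl: float | None = None) -> LikelihoodResult:
    """Round-robin optimisation: branches, then per partition linked rates,
    Gamma shape (or PSR rates/assignments) and ML frequencies, repeated
    until a full round gains < epsilon_logl.

    ``callback(round_index, result)`` fires after every round (used for
    checkpointing); ``start_round``/``last_logl`` let a restored run
    continue exactly where it stopped.
    """
    settings = settings or OptimizerSettings()
    root = _default_root(tl, None)
    last = (tl.evaluate(root, mode=AUTO).total
            if last_logl is None else last_logl)
    for rnd in range(start_round, settings.max_rounds):
        if optimize_branches:
            optimize_all_branches(tl, settings)
        for k, model in enumerate(tl.models):
            if model.subst.linkage is not None and model.subst.linkage.free_classes:
                optimize_rates(tl, k, root, settings)
            if model.het.mode == "GAMMA":
                optimize_alpha(tl, k, root, settings)
            elif model.het.mode == "PSR":
                optimize_psr(tl, k, root, settings)
            if model.freq_mode == "ml":
                optimize_frequencies(tl, k, root, settings)
        res = tl.evaluate(root, mode=AUTO)
        if callback is not None:
            callback(rnd, res)
        if res.total - last < settings.epsilon_logl:
            return res
        last = res.total
    return tl.evaluate(root, mode=AUTO)


# ---------------------------------------------------------------------------
# Two-sequence ML distance (closed-form checks, simulator consistency)

def ml_pair_distance(model: PartitionModel, tip_a: np.ndarray, tip_b: np.ndarray,
                     weights: np.ndarray,
                     bounds: tuple[float, float] = (1e-8, 100.0)) -> float:
    """Maximum-likelihood branch length between two aligned sequences."""
    t = _brent_max_log(
        lambda t: pair_log_likelihood(model, tip_a, tip_b, weights, t),
        bounds, 1e-10)
    return float(t)
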