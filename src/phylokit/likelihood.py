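"""Likelihood evaluation on unrooted trees by Felsenstein pruning.

The engine stores one conditional likelihood vector (CLV) per inner node
and partition, shaped ``(n_categories, n_patterns, n_states)``, plus the
orientation bookkeeping on the tree that records which direction each CLV
was computed toward.  Evaluation places a *virtual root* on an edge: the
edge's two endpoints act as the root's children, and site likelihoods are

    L_s = sum_j w_j sum_x pi_x CLV_u[j,s,x] (P(t) CLV_v[j,s])_x

averaged over rate categories j (or taken at the site's assigned category
under the PSR model).  CLV entries are rescaled by 2^256 whenever a
pattern's maximum drops below 2^-256; the accumulated log-scalers are added
back at the root, which keeps 2000-taxon trees out of the denormal range.

Ascertainment-bias correction (variable-sites-only data) conditions each
site likelihood on the site being variable: the engine carries one dummy
constant pattern per state (weight zero) through every CLV update, sums
their likelihoods into V = Pr(constant), and subtracts log(1 - V) per
observed site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import PatternAlignment, PatternPartition
from .models import PartitionModel
from .states import DataTypeInfo
from .tree import FULL, PARTIAL, HalfEdge, TraversalOp, Tree

SCALE_THRESHOLD = 2.0 ** -256
SCALE_MULTIPLIER = 2.0 ** 256
LOG_SCALE = 256.0 * np.log(2.0)

PER_SITE = "per-site"
PER_NODE = "per-node"
NO_SCALING = "none"

AUTO = "AUTO"


class LikelihoodError(ValueError):
    pass


class UnderflowError(LikelihoodError):
    """A site likelihood evaluated to exactly zero."""


class DegenerateError(LikelihoodError):
    """A numerically meaningless regime (e.g. Pr(constant) -> 1 under the
    ascertainment correction)."""


@dataclass
class LikelihoodResult:
    total: float
    per_partition: list[float]
    pattern_logl: list[np.ndarray]       # per partition, observed patterns only
    weights: list[np.ndarray]
    pattern_to_sites: list[list[list[int]]]
    n_sites: int
    scaling_events: int = 0
    asc_probs: list[float | None] = field(default_factory=list)

    def site_log_likelihoods(self) -> np.ndarray:
        """Expand pattern log-likelihoods back to original site order."""
        out = np.empty(self.n_sites)
        for logl, p2s in zip(self.pattern_logl, self.pattern_to_sites):
            for value, sites in zip(logl, p2s):
                for s in sites:
                    out[s] = value
        return out


@dataclass
class _Scaler:
    """Cumulative scaling record of one (node, partition).

    ``scalar`` counts whole-CLV scalings (per-node mode); ``per_site`` holds
    per-pattern counts when patterns scaled individually.  The cumulative
    count for pattern s is ``scalar + per_site[s]``.
    """

    scalar: float = 0.0
    per_site: np.ndarray | None = None

    def counts(self, n_patterns: int) -> np.ndarray:
        base = np.full(n_patterns, self.scalar)
        if self.per_site is not None:
            base += self.per_site
        return base


class _PartitionState:
    """Per-partition tensors: tip encodings, CLV bank, scalers, P-cache."""

    def __init__(self, pp: PatternPartition, model: PartitionModel,
                 taxon_names: list[str]):
        self.pp = pp
        self.model = model
        dt = model.dtype
        self.n_states = dt.n_states
        self.n_obs = pp.n_patterns
        self.weights = pp.weights.astype(float)

        self.asc = model.ascertainment
        if self.asc and model.het.mode == "PSR":
            raise LikelihoodError(
                "ascertainment correction is not defined under the PSR model")
        if self.asc:
            self._check_no_constant_columns(pp, dt)
        self.n_extra = self.n_states if self.asc else 0
        self.n_pat = self.n_obs + self.n_extra

        # tip encodings: label -> (n_pat, n_states)
        self.tip_clv: dict[str, np.ndarray] = {}
        for ti, name in enumerate(taxon_names):
            enc = np.empty((self.n_pat, self.n_states))
            for p, col in enumerate(pp.patterns):
                enc[p] = dt.tip_vectors[col[ti]]
            for x in range(self.n_extra):
                enc[self.n_obs + x] = 0.0
                enc[self.n_obs + x, x] = 1.0
            self.tip_clv[name] = enc

        self.clvs: dict[int, np.ndarray] = {}
        self.scalers: dict[int, _Scaler] = {}
        self.p_cache: dict[int, tuple[object, float, np.ndarray]] = {}
        self.model_key: object = None

        c = model.het.n_categories
        if model.het.mode == "PSR":
            rates = model.category_rates()
            start = int(np.argmin(np.abs(rates - 1.0)))
            self.psr_assign = np.full(self.n_obs, start, dtype=np.int64)
        else:
            self.psr_assign = None

    @staticmethod
    def _check_no_constant_columns(pp: PatternPartition, dt: DataTypeInfo) -> None:
        for col in pp.patterns:
            mask = dt.full_mask
            for ch in col:
                mask &= dt.bitmasks[ch]
            if mask:
                raise LikelihoodError(
                    "ascertainment-corrected partition contains a column that"
                    f" may be constant: {col!r}")

    def current_key(self) -> object:
        return (self.model.subst.version, tuple(self.model.category_rates()))

    def clv_or_tip(self, rec: HalfEdge) -> np.ndarray:
        """CLV of the node behind ``rec.back`` (child side), tip or inner."""
        child = rec.back
        if child.is_tip:
            return self.tip_clv[child.label]
        return self.clvs[child.node_id]

    def child_scaler(self, rec: HalfEdge) -> _Scaler | None:
        child = rec.back
        if child.is_tip:
            return None
        return self.scalers.get(child.node_id)


class TreeLikelihood:
    """Partitioned likelihood evaluator bound to one tree and alignment.

    Branch lengths must be changed through :meth:`set_branch_length` (or
    the optimizers) so cached transition matrices and dependent CLVs are
    invalidated; model-parameter changes are detected automatically by
    versioning and force a full traversal.
    """

    def __init__(self, tree: Tree, paln: PatternAlignment,
                 models: list[PartitionModel] | None = None,
                 scaling: str = PER_SITE):
        if scaling not in (PER_SITE, PER_NODE, NO_SCALING):
            raise LikelihoodError(f"unknown scaling mode {scaling!r}")
        tree_taxa = set(tree.tips)
        aln_taxa = set(paln.taxon_names)
        if tree_taxa != aln_taxa:
            diff = sorted(tree_taxa.symmetric_difference(aln_taxa))
            raise LikelihoodError(
                f"tree and alignment taxon sets differ: {diff}")
        self.tree = tree
        self.paln = paln
        self.scaling = scaling
        if models is None:
            models = [
                PartitionModel.from_spec(pp.partition.model_spec, pp.patterns,
                                         pp.weights, paln.n_taxa)
                for pp in paln.parts
            ]
        if len(models) != len(paln.parts):
            raise LikelihoodError("one model per partition required")
        self.models = models
        self.parts = [
            _PartitionState(pp, m, paln.taxon_names)
            for pp, m in zip(paln.parts, models)
        ]

    # -- cache management ---------------------------------------------------

    def set_branch_length(self, edge_id: int, t: float) -> None:
        self.tree.set_length(edge_id, t)
        for ps in self.parts:
            ps.p_cache.pop(edge_id, None)

    def drop_edge_caches(self, edge_ids) -> None:
        for eid in edge_ids:
            for ps in self.parts:
                ps.p_cache.pop(eid, None)

    def invalidate_all(self) -> None:
        self.tree.invalidate_all()
        for ps in self.parts:
            ps.p_cache.clear()

    def _refresh_model_keys(self) -> bool:
        """Detect model-parameter changes; returns True if any partition
        changed (stored CLVs are then invalid and a full traversal runs)."""
        changed = False
        for ps in self.parts:
            key = ps.current_key()
            if key != ps.model_key:
                ps.model_key = key
                ps.p_cache.clear()
                changed = True
        return changed

    def _p_matrices(self, ps: _PartitionState, rec: HalfEdge) -> np.ndarray:
        eid = rec.edge_id
        cached = ps.p_cache.get(eid)
        if cached is not None and cached[1] == rec.length:
            return cached[2]
        p = ps.model.subst.transition_matrices(rec.length, ps.model.category_rates())
        ps.p_cache[eid] = (ps.model_key, rec.length, p)
        return p

    # -- CLV update (pruning step) -----------------------------------------

    def _update_clv(self, ps: _PartitionState, op: TraversalOp) -> None:
        pl = self._p_matrices(ps, op.left)       # (c, n, n)
        pr = self._p_matrices(ps, op.right)
        left = ps.clv_or_tip(op.left)            # (c, pat, n) or (pat, n)
        right = ps.clv_or_tip(op.right)
        res = np.matmul(left, np.swapaxes(pl, 1, 2))
        res *= np.matmul(right, np.swapaxes(pr, 1, 2))

        nid = op.node_id
        scaler = _Scaler()
        for child in (op.left, op.right):
            cs = ps.child_scaler(child)
            if cs is not None:
                scaler.scalar += cs.scalar
                if cs.per_site is not None:
                    if scaler.per_site is None:
                        scaler.per_site = cs.per_site.copy()
                    else:
                        scaler.per_site = scaler.per_site + cs.per_site

        if self.scaling != NO_SCALING:
            peak = res.max(axis=(0, 2))          # per-pattern maximum
            low = peak < SCALE_THRESHOLD
            if low.any():
                if self.scaling == PER_NODE and low.all():
                    res *= SCALE_MULTIPLIER
                    scaler.scalar += 1.0
                else:
                    # per-site bookkeeping (also the per-node local fallback
                    # when only some patterns underflow)
                    res[:, low, :] *= SCALE_MULTIPLIER
                    if scaler.per_site is None:
                        scaler.per_site = np.zeros(ps.n_pat)
                    else:
                        scaler.per_site = scaler.per_site.copy()
                    scaler.per_site[low] += 1.0

        ps.clvs[nid] = res
        ps.scalers[nid] = scaler

    # -- evaluation ---------------------------------------------------------

    def evaluate(self, root_edge: int, mode: str = AUTO) -> LikelihoodResult:
        """Total and per-partition log-likelihood with the virtual root on
        ``root_edge``.  ``mode`` is FULL, PARTIAL, or AUTO (partial unless a
        model parameter changed since the last evaluation)."""
        model_changed = self._refresh_model_keys()
        if mode == AUTO:
            mode = FULL if model_changed else PARTIAL
        elif mode == PARTIAL and model_changed:
            mode = FULL
        if mode == FULL:
            self.tree.invalidate_all()
            mode = PARTIAL  # with all orientations unset this is a full pass
        td = self.tree.build_traversal(root_edge, PARTIAL)
        for op in td.ops:
            for ps in self.parts:
                self._update_clv(ps, op)
            self.tree.mark_computed(op)
        return self._combine_at_root(td.root)

    def _root_clv_and_scaler(self, ps: _PartitionState, rec: HalfEdge):
        if rec.is_tip:
            return ps.tip_clv[rec.label], None
        return ps.clvs[rec.node_id], ps.scalers[rec.node_id]

    def _root_terms(self, ps: _PartitionState, root: HalfEdge):
        """(per-category likelihood matrix (c, n_pat), scaler counts)."""
        u, v = root, root.back
        clv_u, sc_u = self._root_clv_and_scaler(ps, u)
        clv_v, sc_v = self._root_clv_and_scaler(ps, v)
        p = self._p_matrices(ps, root)           # (c, n, n)
        moved = np.matmul(clv_v, np.swapaxes(p, 1, 2))
        prod = clv_u * moved                      # broadcasts tips over cats
        percat = prod @ ps.model.subst.freqs      # (c, n_pat)
        counts = np.zeros(ps.n_pat)
        for sc in (sc_u, sc_v):
            if sc is not None:
                counts += sc.counts(ps.n_pat)
        return percat, counts

    def _combine_at_root(self, root: HalfEdge) -> LikelihoodResult:
        per_partition: list[float] = []
        pattern_logl: list[np.ndarray] = []
        weights: list[np.ndarray] = []
        p2s: list[list[list[int]]] = []
        asc_probs: list[float | None] = []
        events = 0
        for k, ps in enumerate(self.parts):
            percat, counts = self._root_terms(ps, root)
            if ps.psr_assign is not None:
                site_l = percat[ps.psr_assign, np.arange(ps.n_obs)]
                obs_counts = counts[:ps.n_obs]
            else:
                w = ps.model.category_weights()
                site_all = w @ percat            # (n_pat,)
                site_l = site_all[:ps.n_obs]
                obs_counts = counts[:ps.n_obs]
            if np.any(site_l <= 0.0):
                bad = int(np.argmax(site_l <= 0.0))
                raise UnderflowError(
                    f"site likelihood underflowed to zero: partition"
                    f" {ps.pp.partition.name!r}, pattern {bad}"
                    f" ({ps.pp.patterns[bad]!r});"
                    " enable scaling or shorten branches")
            logl = np.log(site_l) - LOG_SCALE * obs_counts
            asc_v: float | None = None
            if ps.asc:
                w = ps.model.category_weights()
                extra_all = w @ percat[:, ps.n_obs:]
                extra_counts = counts[ps.n_obs:]
                with np.errstate(divide="ignore"):
                    log_extra = np.log(extra_all) - LOG_SCALE * extra_counts
                asc_v = float(np.exp(log_extra).sum())
                if asc_v >= 1.0 - 1e-6:
                    raise DegenerateError(
                        "ascertainment correction degenerate: Pr(constant)"
                        f" = {asc_v:.6g}; the tree is too short for a"
                        " variable-sites-only correction")
                logl = logl - np.log1p(-asc_v)
            part_logl = float(ps.weights @ logl)
            per_partition.append(part_logl)
            pattern_logl.append(logl)
            weights.append(ps.weights)
            p2s.append(ps.pp.pattern_to_sites)
            asc_probs.append(asc_v)
            events += int(counts.sum())
        return LikelihoodResult(
            total=float(sum(per_partition)),
            per_partition=per_partition,
            pattern_logl=pattern_logl,
            weights=weights,
            pattern_to_sites=p2s,
            n_sites=self.paln.n_sites,
            scaling_events=events,
            asc_probs=asc_probs,
        )

    # -- ancestral states ---------------------------------------------------

    def ancestral_states(self, node_id: int,
                         partition: int = 0) -> np.ndarray:
        """Marginal posterior state probabilities at an inner node,
        shape (n_observed_patterns, n_states), rows summing to one."""
        if node_id not in self.tree.inner:
            raise LikelihoodError(f"node {node_id} is not an inner node")
        r1, r2, r3 = self.tree.inner_records(node_id)
        self.evaluate(r1.edge_id, mode=AUTO)
        ps = self.parts[partition]
        prod = None
        for rec in (r1, r2, r3):
            clv, _ = self._root_clv_and_scaler(ps, rec.back)
            p = self._p_matrices(ps, rec)
            term = np.matmul(clv, np.swapaxes(p, 1, 2))  # (c, pat, states)
            prod = term if prod is None else prod * term
        prod = prod * ps.model.subst.freqs[None, None, :]
        if ps.psr_assign is not None:
            post = prod[ps.psr_assign, np.arange(ps.n_obs), :]
        else:
            w = ps.model.category_weights()
            post = np.einsum("j,jpx->px", w, prod)[:ps.n_obs]
        norm = post.sum(axis=1, keepdims=True)
        if np.any(norm <= 0):
            raise UnderflowError("ancestral posterior underflowed to zero")
        return post / norm

    # -- PSR category assignment -------------------------------------------

    def assign_psr_categories(self, partition: int, root_edge: int) -> np.ndarray:
        """Assign each site (pattern) the category maximising its
        likelihood, then renormalise the category rates to weighted mean
        one over sites.  Branch lengths absorb the normalisation factor
        (r_j -> r_j/m, t -> t*m), so the renormalisation itself is
        likelihood-neutral and the reassignment never decreases logL.
        Returns the per-pattern assignment."""
        ps = self.parts[partition]
        if ps.psr_assign is None:
            raise LikelihoodError("partition does not use the PSR model")
        self.evaluate(root_edge, mode=AUTO)
        td_root = self.tree.root_records(root_edge)[0]
        percat, _ = self._root_terms(ps, td_root)
        ps.psr_assign = np.argmax(percat[:, :ps.n_obs], axis=0)
        rates = ps.model.category_rates()
        mean = float(ps.weights @ rates[ps.psr_assign]) / float(ps.weights.sum())
        ps.model.het.psr_rates = rates / mean
        if len(self.parts) == 1:  # rescale lengths only when unambiguous
            for eid in sorted(self.tree.edges):
                rec = self.tree.edges[eid]
                self.set_branch_length(eid, rec.length * mean)
        return ps.psr_assign.copy()


# ---------------------------------------------------------------------------
# Two-sequence likelihood (no inner nodes; used for closed-form checks and
# pairwise ML distances)

def pair_log_likelihood(model: PartitionModel, tip_a: np.ndarray,
                        tip_b: np.ndarray, weights: np.ndarray,
                        t: float) -> float:
    """Log-likelihood of two aligned sequences separated by branch length t.

    ``tip_a``/``tip_b`` are (n_patterns, n_states) 0/1 encodings.
    """
    p = model.subst.transition_matrices(t, model.category_rates())
    moved = np.matmul(tip_b, np.swapaxes(p, 1, 2))     # (c, pat, states)
    percat = (tip_a * moved) @ model.subst.freqs       # (c, pat)
    site_l = model.category_weights() @ percat
    if np.any(site_l <= 0):
        raise UnderflowError("pairwise site likelihood underflowed")
    return float(weights @ np.log(site_l))
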