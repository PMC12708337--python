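"""Felsenstein pruning under TIM2+G+I with per-site log-likelihoods.

The per-site vectors are the common currency of all RELL-based
topology tests, so the engine exposes them directly.  Ambiguous tip
states are treated as partial observations (ones for every compatible
base); gaps are fully missing.  Site patterns are compressed before
any computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import Alignment
from .model import EigenSystem, ModelParams, build_rate_matrix, gamma_categories
from .tree import PhyloTree

_TINY = 1e-300


@dataclass
class SiteLogLikelihoods:
    """Per-site log-likelihood vector for one (tree, alignment) pair."""

    tree_id: str
    values: np.ndarray

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def __len__(self) -> int:
        return len(self.values)


class AlignmentData:
    """Pattern-compressed alignment, shared across engine instances."""

    def __init__(self, aln: Alignment):
        self.aln = aln
        self.taxa = list(aln.taxa)
        masks = aln.masks()
        pats, inverse, counts = np.unique(
            masks.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = pats.T  # (ntaxa, npat)
        self.inverse = inverse  # site -> pattern index
        self.counts = counts.astype(float)
        self.n_sites = aln.n_sites
        self.n_pat = self.patterns.shape[1]
        bits = np.array([1, 2, 4, 8], dtype=np.uint8)
        # tip partial vectors per taxon: (ntaxa, npat, 4)
        self.tip_partials = (
            (self.patterns[:, :, None] & bits[None, None, :]) > 0
        ).astype(float)
        # bases compatible with every taxon simultaneously (for the
        # invariant-site class)
        agg = np.bitwise_and.reduce(self.patterns, axis=0)
        self.const_compat = ((agg[:, None] & bits[None, :]) > 0).astype(float)


class LikelihoodEngine:
    """Pruning machinery bound to one topology and one alignment."""

    def __init__(
        self, tree: PhyloTree, data: AlignmentData, params: ModelParams
    ):
        self.tree = tree
        self.data = data
        self.params = params
        labels = tree.leaf_labels()
        if set(labels) != set(data.taxa):
            missing = sorted(set(labels) ^ set(data.taxa))
            raise ValueError(
                f"tree/alignment label mismatch; offenders: {missing}"
            )
        self._index_tree()
        self._set_model(params)
        self._stale = True

    # ------------------------------------------------------------------
    def _index_tree(self) -> None:
        nodes = list(self.tree.postorder())
        self.nodes = nodes
        self.idx = {id(n): i for i, n in enumerate(nodes)}
        self.parent = np.full(len(nodes), -1, dtype=int)
        self.children: list[list[int]] = [[] for _ in nodes]
        self.blen = np.zeros(len(nodes))
        taxon_row = {t: i for i, t in enumerate(self.data.taxa)}
        self.tip_row = np.full(len(nodes), -1, dtype=int)
        for i, n in enumerate(nodes):
            self.blen[i] = n.length
            if n.is_leaf():
                self.tip_row[i] = taxon_row[n.name]
            for c in n.children:
                j = self.idx[id(c)]
                self.parent[j] = i
                self.children[i].append(j)
        self.root_idx = self.idx[id(self.tree.root)]

    def _set_model(self, params: ModelParams) -> None:
        self.params = params
        self.q = build_rate_matrix(params)
        self.pi = params.freqs
        self.eig = EigenSystem(self.q, self.pi)
        self.rates, self.rate_weights = gamma_categories(
            params.alpha, params.ncat
        )
        self._log_pinv_term = self._compute_pinv_term()
        self._stale = True

    def _compute_pinv_term(self) -> np.ndarray:
        """log(pinv * sum_b pi_b) per pattern; -inf when impossible."""
        if self.params.pinv == 0:
            return np.full(self.data.n_pat, -np.inf)
        mass = self.data.const_compat @ self.pi
        with np.errstate(divide="ignore"):
            return np.log(self.params.pinv * mass)

    # ------------------------------------------------------------------
    def set_branch_length(self, node_index: int, t: float) -> None:
        self.blen[node_index] = t
        self.nodes[node_index].length = t
        self._stale = True

    def _edge_p(self) -> np.ndarray:
        """Transition matrices per (node, category)."""
        ts = np.multiply.outer(self.blen, self.rates)  # (nn, ncat)
        p = self.eig.p_matrices(ts.ravel())
        return p.reshape(len(self.blen), len(self.rates), 4, 4)

    def _compute(self) -> None:
        """Lower partials and tip-ward messages for every node."""
        nn = len(self.nodes)
        ncat, npat = len(self.rates), self.data.n_pat
        self.P = self._edge_p()
        self.msg = [None] * nn        # message node -> parent, scaled
        self.msg_ls = [None] * nn     # accumulated log-scale (ncat, npat)
        self.lower = [None] * nn
        self.lower_ls = [None] * nn
        for i in range(nn):
            if self.tip_row[i] >= 0:
                low = np.broadcast_to(
                    self.data.tip_partials[self.tip_row[i]][None, :, :],
                    (ncat, npat, 4),
                )
                ls = np.zeros((ncat, npat))
            else:
                low = np.ones((ncat, npat, 4))
                ls = np.zeros((ncat, npat))
                for j in self.children[i]:
                    low = low * self.msg[j]
                    ls = ls + self.msg_ls[j]
                sc = low.max(axis=2)
                safe = np.where(sc > 0, sc, 1.0)
                low = low / safe[:, :, None]
                with np.errstate(divide="ignore"):
                    ls = ls + np.log(np.where(sc > 0, sc, _TINY))
            self.lower[i] = low
            self.lower_ls[i] = ls
            if i != self.root_idx:
                # msg(x) = sum_y P[x, y] low(y)  ==  low @ P^T
                self.msg[i] = np.matmul(
                    low, self.P[i].transpose(0, 2, 1)
                )
                self.msg_ls[i] = ls
        self._stale = False

    # ------------------------------------------------------------------
    def pattern_log_likelihoods(self) -> np.ndarray:
        if self._stale:
            self._compute()
        r = self.root_idx
        vals = self.lower[r] @ self.pi  # (ncat, npat)
        with np.errstate(divide="ignore"):
            lv = np.log(np.maximum(vals, _TINY)) + self.lower_ls[r]
        return self._combine(lv)

    def _combine(self, lv: np.ndarray) -> np.ndarray:
        """Mix gamma categories and the invariant class on log scale."""
        lv = lv + np.log(self.rate_weights)[:, None]
        m = lv.max(axis=0)
        m_safe = np.where(np.isfinite(m), m, 0.0)
        log_var = m_safe + np.log(
            np.exp(lv - m_safe[None, :]).sum(axis=0)
        )
        if self.params.pinv > 0:
            log_var = np.logaddexp(
                np.log1p(-self.params.pinv) + log_var, self._log_pinv_term
            )
        return log_var

    def site_log_likelihoods(self) -> np.ndarray:
        return self.pattern_log_likelihoods()[self.data.inverse]

    def log_likelihood(self) -> float:
        return float(self.pattern_log_likelihoods() @ self.data.counts)

    # ------------------------------------------------------------------
    # branch-length optimization
    # ------------------------------------------------------------------
    def _edge_loglik_closure(self, i: int):
        a, a_ls = self.upper[i], self.upper_ls[i]
        low, low_ls = self.lower[i], self.lower_ls[i]
        base_ls = a_ls + low_ls
        counts = self.data.counts

        def f(t: float) -> float:
            p = self.eig.p_matrices(t * self.rates)
            vals = (np.matmul(a, p) * low).sum(axis=2)
            with np.errstate(divide="ignore"):
                lv = np.log(np.maximum(vals, _TINY)) + base_ls
            return float(self._combine(lv) @ counts)

        return f

    def _compute_upper_for(self, targets: list[int]) -> None:
        """Upper partials only along root-to-target paths (memoized)."""
        nn = len(self.nodes)
        self.upper = [None] * nn
        self.upper_ls = [None] * nn

        def build(i: int) -> None:
            if self.upper[i] is not None:
                return
            p = self.parent[i]
            if p == self.root_idx:
                a = np.ones_like(self.lower[i]) * self.pi[None, None, :]
                ls = np.zeros_like(self.lower_ls[i])
            else:
                build(p)
                a = np.matmul(self.upper[p], self.P[p])
                ls = self.upper_ls[p].copy()
            for j in self.children[p]:
                if j == i:
                    continue
                a = a * self.msg[j]
                ls = ls + self.msg_ls[j]
            sc = a.max(axis=2)
            safe = np.where(sc > 0, sc, 1.0)
            a = a / safe[:, :, None]
            with np.errstate(divide="ignore"):
                ls = ls + np.log(np.where(sc > 0, sc, _TINY))
            self.upper[i] = a
            self.upper_ls[i] = ls

        for t in targets:
            if t != self.root_idx:
                build(t)

    def _optimize_one_edge(
        self, i: int, max_len: float, xatol: float
    ) -> float:
        f = self._edge_loglik_closure(i)
        f_cur = f(self.blen[i])
        res = minimize_scalar(
            lambda t: -f(t),
            bounds=(1e-8, max_len),
            method="bounded",
            options={"xatol": xatol, "maxiter": 40},
        )
        if -res.fun >= f_cur:
            self.set_branch_length(i, float(res.x))
            return float(-res.fun)
        return f_cur

    def internal_edge_indices(self) -> list[int]:
        """Indices of NNI-eligible edges, in ``tree.internal_edges``
        order (both are postorder)."""
        return [
            i
            for i in range(len(self.nodes))
            if i != self.root_idx and self.children[i]
        ]

    def nni_screen(self) -> np.ndarray:
        """Exact log-likelihood of every NNI neighbor at the current
        branch lengths, computed in place from the stored partials.

        Returns an array of shape (n_internal_edges, 2) aligned with
        ``tree.internal_edges()`` and the ``which`` argument of
        ``nni_move``: entry (e, w) swaps child w of the edge's child
        node with the first sibling on the parent side.
        """
        if self._stale:
            self._compute()
        edges = self.internal_edge_indices()
        self._compute_upper_for(edges)
        counts = self.data.counts
        out = np.empty((len(edges), 2))
        for k, ci in enumerate(edges):
            p = self.parent[ci]
            if p == self.root_idx:
                u = np.ones_like(self.lower[ci]) * self.pi[None, None, :]
                ls_u = np.zeros_like(self.lower_ls[ci])
            else:
                u = np.matmul(self.upper[p], self.P[p])
                ls_u = self.upper_ls[p]
            d = next(j for j in self.children[p] if j != ci)
            base, ls_base = u, ls_u
            for j in self.children[p]:
                if j in (ci, d):
                    continue
                base = base * self.msg[j]
                ls_base = ls_base + self.msg_ls[j]
            a_i, b_i = self.children[ci]
            pt = self.P[ci].transpose(0, 2, 1)
            for w, (near, far) in enumerate(
                ((a_i, b_i), (b_i, a_i))
            ):
                # move child ``near`` to the parent side, child ``d`` in
                left = base * self.msg[near]
                right = self.msg[d] * self.msg[far]
                vals = (left * np.matmul(right, pt)).sum(axis=2)
                ls = (
                    ls_base
                    + self.msg_ls[near]
                    + self.msg_ls[d]
                    + self.msg_ls[far]
                )
                with np.errstate(divide="ignore"):
                    lv = np.log(np.maximum(vals, _TINY)) + ls
                out[k, w] = float(self._combine(lv) @ counts)
        return out

    def _batched_branch_round(
        self, targets: list[int], max_len: float
    ) -> None:
        """One round optimizing all target edges at once.

        Uses the stale-partials approximation (partials fixed at the
        round start) and a vectorized golden-section search on a log
        branch-length scale.
        """
        if self._stale:
            self._compute()
        self._compute_upper_for(targets)
        a = np.stack([self.upper[i] for i in targets])
        low = np.stack([self.lower[i] for i in targets])
        base_ls = np.stack(
            [self.upper_ls[i] + self.lower_ls[i] for i in targets]
        )
        counts = self.data.counts
        ne, ncat = len(targets), len(self.rates)
        w = self.rate_weights
        log_pinv = self._log_pinv_term
        pvar = 1.0 - self.params.pinv
        m_ref = base_ls.max(axis=1)                      # (ne, npat)
        scale_w = np.exp(base_ls - m_ref[:, None, :]) * w[None, :, None]
        pinv_part = (
            np.exp(log_pinv[None, :] - m_ref)
            if self.params.pinv > 0
            else 0.0
        )
        u, uinv, lam = self.eig.u, self.eig.uinv, self.eig.vals
        rates = self.rates

        def evaluate(t: np.ndarray, derivs: bool):
            """Conditional logL per edge and (optionally) d/dx, d2/dx2
            with x = log t."""
            s = t[:, None] * rates[None, :]              # (ne, ncat)
            e = np.exp(np.multiply.outer(s, lam))        # (ne, ncat, 4)
            p0 = np.matmul(u[None, None] * e[..., None, :], uinv)
            np.clip(p0, 0.0, None, out=p0)
            v0 = (np.matmul(a, p0) * low).sum(axis=3)
            f0 = (v0 * scale_w).sum(axis=1)              # (ne, npat)
            dd = pvar * f0 + pinv_part
            dd = np.maximum(dd, _TINY)
            ll = (np.log(dd) + m_ref) @ counts           # (ne,)
            if not derivs:
                return ll, None, None
            le = e * lam[None, None, :]
            p1 = np.matmul(u[None, None] * le[..., None, :], uinv)
            p2 = np.matmul(
                u[None, None] * (le * lam[None, None, :])[..., None, :],
                uinv,
            )
            v1 = (np.matmul(a, p1) * low).sum(axis=3) * rates[None, :, None]
            v2 = (np.matmul(a, p2) * low).sum(axis=3) * (
                rates[None, :, None] ** 2
            )
            f1 = (v1 * scale_w).sum(axis=1)
            f2 = (v2 * scale_w).sum(axis=1)
            r1 = pvar * f1 / dd
            g = r1 @ counts                              # dL/dt
            h = (pvar * f2 / dd - r1**2) @ counts        # d2L/dt2
            gx = g * t                                   # dL/dx
            hx = h * t * t + g * t                       # d2L/dx2
            return ll, gx, hx

        t0 = np.clip(
            np.array([self.blen[i] for i in targets]), 1e-8, max_len
        )
        x = np.log(t0)
        x_lo, x_hi = np.log(1e-8), np.log(max_len)
        ll_start, _, _ = evaluate(t0, derivs=False)
        for _ in range(8):
            t = np.exp(x)
            _, gx, hx = evaluate(t, derivs=True)
            concave = hx < -1e-12
            step = np.where(concave, -gx / np.where(concave, hx, -1.0),
                            np.sign(gx) * 1.0)
            step = np.clip(step, -2.0, 2.0)
            x = np.clip(x + step, x_lo, x_hi)
            if np.all(np.abs(step) < 1e-5):
                break
        t_new = np.exp(x)
        ll_end, _, _ = evaluate(t_new, derivs=False)
        final = np.where(ll_end >= ll_start, t_new, t0)
        for k, i in enumerate(targets):
            self.set_branch_length(i, float(final[k]))
        # all conditional values at the round's start coincide with the
        # joint log-likelihood there
        return float(ll_start[0])

    def optimize_branch_lengths(
        self, rounds: int = 2, edges: list[int] | None = None,
        max_len: float = 20.0, fresh: bool = False, xatol: float = 1e-5,
    ) -> float:
        """Per-edge 1-D optimization of branch lengths.

        The default mode optimizes all edges of a round against the
        partials computed at the start of the round; if that ever
        lowers the likelihood (rare), the round is redone with partials
        refreshed before every edge, which makes each accepted step an
        exact conditional maximum and the trace monotone.
        """
        targets = edges
        if targets is None:
            targets = [
                i for i in range(len(self.nodes)) if i != self.root_idx
            ]
        best = None
        for _ in range(rounds):
            saved = self.blen.copy()
            if not fresh:
                ll_before = self._batched_branch_round(targets, max_len)
                if best is None:
                    best = ll_before
                cur = self.log_likelihood()
                if cur < best - 1e-9:  # stale partials misled us
                    for i in targets:
                        self.set_branch_length(i, saved[i])
                else:
                    if cur - best < 1e-6:
                        return cur
                    best = cur
                    continue
            # exact per-edge refresh
            if best is None:
                best = self.log_likelihood()
            for i in targets:
                if self._stale:
                    self._compute()
                self._compute_upper_for([i])
                self._optimize_one_edge(i, max_len, xatol)
            cur = self.log_likelihood()
            if cur - best < 1e-6:
                return max(cur, best)
            best = cur
        return self.log_likelihood()


@dataclass
class FitResult:
    tree: PhyloTree
    params: ModelParams
    loglik: float
    trace: list[float] = field(default_factory=list)


def site_log_likelihoods(
    tree: PhyloTree, aln: Alignment, params: ModelParams,
    tree_id: str = "tree",
) -> SiteLogLikelihoods:
    engine = LikelihoodEngine(tree, AlignmentData(aln), params)
    return SiteLogLikelihoods(tree_id, engine.site_log_likelihoods())


def optimize_parameters(
    tree: PhyloTree,
    aln: Alignment,
    init: ModelParams | None = None,
    tol: float = 1e-4,
    max_rounds: int = 20,
    optimize_rates: bool = True,
    branch_rounds: int = 1,
    data: AlignmentData | None = None,
    joint_refine: bool = True,
) -> FitResult:
    """Coordinate ascent over branch lengths and model parameters.

    Base frequencies stay at their empirical (count) values; gamma
    shape, invariant proportion and the free TIM2 rate classes are
    refined by bounded 1-D line searches.  The returned likelihood is
    never below the starting one.
    """
    if data is None:
        data = AlignmentData(aln)
    if init is None:
        init = ModelParams(freqs=aln.empirical_frequencies(),
                           alpha=0.8, pinv=0.1)
    work = tree.copy()
    engine = LikelihoodEngine(work, data, init)
    trace = [engine.log_likelihood()]
    if not np.isfinite(trace[0]):
        raise ArithmeticError("non-finite likelihood at start of search")

    def _line_search(name: str, lo: float, hi: float, log_space: bool):
        current = getattr(engine.params, name)

        def apply(v: float):
            engine._set_model(engine.params.with_(**{name: v}))

        def obj(x: float) -> float:
            v = 10 ** x if log_space else x
            apply(v)
            return -engine.log_likelihood()

        x0 = np.log10(current) if log_space else current
        res = minimize_scalar(
            obj, bounds=(lo, hi), method="bounded",
            options={"xatol": 3e-4},
        )
        best = 10 ** res.x if log_space else float(res.x)
        if -res.fun < -obj(x0):  # keep the better of (current, found)
            best = current
        apply(best)

    def _joint_alpha_pinv():
        """Joint refinement of (alpha, pinv, global branch scale).

        The three quantities trade off along a likelihood ridge —
        raising pinv calls for proportionally longer branches on the
        variable fraction — which 1-D sweeps traverse very slowly.
        """
        from scipy.optimize import minimize

        cur_a = engine.params.alpha
        cur_p = engine.params.pinv
        base = engine.blen.copy()
        best = [engine.log_likelihood(), cur_a, cur_p, 1.0]

        def obj(x):
            a = float(np.clip(10 ** x[0], 0.02, 100.0))
            p = float(np.clip(x[1], 0.0, 0.85))
            s = float(np.clip(10 ** x[2], 0.2, 5.0))
            engine.blen = base * s
            engine._set_model(engine.params.with_(alpha=a, pinv=p))
            ll = engine.log_likelihood()
            if ll > best[0]:
                best[:] = [ll, a, p, s]
            return -ll

        minimize(
            obj, x0=[np.log10(cur_a), cur_p, 0.0],
            method="Nelder-Mead",
            options={"maxfev": 80, "xatol": 5e-4, "fatol": 1e-7},
        )
        engine.blen = base * best[3]
        for i, node in enumerate(engine.nodes):
            if i != engine.root_idx:
                node.length = float(engine.blen[i])
        engine._set_model(
            engine.params.with_(alpha=best[1], pinv=best[2])
        )

    for _ in range(max_rounds):
        prev = trace[-1]
        engine.optimize_branch_lengths(rounds=branch_rounds)
        _line_search("alpha", -1.7, 2.0, log_space=True)
        _line_search("pinv", 0.0, 0.85, log_space=False)
        if joint_refine:
            _joint_alpha_pinv()
        if optimize_rates:
            for nm in ("r_ag", "r_ct", "r_cg_gt"):
                _line_search(nm, -1.5, 2.0, log_space=True)
        cur = engine.log_likelihood()
        if not np.isfinite(cur):
            raise ArithmeticError("non-finite likelihood during search")
        trace.append(cur)
        if cur - prev < tol:
            break
    return FitResult(work, engine.params, trace[-1], trace)


def optimize_branch_lengths_only(
    tree: PhyloTree,
    aln: Alignment,
    params: ModelParams,
    rounds: int = 2,
    data: AlignmentData | None = None,
) -> FitResult:
    """Fixed topology and model; refit branch lengths only."""
    if data is None:
        data = AlignmentData(aln)
    work = tree.copy()
    engine = LikelihoodEngine(work, data, params)
    ll = engine.optimize_branch_lengths(rounds=rounds)
    return FitResult(work, params, ll, [ll])
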