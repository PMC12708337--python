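"""Tree search: ML hill climbing over NNI moves, and Fitch parsimony.

Both searches start from a uniform random topology and climb by
nearest-neighbor interchanges, matching the random-start hill-climbing
strategy of standard ML software.  Parsimony machinery backs the ILD
permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alignment import Alignment
from .likelihood import AlignmentData, LikelihoodEngine, optimize_parameters
from .model import ModelParams
from .tree import PhyloTree, Node, nni_move, random_tree


@dataclass
class SearchResult:
    tree: PhyloTree
    score: float
    n_accepted: int
    seed: int
    params: Optional[ModelParams] = None
    trace: list[float] = field(default_factory=list)


# ----------------------------------------------------------------------
# maximum likelihood
# ----------------------------------------------------------------------
def ml_search(
    aln: Alignment,
    params: Optional[ModelParams] = None,
    seed: int = 0,
    restarts: int = 1,
    nni_tol: float = 1e-3,
    final_rounds: int = 4,
    optimize_rates: bool = True,
    data: Optional[AlignmentData] = None,
) -> SearchResult:
    """Random-start NNI hill climbing with branch re-optimization.

    Each iteration scores every NNI neighbor after re-optimizing the
    rearranged edge, accepts the best strictly improving move, and
    finishes with a full parameter/branch-length optimization pass.
    Ties are broken toward the lexicographically smallest Newick string
    for reproducibility.
    """
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if data is None:
        data = AlignmentData(aln)
    best: Optional[SearchResult] = None
    for r in range(restarts):
        res = _ml_search_once(
            aln, data, params, seed + 1000 * r, nni_tol,
            final_rounds, optimize_rates,
        )
        if (
            best is None
            or res.score > best.score + 1e-9
            or (
                abs(res.score - best.score) <= 1e-9
                and res.tree.to_newick() < best.tree.to_newick()
            )
        ):
            best = res
    best.seed = seed
    return best


def _ml_search_once(
    aln, data, params, seed, nni_tol, final_rounds, optimize_rates
) -> SearchResult:
    tree = random_tree(data.taxa, seed, branch_length=0.1)
    if params is None:
        params = ModelParams(
            freqs=aln.empirical_frequencies(), alpha=0.8, pinv=0.1
        )
    engine = LikelihoodEngine(tree, data, params)
    cur = engine.optimize_branch_lengths(rounds=2)
    trace = [cur]
    accepted = 0
    screen_top = 4  # neighbors kept for branch re-optimization
    while True:
        # exact in-place screen of all neighbors at current lengths
        scores = engine.nni_screen()
        order = np.argsort(-scores.ravel())

        def _realize(flat_index: int):
            e, w = divmod(int(flat_index), 2)
            cand, central = nni_move(tree, e, w)
            return cand, LikelihoodEngine(cand, data, params)

        best_ll, best_cand = -np.inf, None
        for fi in order[:screen_top]:
            cand, cand_engine = _realize(fi)
            ll = cand_engine.optimize_branch_lengths(rounds=1)
            if ll > best_ll + 1e-9 or (
                best_cand is not None
                and abs(ll - best_ll) <= 1e-9
                and cand.to_newick() < best_cand[0].to_newick()
            ):
                best_ll, best_cand = ll, (cand, cand_engine)
        if best_cand is not None and best_ll > cur + nni_tol:
            tree, engine = best_cand
            cur = best_ll  # engine already re-optimized during scoring
            accepted += 1
            trace.append(cur)
            continue
        # stall: deeper branch pass on the current tree
        improved = engine.optimize_branch_lengths(rounds=3)
        if improved > cur + nni_tol:
            cur = improved
            trace.append(cur)
            continue
        # endgame: deepen branch re-optimization for the neighbors whose
        # screened score is close enough to plausibly overtake after
        # refitting; affordable only on smaller trees, where
        # weak-signal local optima are also most common
        if len(data.taxa) > 25:
            break
        flat = scores.ravel()
        plausible = [
            fi for fi in order[screen_top:] if flat[fi] > cur - 15.0
        ][:8]
        best_ll, best_cand = -np.inf, None
        for fi in list(order[:screen_top]) + plausible:
            cand, cand_engine = _realize(fi)
            ll = cand_engine.optimize_branch_lengths(rounds=2)
            if ll > best_ll:
                best_ll, best_cand = ll, (cand, cand_engine)
        if best_cand is not None and best_ll > cur + nni_tol:
            tree, engine = best_cand
            cur = engine.optimize_branch_lengths(rounds=1)
            accepted += 1
            trace.append(cur)
            continue
        break
    fit = optimize_parameters(
        tree, aln, init=params, max_rounds=final_rounds,
        optimize_rates=optimize_rates, data=data,
    )
    trace.extend(fit.trace[1:])
    return SearchResult(
        fit.tree, fit.loglik, accepted, seed, fit.params, trace
    )


def _edges_around(engine: "LikelihoodEngine", central: Node) -> list[int]:
    """Indices of the rearranged edge and its four flanking edges."""
    ci = engine.idx[id(central)]
    out = [ci]
    out.extend(engine.children[ci])
    p = engine.parent[ci]
    if p >= 0:
        if p != engine.root_idx:
            out.append(p)
        out.extend(j for j in engine.children[p] if j != ci)
    return out


# ----------------------------------------------------------------------
# parsimony
# ----------------------------------------------------------------------
class ParsimonyData:
    """Pattern-compressed bitmask matrix for Fitch counting."""

    def __init__(self, aln: Alignment):
        self.taxa = list(aln.taxa)
        masks = aln.masks()
        pats, counts = np.unique(masks.T, axis=0, return_counts=True)
        self.patterns = pats.T  # (ntaxa, npat)
        self.counts = counts
        self.row = {t: i for i, t in enumerate(self.taxa)}


def fitch_length(
    tree: PhyloTree, aln: Alignment, data: Optional[ParsimonyData] = None
) -> int:
    """Fitch parsimony length summed over sites.

    Ambiguity codes and gaps contribute their compatible-state sets, so
    fully missing residues never force a change.
    """
    if data is None:
        data = ParsimonyData(aln)
    labels = tree.leaf_labels()
    if set(labels) != set(data.taxa):
        missing = sorted(set(labels) ^ set(data.taxa))
        raise ValueError(f"tree/alignment label mismatch: {missing}")
    total = np.zeros(len(data.counts), dtype=np.int64)
    states: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf():
            states[id(node)] = data.patterns[data.row[node.name]]
            continue
        it = iter(node.children)
        cur = states[id(next(it))]
        for child in it:
            c = states[id(child)]
            inter = cur & c
            union = cur | c
            miss = inter == 0
            total += miss
            cur = np.where(miss, union, inter)
        states[id(node)] = cur
    return int(total @ data.counts)


def parsimony_search(
    aln: Alignment,
    seed: int = 0,
    restarts: int = 1,
    data: Optional[ParsimonyData] = None,
) -> SearchResult:
    """Random-start NNI hill climbing minimizing Fitch length."""
    if aln.n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    if data is None:
        data = ParsimonyData(aln)
    best: Optional[SearchResult] = None
    for r in range(restarts):
        res = _parsimony_once(aln, data, seed + 1000 * r)
        if (
            best is None
            or res.score < best.score
            or (
                res.score == best.score
                and res.tree.to_newick() < best.tree.to_newick()
            )
        ):
            best = res
    best.seed = seed
    return best


def _parsimony_once(aln, data, seed) -> SearchResult:
    tree = random_tree(data.taxa, seed)
    cur = fitch_length(tree, aln, data)
    trace = [cur]
    accepted = 0
    improved = True
    while improved:
        improved = False
        n_int = len(tree.internal_edges())
        best_len, best_tree = cur, None
        for e in range(n_int):
            for which in (0, 1):
                cand, _ = nni_move(tree, e, which)
                length = fitch_length(cand, aln, data)
                if length < best_len or (
                    best_tree is not None
                    and length == best_len
                    and cand.to_newick() < best_tree.to_newick()
                ):
                    best_len, best_tree = length, cand
        if best_tree is not None and best_len < cur:
            tree, cur = best_tree, best_len
            accepted += 1
            trace.append(cur)
            improved = True
    return SearchResult(tree, float(cur), accepted, seed, None, trace)
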