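"""Likelihood-based topology tests and the parsimony ILD test.

All seven likelihood tests (bp-RELL, KH, SH, weighted KH/SH, c-ELW,
AU) share one RELL resampling engine: bootstrap replicates resample
per-site log-likelihoods with replacement — identically across the
candidate trees — and the tests differ only in how replicate totals
are centered, standardized and compared.  The ILD test is a
permutation test on the excess parsimony length of a combined matrix
over the sum of its partitions' lengths.

Decision convention for a gene pair: each gene's tree is evaluated
against the other gene's alignment; *incongruent* means both
directions reject at level alpha, *congruent* means neither does, and
a single rejection is *ambiguous*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp, ndtr, ndtri

from .alignment import Alignment
from .inference import (
    ParsimonyData,
    SearchResult,
    fitch_length,
    ml_search,
    parsimony_search,
)
from .likelihood import AlignmentData, LikelihoodEngine, optimize_parameters
from .model import ModelParams
from .tree import PhyloTree

LIKELIHOOD_TESTS = ("bp_rell", "p_kh", "p_wkh", "p_sh", "p_wsh", "c_elw", "p_au")
ALL_TESTS = LIKELIHOOD_TESTS + ("p_ild",)

DEFAULT_AU_SCALES = tuple(np.round(np.arange(0.5, 1.41, 0.1), 2))


# ----------------------------------------------------------------------
# RELL engine
# ----------------------------------------------------------------------
def rell_resample(
    site_ll: np.ndarray,
    b_reps: int,
    scale: float = 1.0,
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """RELL bootstrap totals, shape (B, n_trees).

    Each replicate draws ``round(scale * n)`` site indices with
    replacement — the same indices for every tree — and sums their
    log-likelihoods.
    """
    site_ll = np.atleast_2d(np.asarray(site_ll, dtype=float))
    n_trees, n_sites = site_ll.shape
    if n_sites < 1 or b_reps < 1 or scale <= 0:
        raise ValueError("need n >= 1, B >= 1, scale > 0")
    m = max(1, int(round(scale * n_sites)))
    rng = np.random.default_rng(seed)
    # sites sharing a log-likelihood column are interchangeable, so the
    # draw reduces to a multinomial over unique columns
    cols, counts = np.unique(site_ll.T, axis=0, return_counts=True)
    pvals = counts / counts.sum()
    draws = rng.multinomial(m, pvals, size=b_reps)
    return draws @ cols


def _bp_from_totals(totals: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Bootstrap proportions with ties split evenly among the leaders."""
    best = totals.max(axis=1, keepdims=True)
    is_max = totals >= best - tol
    weights = is_max / is_max.sum(axis=1, keepdims=True)
    return weights.mean(axis=0)


def bp_rell(
    site_ll: np.ndarray, b_reps: int, seed=0,
    totals: np.ndarray | None = None,
) -> np.ndarray:
    """RELL bootstrap proportion per tree (sums to 1)."""
    if totals is None:
        totals = rell_resample(site_ll, b_reps, 1.0, seed)
    return _bp_from_totals(totals)


def _pairwise_sds(site_ll: np.ndarray) -> np.ndarray:
    """sd of the total log-likelihood difference for every tree pair."""
    n = site_ll.shape[1]
    diffs = site_ll[:, None, :] - site_ll[None, :, :]
    sd = diffs.std(axis=2, ddof=1) * np.sqrt(n)
    return sd


def kh_test(
    site_ll: np.ndarray, b_reps: int, seed=0, weighted: bool = False,
    totals: np.ndarray | None = None,
) -> np.ndarray:
    """One-sided Kishino-Hasegawa p-value per tree via centered RELL.

    For tree m the statistic is ``L_best - L_m`` on the observed data;
    the null is the centered bootstrap distribution of the same
    difference.  The weighted variant standardizes observed and
    replicate differences by the difference's standard deviation.
    """
    site_ll = np.atleast_2d(np.asarray(site_ll, dtype=float))
    n_trees = site_ll.shape[0]
    obs = site_ll.sum(axis=1)
    best = int(np.argmax(obs))
    if totals is None:
        totals = rell_resample(site_ll, b_reps, 1.0, seed)
    sds = _pairwise_sds(site_ll)
    p = np.ones(n_trees)
    for m in range(n_trees):
        if m == best:
            ref = int(np.argsort(obs)[-2]) if n_trees > 1 else m
        else:
            ref = best
        sd = sds[ref, m]
        if sd < 1e-12:
            p[m] = 1.0  # identical vectors cannot reject
            continue
        delta = obs[ref] - obs[m]
        d_star = totals[:, ref] - totals[:, m]
        d_star = d_star - d_star.mean()
        if weighted:
            delta, d_star = delta / sd, d_star / sd
        p[m] = float((d_star >= delta).mean())
    return p


def sh_test(
    site_ll: np.ndarray, b_reps: int, seed=0, weighted: bool = False,
    totals: np.ndarray | None = None,
) -> np.ndarray:
    """Shimodaira-Hasegawa p-value per tree (multiplicity-corrected).

    Replicate totals are centered tree-by-tree; the null statistic for
    tree m in replicate b is ``max_k centered_k - centered_m``, which
    dominates the KH null and makes p_sh >= p_kh.
    """
    site_ll = np.atleast_2d(np.asarray(site_ll, dtype=float))
    n_trees = site_ll.shape[0]
    obs = site_ll.sum(axis=1)
    if totals is None:
        totals = rell_resample(site_ll, b_reps, 1.0, seed)
    centered = totals - totals.mean(axis=0, keepdims=True)
    p = np.ones(n_trees)
    if not weighted:
        null_max = centered.max(axis=1)
        for m in range(n_trees):
            delta = obs.max() - obs[m]
            stat = null_max - centered[:, m]
            p[m] = float((stat >= delta).mean())
        return p
    sds = _pairwise_sds(site_ll)
    safe = np.where(sds < 1e-12, np.inf, sds)
    for m in range(n_trees):
        obs_stat = np.max((obs - obs[m]) / safe[:, m])
        rep = (centered - centered[:, m][:, None]) / safe[None, :, m]
        stat = rep.max(axis=1)
        p[m] = float((stat >= max(obs_stat, 0.0)).mean())
    return p


def elw(
    site_ll: np.ndarray, b_reps: int, seed=0,
    totals: np.ndarray | None = None,
) -> np.ndarray:
    """Expected likelihood weights: mean normalized weight per tree."""
    if totals is None:
        totals = rell_resample(site_ll, b_reps, 1.0, seed)
    logw = totals - logsumexp(totals, axis=1, keepdims=True)
    return np.exp(logw).mean(axis=0)


@dataclass
class AuResult:
    p_values: np.ndarray
    fallback: np.ndarray  # True where the curve fit was degenerate


def au_test(
    site_ll: np.ndarray,
    b_per_scale: int,
    scales: Sequence[float] = DEFAULT_AU_SCALES,
    seed: int | np.random.SeedSequence = 0,
) -> AuResult:
    """Approximately unbiased test via multiscale RELL bootstrap.

    For each resampling scale r the bootstrap proportion bp_r of each
    tree attaining the maximum is recorded; a weighted least-squares
    fit of ``ndtri(1 - bp_r) = d*sqrt(r) + c/sqrt(r)`` (binomial
    weights) yields ``p_au = 1 - Phi(d - c)``.  Trees whose proportions
    are degenerate at every scale fall back to the bp-RELL call (0 or
    1) and are flagged.
    """
    site_ll = np.atleast_2d(np.asarray(site_ll, dtype=float))
    n_trees = site_ll.shape[0]
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    children = ss.spawn(len(scales))
    bps = np.empty((len(scales), n_trees))
    for k, (r, child) in enumerate(zip(scales, children)):
        totals = rell_resample(site_ll, b_per_scale, r, child)
        bps[k] = _bp_from_totals(totals)
    return au_from_bootstrap_proportions(bps, scales, b_per_scale)


def au_from_bootstrap_proportions(
    bps: np.ndarray,
    scales: Sequence[float],
    b_per_scale: int,
) -> AuResult:
    """Probit-scale curve fit of multiscale bootstrap proportions.

    ``bps`` has shape (n_scales, n_trees).  Fits
    ``ndtri(1 - bp_r) = d*sqrt(r) + c/sqrt(r)`` by weighted least
    squares with binomial weights and returns ``1 - Phi(d - c)`` per
    tree; trees degenerate at every scale fall back to the bp-RELL
    call and are flagged.
    """
    bps = np.asarray(bps, dtype=float)
    n_trees = bps.shape[1]
    lo, hi = 1.0 / (2 * b_per_scale), 1.0 - 1.0 / (2 * b_per_scale)
    clamped = np.clip(bps, lo, hi)
    p = np.empty(n_trees)
    fb = np.zeros(n_trees, dtype=bool)
    sqrt_r = np.sqrt(np.asarray(scales, dtype=float))
    for m in range(n_trees):
        usable = (bps[:, m] > lo) & (bps[:, m] < hi)
        if usable.sum() < 2:
            fb[m] = True
            p[m] = 1.0 if bps[:, m].mean() > 0.5 else 0.0
            continue
        y = ndtri(1.0 - clamped[usable, m])
        x = np.column_stack([sqrt_r[usable], 1.0 / sqrt_r[usable]])
        bp = clamped[usable, m]
        dens = np.exp(-0.5 * y**2) / np.sqrt(2 * np.pi)
        w = b_per_scale * dens**2 / (bp * (1.0 - bp))
        wx = x * w[:, None]
        coef, *_ = np.linalg.lstsq(wx.T @ x, wx.T @ y, rcond=None)
        d, c = coef
        p[m] = float(1.0 - ndtr(d - c))
    return AuResult(p, fb)


# ----------------------------------------------------------------------
# batteries and decisions
# ----------------------------------------------------------------------
@dataclass
class TestBattery:
    """All seven likelihood statistics for one candidate-tree set
    evaluated against one alignment."""

    tree_ids: list[str]
    bp_rell: np.ndarray
    p_kh: np.ndarray
    p_wkh: np.ndarray
    p_sh: np.ndarray
    p_wsh: np.ndarray
    c_elw: np.ndarray
    p_au: np.ndarray
    au_fallback: np.ndarray
    b_reps: int
    seed: int

    def value(self, test: str, tree_index: int) -> float:
        return float(getattr(self, test)[tree_index])

    def rejects(self, test: str, tree_index: int, alpha: float) -> bool:
        # bp-RELL and c-ELW are confidence shares, the rest p-values;
        # in both cases "below alpha" is the rejection rule
        return self.value(test, tree_index) < alpha


def test_battery(
    site_ll: np.ndarray,
    tree_ids: Sequence[str],
    b_reps: int = 10000,
    seed: int = 0,
    au_scales: Sequence[float] = DEFAULT_AU_SCALES,
) -> TestBattery:
    """Run the full seven-test battery on per-site log-likelihoods."""
    ss = np.random.SeedSequence(seed)
    s_rell, s_au = ss.spawn(2)
    # one RELL replicate set feeds every unit-scale statistic, the
    # usual convention of tree-test batteries
    totals = rell_resample(site_ll, b_reps, 1.0, s_rell)
    au = au_test(site_ll, b_reps, au_scales, s_au)
    return TestBattery(
        tree_ids=list(tree_ids),
        bp_rell=bp_rell(site_ll, b_reps, totals=totals),
        p_kh=kh_test(site_ll, b_reps, totals=totals),
        p_wkh=kh_test(site_ll, b_reps, weighted=True, totals=totals),
        p_sh=sh_test(site_ll, b_reps, totals=totals),
        p_wsh=sh_test(site_ll, b_reps, weighted=True, totals=totals),
        c_elw=elw(site_ll, b_reps, totals=totals),
        p_au=au.p_values,
        au_fallback=au.fallback,
        b_reps=b_reps,
        seed=seed,
    )


@dataclass
class CongruenceDecision:
    """Three-state reciprocal call for one gene pair and one test."""

    test: str
    reject_ab: bool  # alignment A rejects B's tree
    reject_ba: bool  # alignment B rejects A's tree
    alpha: float

    @property
    def call(self) -> str:
        if self.reject_ab and self.reject_ba:
            return "incongruent"
        if not self.reject_ab and not self.reject_ba:
            return "congruent"
        return "ambiguous"


# ----------------------------------------------------------------------
# ILD
# ----------------------------------------------------------------------
@dataclass
class IldResult:
    d_observed: int
    d_permuted: np.ndarray
    n_permutations: int
    p_value: float
    low_signal: bool = False


def ild_test(
    part_a: Alignment,
    part_b: Alignment,
    n_permutations: int = 99,
    seed: int = 0,
    restarts: int = 1,
) -> IldResult:
    """Incongruence length difference permutation test.

    ``D = L(combined) - [L(A) + L(B)]`` in parsimony steps, with the
    null built by shuffling site assignment into pseudo-partitions of
    the original sizes; ``p = (1 + #{D* >= D}) / (R + 1)``.  Heuristic
    search can in principle leave D slightly negative, in which case it
    is clamped at zero.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if set(part_a.taxa) != set(part_b.taxa):
        raise ValueError("partitions must share the same taxa")
    part_b = part_b.subset_taxa(part_a.taxa)
    combined = part_a.concat(part_b)
    rng = np.random.default_rng(seed)

    def _variable(aln: Alignment) -> int:
        masks = aln.masks()
        agg = np.bitwise_and.reduce(masks, axis=0)
        return int((agg == 0).sum())

    if _variable(part_a) < 1 or _variable(part_b) < 1:
        return IldResult(0, np.zeros(n_permutations, dtype=int),
                         n_permutations, 1.0, low_signal=True)

    def _length(aln: Alignment, s: int) -> int:
        return int(parsimony_search(aln, seed=s, restarts=restarts).score)

    n_a = part_a.n_sites
    l_comb = _length(combined, int(rng.integers(2**31)))
    d_obs = l_comb - (
        _length(part_a, int(rng.integers(2**31)))
        + _length(part_b, int(rng.integers(2**31)))
    )
    d_obs = max(d_obs, 0)
    d_perm = np.empty(n_permutations, dtype=int)
    for r in range(n_permutations):
        order = rng.permutation(combined.n_sites)
        pa = combined.columns(order[:n_a])
        pb = combined.columns(order[n_a:])
        # heuristic-search noise can leave the difference slightly
        # negative; clamp like the observed statistic
        d_perm[r] = max(
            l_comb
            - (
                _length(pa, int(rng.integers(2**31)))
                + _length(pb, int(rng.integers(2**31)))
            ),
            0,
        )
    p = (1.0 + np.sum(d_perm >= d_obs)) / (n_permutations + 1.0)
    return IldResult(int(d_obs), d_perm, n_permutations, float(p))


# ----------------------------------------------------------------------
# reciprocal design
# ----------------------------------------------------------------------
@dataclass
class ReciprocalResult:
    decisions: dict[str, CongruenceDecision]
    battery_on_a: TestBattery
    battery_on_b: TestBattery
    ild: Optional[IldResult] = None
    tree_a: Optional[PhyloTree] = None
    tree_b: Optional[PhyloTree] = None


@dataclass
class TestConfig:
    """Shared knobs of the reciprocal congruence machinery."""

    __test__ = False  # not a pytest collectible despite the name

    alpha: float = 0.05
    b_reps: int = 10000
    au_scales: tuple[float, ...] = DEFAULT_AU_SCALES
    ild_permutations: int = 99
    restarts: int = 1
    optimize_rates: bool = True
    reopt_model: bool = False   # refit alpha/pinv per topology per alignment
    final_rounds: int = 3
    run_ild: bool = False


def evaluate_topologies(
    alignment: Alignment,
    trees: Sequence[PhyloTree],
    params: ModelParams,
    config: TestConfig,
    data: AlignmentData | None = None,
    skip_reopt: Sequence[int] = (),
) -> np.ndarray:
    """Per-site log-likelihood matrix for candidate topologies.

    Branch lengths (and optionally alpha/pinv) are re-optimized per
    topology on the evaluation alignment before the vectors are taken,
    matching standard tree-test practice.  Indices in ``skip_reopt``
    mark trees whose lengths were already fitted on this alignment
    (typically the alignment's own search tree).
    """
    if data is None:
        data = AlignmentData(alignment)
    rows = []
    for k, tree in enumerate(trees):
        if k in skip_reopt:
            engine = LikelihoodEngine(tree.copy(), data, params)
        elif config.reopt_model:
            fit = optimize_parameters(
                tree, alignment, init=params, max_rounds=2,
                optimize_rates=False, data=data,
            )
            engine = LikelihoodEngine(fit.tree, data, fit.params)
        else:
            engine = LikelihoodEngine(tree.copy(), data, params)
            engine.optimize_branch_lengths(rounds=2)
        rows.append(engine.site_log_likelihoods())
    return np.vstack(rows)


def reciprocal_congruence(
    gene_a: Alignment,
    gene_b: Alignment,
    config: TestConfig | None = None,
    seed: int = 0,
    tree_a: Optional[SearchResult] = None,
    tree_b: Optional[SearchResult] = None,
    data_a: Optional[AlignmentData] = None,
    data_b: Optional[AlignmentData] = None,
) -> ReciprocalResult:
    """Reciprocal topology tests between two gene alignments.

    Infers each gene's ML tree (unless provided), evaluates both
    topologies against each alignment, and combines the two rejection
    directions into the three-state congruence call per test.
    """
    if config is None:
        config = TestConfig()
    ss = np.random.SeedSequence(seed)
    s_a, s_b, s_ta, s_tb, s_ild = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    )
    if data_a is None:
        data_a = AlignmentData(gene_a)
    if data_b is None:
        data_b = AlignmentData(gene_b)
    if tree_a is None:
        tree_a = ml_search(
            gene_a, seed=s_ta, restarts=config.restarts,
            optimize_rates=config.optimize_rates,
            final_rounds=config.final_rounds, data=data_a,
        )
    if tree_b is None:
        tree_b = ml_search(
            gene_b, seed=s_tb, restarts=config.restarts,
            optimize_rates=config.optimize_rates,
            final_rounds=config.final_rounds, data=data_b,
        )
    ids = ["tree_a", "tree_b"]
    sll_a = evaluate_topologies(
        gene_a, [tree_a.tree, tree_b.tree], tree_a.params, config,
        data=data_a, skip_reopt=(0,),
    )
    sll_b = evaluate_topologies(
        gene_b, [tree_a.tree, tree_b.tree], tree_b.params, config,
        data=data_b, skip_reopt=(1,),
    )
    bat_a = test_battery(sll_a, ids, config.b_reps, s_a, config.au_scales)
    bat_b = test_battery(sll_b, ids, config.b_reps, s_b, config.au_scales)
    same_topology = tree_a.tree.rf_distance(tree_b.tree) == 0
    decisions: dict[str, CongruenceDecision] = {}
    for test in LIKELIHOOD_TESTS:
        if same_topology:
            rej_ab = rej_ba = False  # identical trees cannot conflict
        else:
            rej_ab = bat_a.rejects(test, 1, config.alpha)
            rej_ba = bat_b.rejects(test, 0, config.alpha)
        decisions[test] = CongruenceDecision(
            test, rej_ab, rej_ba, config.alpha
        )
    ild_res = None
    if config.run_ild:
        ild_res = ild_test(
            gene_a, gene_b, config.ild_permutations, s_ild,
            restarts=config.restarts,
        )
        rej = ild_res.p_value < config.alpha
        decisions["p_ild"] = CongruenceDecision(
            "p_ild", rej, rej, config.alpha
        )
    return ReciprocalResult(
        decisions, bat_a, bat_b, ild_res, tree_a.tree, tree_b.tree
    )
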