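"""The four congruence experiment designs.

* pairwise gene-by-gene summary matrices (15 x 15 for a full
  mitogenome dataset, diagonal congruent by construction);
* antigene (leave-one-out) matrices: each gene removed in turn and the
  14-gene complement tested against every remaining single gene;
* functional-category comparisons (CO / ND / AT / rRNA concatenations);
* taxon subsampling, re-running the pairwise design on randomly culled
  datasets.

Cells are symmetric by design: each unordered pair is evaluated once
with a seed derived from the pair's sorted names, then mirrored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import Alignment, PartitionedAlignment
from .inference import SearchResult, ml_search
from .likelihood import AlignmentData
from .toptests import (
    ALL_TESTS,
    LIKELIHOOD_TESTS,
    CongruenceDecision,
    ReciprocalResult,
    TestConfig,
    reciprocal_congruence,
)

logger = logging.getLogger(__name__)


def _has_variable_site(aln: Alignment) -> bool:
    masks = aln.masks()
    agg = np.bitwise_and.reduce(masks, axis=0)
    return bool((agg == 0).any())


@dataclass
class CongruenceMatrix:
    """Per-test three-state decisions for every partition pair."""

    names: list[str]
    alpha: float
    cells: dict[tuple[str, str], dict[str, CongruenceDecision]] = field(
        default_factory=dict
    )
    warnings: list[str] = field(default_factory=list)
    group_label: str = ""

    def call(self, a: str, b: str, test: str) -> str:
        if a == b:
            return "congruent"  # self-comparison, diagonal convention
        key = (a, b) if (a, b) in self.cells else (b, a)
        cell = self.cells.get(key)
        if cell is None or test not in cell:
            return "ambiguous"
        return cell[test].call

    def tests(self) -> list[str]:
        for cell in self.cells.values():
            return list(cell)
        return []

    def long_rows(self) -> list[dict]:
        rows = []
        for (a, b), cell in self.cells.items():
            for test, dec in cell.items():
                rows.append(
                    {
                        "partition_a": a,
                        "partition_b": b,
                        "test": test,
                        "reject_ab": dec.reject_ab,
                        "reject_ba": dec.reject_ba,
                        "call": dec.call,
                        "alpha": dec.alpha,
                    }
                )
        return rows


def congruent_proportion(
    matrix: CongruenceMatrix,
    test: str,
    orientation: str = "congruent",
    include_ambiguous_in_denominator: bool = True,
) -> float:
    """Fraction of unordered off-diagonal pairs with the given call.

    Ambiguous cells count toward the denominator but never the
    numerator (the default); the reciprocal design makes ordered pairs
    redundant.
    """
    names = matrix.names
    hits = denom = 0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            call = matrix.call(a, b, test)
            if call == "ambiguous" and not include_ambiguous_in_denominator:
                continue
            denom += 1
            if call == orientation:
                hits += 1
    return hits / denom if denom else float("nan")


def _pair_seed(master: int, a: str, b: str) -> int:
    lo, hi = sorted([a, b])
    key = f"{lo}|{hi}".encode()
    ss = np.random.SeedSequence([master, *key])
    return int(ss.generate_state(1)[0] % (2**31))


def _gene_trees(
    dataset: PartitionedAlignment,
    genes: Sequence[str],
    config: TestConfig,
    seed: int,
    cache: dict[str, tuple[Alignment, AlignmentData]],
) -> dict[str, SearchResult]:
    trees: dict[str, SearchResult] = {}
    for g in genes:
        aln = dataset.gene_alignment(g)
        data = AlignmentData(aln)
        cache[g] = (aln, data)
        s = int(
            np.random.SeedSequence([seed, *f"tree|{g}".encode()])
            .generate_state(1)[0] % (2**31)
        )
        trees[g] = ml_search(
            aln, seed=s, restarts=config.restarts,
            optimize_rates=config.optimize_rates,
            final_rounds=config.final_rounds, data=data,
        )
    return trees


def pairwise_matrix(
    dataset: PartitionedAlignment,
    config: TestConfig | None = None,
    seed: int = 0,
    genes: Optional[Sequence[str]] = None,
    group_label: str = "",
) -> CongruenceMatrix:
    """Reciprocal congruence tests for every unordered gene pair."""
    if config is None:
        config = TestConfig()
    names = list(genes) if genes is not None else dataset.gene_names
    if len(names) < 2:
        raise ValueError("need at least 2 partitions")
    matrix = CongruenceMatrix(names, config.alpha, group_label=group_label)
    cache: dict[str, tuple[Alignment, AlignmentData]] = {}
    trees = _gene_trees(dataset, names, config, seed, cache)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            cell = _compare(
                cache[a], cache[b], trees[a], trees[b], config,
                _pair_seed(seed, a, b), matrix, f"{a} vs {b}",
            )
            matrix.cells[(a, b)] = cell
    return matrix


def _compare(
    pack_a: tuple[Alignment, AlignmentData],
    pack_b: tuple[Alignment, AlignmentData],
    tree_a: Optional[SearchResult],
    tree_b: Optional[SearchResult],
    config: TestConfig,
    seed: int,
    matrix: CongruenceMatrix,
    label: str,
) -> dict[str, CongruenceDecision]:
    aln_a, data_a = pack_a
    aln_b, data_b = pack_b
    if not _has_variable_site(aln_a) or not _has_variable_site(aln_b):
        msg = f"{label}: no variable sites; cell marked ambiguous"
        logger.warning(msg)
        matrix.warnings.append(msg)
        tests = list(LIKELIHOOD_TESTS) + (
            ["p_ild"] if config.run_ild else []
        )
        return {
            t: CongruenceDecision(t, True, False, config.alpha)
            for t in tests
        }
    res = reciprocal_congruence(
        aln_a, aln_b, config, seed, tree_a=tree_a, tree_b=tree_b,
        data_a=data_a, data_b=data_b,
    )
    return res.decisions


@dataclass
class AntigeneResult:
    """removed gene -> (single gene -> decision per test)."""

    rows: dict[str, dict[str, dict[str, CongruenceDecision]]]
    alpha: float
    warnings: list[str] = field(default_factory=list)

    def congruent_fraction(self, removed: str, test: str) -> float:
        cells = self.rows[removed]
        calls = [cells[h][test].call for h in cells]
        return sum(c == "congruent" for c in calls) / len(calls)


def antigene_matrices(
    dataset: PartitionedAlignment,
    config: TestConfig | None = None,
    seed: int = 0,
    removed_genes: Optional[Sequence[str]] = None,
) -> AntigeneResult:
    """Leave-one-out design: anti-g (the other 14 genes concatenated)
    tested reciprocally against each single gene h != g."""
    if config is None:
        config = TestConfig()
    all_genes = dataset.gene_names
    removed = list(removed_genes) if removed_genes is not None else all_genes
    cache: dict[str, tuple[Alignment, AlignmentData]] = {}
    gene_trees = _gene_trees(dataset, all_genes, config, seed, cache)
    result = AntigeneResult({}, config.alpha)
    matrix = CongruenceMatrix(all_genes, config.alpha)  # warning sink
    for g in removed:
        anti = dataset.antigene_alignment(g)
        anti_data = AlignmentData(anti)
        s = int(
            np.random.SeedSequence([seed, *f"anti|{g}".encode()])
            .generate_state(1)[0] % (2**31)
        )
        anti_tree = ml_search(
            anti, seed=s, restarts=config.restarts,
            optimize_rates=config.optimize_rates,
            final_rounds=config.final_rounds, data=anti_data,
        )
        row: dict[str, dict[str, CongruenceDecision]] = {}
        for h in all_genes:
            if h == g:
                continue  # the removed gene is never compared to its
                # own antigene matrix
            # seeds keyed by the partner gene only: leave-one-out
            # rows share RNG streams, so row contrasts are paired
            cell = _compare(
                (anti, anti_data), cache[h], anti_tree,
                gene_trees[h], config,
                _pair_seed(seed, "antigene", h), matrix,
                f"anti-{g} vs {h}",
            )
            row[h] = cell
        result.rows[g] = row
    result.warnings = matrix.warnings
    return result


def category_matrix(
    dataset: PartitionedAlignment,
    category_map: dict[str, list[str]],
    config: TestConfig | None = None,
    seed: int = 0,
) -> CongruenceMatrix:
    """Pairwise reciprocal tests among functional-category
    concatenations (CO, ND, AT, rRNA by default)."""
    if config is None:
        config = TestConfig()
    for cat, members in category_map.items():
        if not members:
            raise ValueError(f"empty category {cat!r}")
        unknown = [g for g in members if g not in dataset.partitions]
        if unknown:
            raise KeyError(f"unknown genes in category {cat!r}: {unknown}")
    names = list(category_map)
    matrix = CongruenceMatrix(names, config.alpha)
    packs = {}
    for c in names:
        aln = dataset.extract(category_map[c])
        packs[c] = (aln, AlignmentData(aln))
    trees: dict[str, SearchResult] = {}
    for c in names:
        s = int(
            np.random.SeedSequence([seed, *f"cat|{c}".encode()])
            .generate_state(1)[0] % (2**31)
        )
        trees[c] = ml_search(
            packs[c][0], seed=s, restarts=config.restarts,
            optimize_rates=config.optimize_rates,
            final_rounds=config.final_rounds, data=packs[c][1],
        )
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            matrix.cells[(a, b)] = _compare(
                packs[a], packs[b], trees[a], trees[b], config,
                _pair_seed(seed, a, b), matrix, f"{a} vs {b}",
            )
    return matrix


@dataclass
class SubsampleReport:
    fraction: float
    retained_taxa: list[str]
    congruent_proportion: dict[str, float]
    ambiguous_proportion: dict[str, float]
    seed: int
    skipped: bool = False
    matrix: Optional[CongruenceMatrix] = None


def subsample_experiment(
    dataset: PartitionedAlignment,
    fractions: Sequence[float] = (1.0, 0.5, 0.25, 0.10),
    config: TestConfig | None = None,
    seed: int = 0,
    genes: Optional[Sequence[str]] = None,
    keep_matrices: bool = False,
) -> list[SubsampleReport]:
    """Random taxon culling per fraction, full pairwise recomputation.

    Draws are independent across fractions; a fraction leaving fewer
    than 4 taxa is skipped with a warning.
    """
    if config is None:
        config = TestConfig()
    taxa = list(dataset.alignment.taxa)
    reports = []
    for k, frac in enumerate(fractions):
        n_keep = int(round(frac * len(taxa)))
        sub_seed = int(
            np.random.SeedSequence([seed, k]).generate_state(1)[0]
            % (2**31)
        )
        if n_keep < 4:
            logger.warning(
                "fraction %.2f keeps %d taxa (<4); skipped", frac, n_keep
            )
            reports.append(
                SubsampleReport(frac, [], {}, {}, sub_seed, skipped=True)
            )
            continue
        rng = np.random.default_rng(sub_seed)
        keep = sorted(rng.choice(taxa, size=n_keep, replace=False))
        reduced = dataset.subset_taxa(keep)
        matrix = pairwise_matrix(reduced, config, seed=sub_seed, genes=genes)
        cp = {
            t: congruent_proportion(matrix, t) for t in matrix.tests()
        }
        ap = {
            t: congruent_proportion(matrix, t, orientation="ambiguous")
            for t in matrix.tests()
        }
        reports.append(
            SubsampleReport(
                frac, list(keep), cp, ap, sub_seed,
                matrix=matrix if keep_matrices else None,
            )
        )
    return reports
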