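"""Synthetic partitioned mitogenome datasets with known congruence.

Scenarios
---------
``congruent``
    every gene evolves on the species tree;
``block_discordant``
    a configured gene subset (default ND4, ND5) evolves on a topology
    perturbed by ``lam`` rearrangement moves;
``or_gradient``
    gene *g* is perturbed by ``Poisson(lam * d_g / d_max)`` moves,
    where ``d_g`` is its replication distance from its strand's origin
    of replication — the planted form of the hypothesis that distance
    from the OR breeds incongruence.

All randomness flows from the scenario seed through named
``numpy.random.SeedSequence`` children, so outputs are pure functions
of (scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .alignment import Alignment, PartitionedAlignment
from .gradient import gene_distances
from .layout import GenomeLayout, insect_layout, vertebrate_layout
from .model import EigenSystem, ModelParams, build_rate_matrix, gamma_categories
from .tree import PhyloTree, perturb_tree, sample_species_tree

BASES = np.array(list("ACGT"))

SCENARIOS = ("congruent", "block_discordant", "or_gradient")


def default_mito_model() -> ModelParams:
    """Mitochondria-like TIM2+G+I defaults: strong transition bias,
    AT-rich composition, substantial rate heterogeneity."""
    return ModelParams(
        r_ac_at=1.0, r_ag=6.0, r_cg_gt=0.7, r_ct=10.0,
        freqs=np.array([0.32, 0.27, 0.12, 0.29]),
        alpha=0.45, pinv=0.25, ncat=4,
    )


@dataclass
class SimulationScenario:
    n_taxa: int = 20
    layout_template: str | GenomeLayout = "vertebrate"
    scenario: str = "congruent"
    lam: float = 0.0
    block_genes: tuple[str, ...] = ("ND4", "ND5")
    move_kind: str = "NNI"
    rate_multipliers: Mapping[str, float] = field(default_factory=dict)
    model: ModelParams = field(default_factory=default_mito_model)
    length_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if any(m <= 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be > 0")

    def layout(self) -> GenomeLayout:
        if isinstance(self.layout_template, GenomeLayout):
            base = self.layout_template
        elif self.layout_template == "vertebrate":
            base = vertebrate_layout()
        elif self.layout_template == "insect":
            base = insect_layout()
        else:
            raise ValueError(
                f"unknown layout template {self.layout_template!r}"
            )
        if self.length_scale != 1.0:
            base = base.scaled(self.length_scale)
        return base

    def subseed(self, *key: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=tuple(key))


@dataclass
class TruthRecord:
    """Ground truth of a simulated dataset."""

    species_tree: PhyloTree
    gene_trees: dict[str, PhyloTree]
    perturbations: dict[str, int]
    scenario: SimulationScenario


@dataclass
class SyntheticDataset:
    data: PartitionedAlignment
    layout: GenomeLayout
    truth: TruthRecord


def assign_gene_trees(
    species_tree: PhyloTree,
    layout: GenomeLayout,
    scenario: SimulationScenario,
) -> tuple[dict[str, PhyloTree], TruthRecord]:
    """Per-gene true topologies under the scenario's discordance plan."""
    names = layout.gene_names
    unknown = [g for g in scenario.block_genes if g not in names]
    if scenario.scenario == "block_discordant" and unknown:
        raise ValueError(f"unknown genes in perturbation subset: {unknown}")
    k_moves: dict[str, int] = {g: 0 for g in names}
    shared_block: PhyloTree | None = None
    if scenario.scenario == "block_discordant":
        for g in scenario.block_genes:
            k_moves[g] = int(round(scenario.lam))
        # the block shares one discordant history
        if k_moves and any(k_moves.values()):
            seed = int(
                scenario.subseed(2, 9999).generate_state(1)[0] % (2**31)
            )
            shared_block = perturb_tree(
                species_tree, int(round(scenario.lam)),
                scenario.move_kind, seed,
            )
    elif scenario.scenario == "or_gradient":
        # per-strand relative distance: the most distant gene on each
        # strand sees the full perturbation intensity lam
        rel: dict[str, float] = {}
        for strand in ("majority", "minority"):
            table = gene_distances(layout, strand)
            if not table.rows:
                continue
            d_max = max(r.distance for r in table.rows.values()) or 1.0
            rel.update(
                {g: r.distance / d_max for g, r in table.rows.items()}
            )
        for gi, g in enumerate(names):
            rng = np.random.default_rng(scenario.subseed(1, gi))
            k_moves[g] = int(rng.poisson(scenario.lam * rel[g]))
    trees: dict[str, PhyloTree] = {}
    for gi, g in enumerate(names):
        if k_moves[g] == 0:
            trees[g] = species_tree.copy()
        elif shared_block is not None:
            trees[g] = shared_block.copy()
        else:
            seed = int(
                scenario.subseed(2, gi).generate_state(1)[0] % (2**31)
            )
            trees[g] = perturb_tree(
                species_tree, k_moves[g], scenario.move_kind, seed
            )
    truth = TruthRecord(species_tree, trees, k_moves, scenario)
    return trees, truth


def simulate_alignment(
    tree: PhyloTree,
    model: ModelParams,
    length: int,
    seed: int | np.random.SeedSequence = 0,
) -> Alignment:
    """Simulate sites independently under TIM2+G+I along the tree.

    Each site is invariant with probability ``pinv`` (a single base
    drawn from the stationary frequencies, no substitutions); otherwise
    it draws a discrete-gamma rate category, the root state comes from
    the stationary frequencies and substitutions follow ``exp(Q t r)``
    along each branch.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    pi = model.freqs
    rates, _ = gamma_categories(model.alpha, model.ncat)
    q = build_rate_matrix(model)
    eig = EigenSystem(q, pi)

    is_inv = rng.random(length) < model.pinv
    cat = rng.integers(0, model.ncat, size=length)
    site_rate = np.where(is_inv, 0.0, rates[cat])

    leaves = tree.leaves()
    taxa = [n.name for n in leaves]
    out = np.empty((len(taxa), length), dtype=np.int64)
    row = {t: i for i, t in enumerate(taxa)}

    states: dict[int, np.ndarray] = {}
    root_state = rng.choice(4, size=length, p=pi)
    states[id(tree.root)] = root_state
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[id(node.parent)]
        child = np.empty(length, dtype=np.int64)
        for r in np.unique(site_rate):
            sel = site_rate == r
            if r == 0.0:
                child[sel] = parent_state[sel]
                continue
            p = eig.p_matrix(node.length * r)
            p = np.maximum(p, 0)
            p = p / p.sum(axis=1, keepdims=True)
            cum = p.cumsum(axis=1)
            u = rng.random(int(sel.sum()))
            child[sel] = (u[:, None] > cum[parent_state[sel]]).sum(axis=1)
        states[id(node)] = child
        if node.is_leaf():
            out[row[node.name]] = child
    if tree.root.is_leaf():  # not expected, defensive
        out[row[tree.root.name]] = root_state
    return Alignment(taxa, BASES[out])


def generate_dataset(scenario: SimulationScenario) -> SyntheticDataset:
    """Full synthetic dataset: species tree, gene trees, partitioned
    alignment matching the layout's gene lengths."""
    layout = scenario.layout()
    species_seed = int(
        scenario.subseed(0).generate_state(1)[0] % (2**31)
    )
    species = sample_species_tree(scenario.n_taxa, species_seed)
    gene_trees, truth = assign_gene_trees(species, layout, scenario)
    blocks: list[np.ndarray] = []
    partitions: dict[str, tuple[int, int]] = {}
    taxa: Optional[list[str]] = None
    cursor = 0
    for gi, g in enumerate(layout.genes):
        gtree = gene_trees[g.name].copy()
        mult = scenario.rate_multipliers.get(g.name, 1.0)
        if mult != 1.0:
            gtree.scale_lengths(mult)
        sub = simulate_alignment(
            gtree, scenario.model, g.length, scenario.subseed(3, gi)
        )
        if taxa is None:
            taxa = sub.taxa
        else:
            sub = sub.subset_taxa(taxa)
        blocks.append(sub.matrix)
        partitions[g.name] = (cursor, cursor + g.length)
        cursor += g.length
    aln = Alignment(taxa, np.hstack(blocks))
    pa = PartitionedAlignment(aln, partitions)
    return SyntheticDataset(pa, layout, truth)


def write_dataset(
    dataset: SyntheticDataset, outdir, overwrite: bool = False
) -> None:
    """Write per-gene FASTA, combined NEXUS with charsets, gene-map
    TSV, truth Newick files and a JSON manifest."""
    from pathlib import Path

    from . import io as mio
    from .layout import write_layout_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    targets = [outdir / "alignment.nex", outdir / "gene_map.tsv"]
    if not overwrite:
        clashes = [str(t) for t in targets if t.exists()]
        if clashes:
            raise FileExistsError(
                f"refusing to overwrite existing outputs: {clashes}"
            )
    for g in dataset.data.gene_names:
        mio.write_fasta(
            dataset.data.gene_alignment(g), outdir / f"{g}.fasta"
        )
    mio.write_nexus(dataset.data, outdir / "alignment.nex")
    write_layout_tsv(dataset.layout, outdir / "gene_map.tsv")
    trees = outdir / "truth_trees"
    trees.mkdir(exist_ok=True)
    mio.write_newick(
        dataset.truth.species_tree, trees / "species.nwk"
    )
    for g, t in dataset.truth.gene_trees.items():
        mio.write_newick(t, trees / f"{g}.nwk")
    sc = dataset.truth.scenario
    mio.write_json(
        {
            "n_taxa": sc.n_taxa,
            "layout_template": (
                sc.layout_template
                if isinstance(sc.layout_template, str)
                else "custom"
            ),
            "scenario": sc.scenario,
            "lam": sc.lam,
            "block_genes": list(sc.block_genes),
            "move_kind": sc.move_kind,
            "length_scale": sc.length_scale,
            "seed": sc.seed,
            "perturbations": dataset.truth.perturbations,
        },
        outdir / "manifest.json",
    )
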