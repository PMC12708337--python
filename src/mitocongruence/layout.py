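"""Circular mitogenome gene maps.

A :class:`GenomeLayout` records where each of the 15 canonical genes
(13 protein-coding + 2 rRNA) sits on the circle, which strand carries
it, its functional category, and the per-strand origin of replication
(OR) with its replication direction.  Two editable templates are
bundled: a vertebrate (human-like) arrangement in which only ND6 sits
on the minority strand, and a derived-insect (Drosophila-like)
arrangement with the rRNAs adjacent to the minority-strand OR.

Coordinates in the TSV templates are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

CANONICAL_GENES = frozenset(
    ["COX1", "COX2", "COX3", "CYTB", "ATP6", "ATP8",
     "ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6", "12S", "16S"]
)
CATEGORIES = ("CO", "ND", "AT", "rRNA")
STRANDS = ("majority", "minority")

DEFAULT_CATEGORY_MAP = {
    "CO": ["COX1", "COX2", "COX3", "CYTB"],
    "ND": ["ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6"],
    "AT": ["ATP6", "ATP8"],
    "rRNA": ["12S", "16S"],
}


@dataclass(frozen=True)
class GeneRecord:
    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str
    category: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeLayout:
    genome_length: int
    genes: list[GeneRecord]
    or_position: dict[str, int]
    replication_direction: dict[str, str]

    def __post_init__(self):
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in layout")
        for g in self.genes:
            if g.strand not in STRANDS:
                raise ValueError(f"bad strand {g.strand!r} for {g.name}")
            if g.category not in CATEGORIES:
                raise ValueError(f"bad category {g.category!r} for {g.name}")
            if not (1 <= g.start <= g.end <= self.genome_length):
                raise ValueError(f"gene {g.name} outside genome")
        spans = sorted((g.start, g.end) for g in self.genes)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("overlapping gene intervals")
        for strand, pos in self.or_position.items():
            if not (0 <= pos < self.genome_length):
                raise ValueError(f"OR for {strand} outside [0, L)")
        for strand, d in self.replication_direction.items():
            if d not in ("increasing", "decreasing"):
                raise ValueError(f"bad replication direction {d!r}")

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def gene(self, name: str) -> GeneRecord:
        for g in self.genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def genes_on_strand(self, strand: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.strand == strand]

    def gene_lengths(self) -> dict[str, int]:
        return {g.name: g.length for g in self.genes}

    def total_gene_length(self) -> int:
        return sum(g.length for g in self.genes)

    def category_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {c: [] for c in CATEGORIES}
        for g in self.genes:
            out[g.category].append(g.name)
        return {c: v for c, v in out.items() if v}

    def is_canonical(self) -> bool:
        return set(self.gene_names) == CANONICAL_GENES

    def scaled(self, factor: float) -> "GenomeLayout":
        """Layout with gene lengths scaled down (for desk-scale runs).

        Coordinates are compressed proportionally; every gene keeps at
        least 100 sites so parsimony and likelihood stay informative.
        """
        new_genes = []
        for g in self.genes:
            length = max(100, int(round(g.length * factor)))
            start = max(1, int(round(g.start * factor)))
            new_genes.append(
                GeneRecord(g.name, start, start + length - 1,
                           g.strand, g.category)
            )
        # re-pack to remove any overlap introduced by rounding
        new_genes.sort(key=lambda g: g.start)
        packed, cursor = [], 1
        for g in new_genes:
            start = max(g.start, cursor)
            packed.append(
                GeneRecord(g.name, start, start + g.length - 1,
                           g.strand, g.category)
            )
            cursor = start + g.length + 1
        glen = max(int(round(self.genome_length * factor)),
                   packed[-1].end + 1)
        return GenomeLayout(
            genome_length=glen,
            genes=packed,
            or_position={
                s: min(int(round(p * factor)), glen - 1)
                for s, p in self.or_position.items()
            },
            replication_direction=dict(self.replication_direction),
        )


def _parse_layout_lines(lines: Iterable[str]) -> GenomeLayout:
    meta: dict[str, str] = {}
    genes: list[GeneRecord] = []
    header_seen = False
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line[1:].partition("=")
            meta[key.strip()] = val.strip()
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields[:5] != ["gene", "start", "end", "strand", "category"]:
                raise ValueError(f"unexpected gene-map header: {fields}")
            header_seen = True
            continue
        name, start, end, strand, category = fields[:5]
        genes.append(
            GeneRecord(name, int(start), int(end), strand, category)
        )
    return GenomeLayout(
        genome_length=int(meta["genome_length"]),
        genes=genes,
        or_position={
            "majority": int(meta["or_majority"]),
            "minority": int(meta["or_minority"]),
        },
        replication_direction={
            "majority": meta["repdir_majority"],
            "minority": meta["repdir_minority"],
        },
    )


def read_layout_tsv(path: str | Path) -> GenomeLayout:
    with open(path) as fh:
        return _parse_layout_lines(fh)


def write_layout_tsv(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#genome_length={layout.genome_length}\n")
        fh.write(f"#or_majority={layout.or_position['majority']}\n")
        fh.write(f"#or_minority={layout.or_position['minority']}\n")
        fh.write(
            f"#repdir_majority={layout.replication_direction['majority']}\n"
        )
        fh.write(
            f"#repdir_minority={layout.replication_direction['minority']}\n"
        )
        fh.write("gene\tstart\tend\tstrand\tcategory\n")
        for g in layout.genes:
            fh.write(
                f"{g.name}\t{g.start}\t{g.end}\t{g.strand}\t{g.category}\n"
            )


def _load_template(name: str) -> GenomeLayout:
    text = (
        resources.files("mitocongruence.data")
        .joinpath(name)
        .read_text()
    )
    return _parse_layout_lines(text.splitlines())


def vertebrate_layout() -> GenomeLayout:
    """Human-like arrangement: ND6 is the sole minority-strand gene."""
    return _load_template("vertebrate_layout.tsv")


def insect_layout() -> GenomeLayout:
    """Drosophila-like arrangement: rRNAs adjacent to the minority OR."""
    return _load_template("insect_layout.tsv")
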