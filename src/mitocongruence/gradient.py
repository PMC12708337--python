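"""Per-gene congruence counts regressed on distance from the origin of
replication, reported per strand.

The unscaled congruence measure for a gene is simply the number of its
pairwise comparisons flagged in the requested orientation (congruent or
incongruent) at the chosen significance level; it is regressed by
ordinary least squares on the gene's replication distance in bp.
Strands carrying fewer than three genes yield an NA row rather than a
meaningless fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .layout import GenomeLayout

SIGN_TOL = 1e-12  # counts per bp below which a slope is called "0"


@dataclass(frozen=True)
class DistanceRow:
    gene: str
    strand: str
    distance: float  # bp from the strand's OR along replication


@dataclass
class OrDistanceTable:
    strand: str
    rows: dict[str, DistanceRow] = field(default_factory=dict)


def gene_distances(
    layout: GenomeLayout, strand: str, anchor: str = "five_prime"
) -> OrDistanceTable:
    """Replication distance of every gene on ``strand`` from its OR.

    The distance runs from the strand's OR to the gene's anchor
    coordinate (5' end by default, midpoint via ``anchor='midpoint'``)
    along the strand's replication direction, modulo genome length.
    """
    if strand not in layout.or_position:
        raise KeyError(f"no OR recorded for strand {strand!r}")
    origin = layout.or_position[strand]
    direction = layout.replication_direction[strand]
    length = layout.genome_length
    table = OrDistanceTable(strand)
    for g in layout.genes_on_strand(strand):
        if anchor == "midpoint":
            coord = (g.start + g.end) / 2.0
        elif anchor == "five_prime":
            # majority-strand genes read with the coordinate system,
            # minority-strand genes against it
            coord = float(g.start if strand == "majority" else g.end)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        if direction == "increasing":
            d = (coord - origin) % length
        else:
            d = (origin - coord) % length
        table.rows[g.name] = DistanceRow(g.name, strand, d)
    return table


@dataclass
class UnscaledMeasure:
    """Per-gene count of flagged pairwise comparisons."""

    orientation: str  # "congruent" or "incongruent"
    test: str
    alpha: float
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class RegressionResult:
    strand: str
    n_genes: int
    slope: float = float("nan")
    intercept: float = float("nan")
    r_squared: float = float("nan")
    p_slope: float = float("nan")
    slope_sign: str = "NA"
    na_reason: Optional[str] = None

    @property
    def is_na(self) -> bool:
        return self.na_reason is not None


def regress(
    distances: OrDistanceTable,
    measure: UnscaledMeasure,
    strand: str,
) -> RegressionResult:
    """OLS of congruence counts on replication distance for one strand."""
    genes = [
        g for g in distances.rows
        if distances.rows[g].strand == strand and g in measure.counts
    ]
    if len(genes) < 3:
        return RegressionResult(
            strand, len(genes),
            na_reason=f"only {len(genes)} genes on {strand} strand",
        )
    x = np.array([distances.rows[g].distance for g in genes], dtype=float)
    y = np.array([measure.counts[g] for g in genes], dtype=float)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        # degenerate: no variation to regress
        return RegressionResult(
            strand, len(genes), slope=0.0, intercept=float(np.mean(y)),
            r_squared=0.0, p_slope=1.0, slope_sign="0",
        )
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if abs(slope) < SIGN_TOL:
        sign = "0"
    else:
        sign = "P" if slope > 0 else "N"
    return RegressionResult(
        strand, len(genes),
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        p_slope=float(fit.pvalue),
        slope_sign=sign,
    )


def unscaled_measure(matrix, test: str, orientation: str) -> UnscaledMeasure:
    """Count per gene of off-diagonal cells with the given orientation.

    ``matrix`` is a :class:`~mitocongruence.workflows.CongruenceMatrix`;
    congruent + incongruent + ambiguous counts sum to (n_genes - 1).
    """
    if orientation not in ("congruent", "incongruent"):
        raise ValueError(f"unknown orientation {orientation!r}")
    out = UnscaledMeasure(orientation, test, matrix.alpha)
    for g in matrix.names:
        count = 0
        for h in matrix.names:
            if h == g:
                continue
            if matrix.call(g, h, test) == orientation:
                count += 1
        out.counts[g] = count
    return out


def gradient_report(
    layout: GenomeLayout,
    matrix,
    test: str,
    orientations: tuple[str, ...] = ("incongruent", "congruent"),
    anchor: str = "five_prime",
) -> list[dict]:
    """Machine-readable per-strand regression table.

    Both count orientations are reported so either convention for the
    unscaled measure can be read off the same table.
    """
    rows = []
    for strand in ("majority", "minority"):
        dist = gene_distances(layout, strand, anchor=anchor)
        for orient in orientations:
            meas = unscaled_measure(matrix, test, orient)
            res = regress(dist, meas, strand)
            rows.append(
                {
                    "strand": strand,
                    "orientation": orient,
                    "test": test,
                    "n_genes": res.n_genes,
                    "R2": res.r_squared,
                    "slope": res.slope,
                    "slope_sign": res.slope_sign,
                    "p_slope": res.p_slope,
                    "NA_reason": res.na_reason or "",
                }
            )
    return rows
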