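"""Readers and writers for the formats the pipeline touches.

FASTA parsing goes through Biopython; NEXUS (DATA + SETS blocks, both
interleaved and sequential dialects) through ``Bio.Nexus``; Newick
through dendropy.  Charset coordinates are 1-based inclusive on disk
and half-open 0-based in memory, with the conversion confined to this
module.  Readers reject structural errors instead of repairing them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Nexus import Nexus

from .alignment import Alignment, PartitionedAlignment
from .tree import PhyloTree


# ----------------------------------------------------------------------
# FASTA
# ----------------------------------------------------------------------
def read_fasta(path: str | Path) -> Alignment:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate taxon label: {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no sequences in {path}")
    lengths = {t: len(s) for t, s in records.items()}
    if len(set(lengths.values())) > 1:
        raise ValueError(f"ragged alignment rows: {lengths}")
    return Alignment.from_sequences(records)


def write_fasta(aln: Alignment, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for taxon in aln.taxa:
            fh.write(f">{taxon}\n")
            seq = aln.sequence(taxon)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ----------------------------------------------------------------------
# NEXUS with charsets
# ----------------------------------------------------------------------
def read_nexus(path: str | Path) -> PartitionedAlignment:
    """Parse a NEXUS matrix; charsets become partitions.

    A file without a SETS block yields a single partition named
    ``all``.  Overlapping charsets or charsets beyond the matrix are
    rejected.
    """
    nex = Nexus.Nexus(str(path))
    if not nex.matrix:
        raise ValueError(f"no DATA matrix in {path}")
    records = {str(t): str(nex.matrix[t]) for t in nex.taxlabels}
    aln = Alignment.from_sequences(records)
    partitions: dict[str, tuple[int, int]] = {}
    for name, sites in (nex.charsets or {}).items():
        if not sites:
            continue
        sites = sorted(sites)  # Bio.Nexus stores 0-based positions
        start, stop = sites[0], sites[-1] + 1
        if sites != list(range(start, stop)):
            raise ValueError(f"charset {name!r} is not contiguous")
        if stop > aln.n_sites:
            raise ValueError(
                f"charset {name!r} exceeds matrix length {aln.n_sites}"
            )
        partitions[name] = (start, stop)
    if not partitions:
        partitions = {"all": (0, aln.n_sites)}
    ordered = dict(sorted(partitions.items(), key=lambda kv: kv[1]))
    return PartitionedAlignment(aln, ordered)


def write_nexus(pa: PartitionedAlignment, path: str | Path) -> None:
    aln = pa.alignment
    pad = max(len(t) for t in aln.taxa) + 2
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(
            f"  DIMENSIONS NTAX={aln.n_taxa} NCHAR={aln.n_sites};\n"
        )
        fh.write(
            "  FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE=NO;\n"
        )
        fh.write("  MATRIX\n")
        for t in aln.taxa:
            label = f"'{t}'" if " " in t else t
            fh.write(f"    {label:<{pad}}{aln.sequence(t)}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for name, (start, stop) in pa.partitions.items():
            fh.write(f"  CHARSET {name} = {start + 1}-{stop};\n")
        fh.write("END;\n")


# ----------------------------------------------------------------------
# Newick
# ----------------------------------------------------------------------
def read_newick(path: str | Path) -> PhyloTree:
    return PhyloTree.from_newick(Path(path).read_text())


def write_newick(tree: PhyloTree, path: str | Path) -> None:
    Path(path).write_text(tree.to_newick() + "\n")


# ----------------------------------------------------------------------
# tables
# ----------------------------------------------------------------------
def write_tsv(rows: Iterable[dict], path: str | Path) -> None:
    rows = list(rows)
    if not rows:
        Path(path).write_text("")
        return
    cols = list(rows[0])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row[c]) for c in cols) + "\n")


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (bool, np.bool_)):
        return str(bool(v))
    return str(v)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
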