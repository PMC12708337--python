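import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocongruence.alignment import Alignment, PartitionedAlignment
from mitocongruence.io import (
    read_fasta,
    read_nexus,
    write_fasta,
    write_nexus,
)
from mitocongruence.layout import vertebrate_layout
from mitocongruence.simulate import SimulationScenario, generate_dataset


def _random_alignment(rng, n_taxa=5, n_sites=100) -> Alignment:
    mat = rng.choice(list("ACGT"), size=(n_taxa, n_sites))
    return Alignment([f"t{i}" for i in range(n_taxa)], mat)


class TestAlignment:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ValueError, match="dup"):
            Alignment(["a", "a"], np.array([["A"], ["C"]]))

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment.from_sequences({"a": "ACGT", "b": "ACG"})

    def test_lowercase_normalized(self):
        aln = Alignment.from_sequences({"a": "acgt", "b": "ACGT"})
        assert aln.sequence("a") == "ACGT"

    def test_unknown_characters_rejected(self):
        with pytest.raises(ValueError):
            Alignment.from_sequences({"a": "ACXT", "b": "ACGT"})

    def test_empirical_frequencies_sum_to_one(self, rng):
        aln = _random_alignment(rng)
        f = aln.empirical_frequencies()
        assert f.sum() == pytest.approx(1.0)
        assert (f > 0).all()


class TestFasta:
    def test_round_trip_identity(self, tmp_path, rng):
        aln = _random_alignment(rng, 5, 100)
        path = tmp_path / "a.fasta"
        write_fasta(aln, path)
        back = read_fasta(path)
        assert back.taxa == aln.taxa
        assert (back.matrix == aln.matrix).all()

    def test_duplicate_label_named_in_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">tax1\nACGT\n>tax1\nACGT\n")
        with pytest.raises(ValueError, match="tax1"):
            read_fasta(path)

    def test_ragged_rejected(self, tmp_path):
        path = tmp_path / "ragged.fasta"
        path.write_text(">a\nACGT\n>b\nAC\n")
        with pytest.raises(ValueError, match="ragged"):
            read_fasta(path)


class TestNexus:
    def _partitioned(self, rng) -> PartitionedAlignment:
        aln = _random_alignment(rng, 4, 60)
        return PartitionedAlignment(
            aln, {"COX1": (0, 25), "ND2": (25, 45), "12S": (45, 60)}
        )

    def test_round_trip(self, tmp_path, rng):
        pa = self._partitioned(rng)
        path = tmp_path / "m.nex"
        write_nexus(pa, path)
        back = read_nexus(path)
        assert (back.alignment.matrix == pa.alignment.matrix).all()
        assert back.partitions == pa.partitions

    def test_charset_convention_one_based_inclusive(self, tmp_path, rng):
        pa = self._partitioned(rng)
        path = tmp_path / "m.nex"
        write_nexus(pa, path)
        text = path.read_text()
        assert "CHARSET COX1 = 1-25;" in text
        back = read_nexus(path)
        start, stop = back.partitions["COX1"]
        assert stop - start == 25

    def test_interleaved_equals_sequential(self, tmp_path, rng):
        aln = _random_alignment(rng, 3, 40)
        seq_path = tmp_path / "seq.nex"
        write_nexus(PartitionedAlignment(aln, {"all": (0, 40)}), seq_path)
        inter = ["#NEXUS", "", "BEGIN DATA;",
                 "  DIMENSIONS NTAX=3 NCHAR=40;",
                 "  FORMAT DATATYPE=DNA MISSING=? GAP=- INTERLEAVE=YES;",
                 "  MATRIX"]
        for chunk in (0, 20):
            for t in aln.taxa:
                inter.append(f"    {t}  {aln.sequence(t)[chunk:chunk+20]}")
            inter.append("")
        inter += ["  ;", "END;", ""]
        int_path = tmp_path / "int.nex"
        int_path.write_text("\n".join(inter))
        a = read_nexus(seq_path)
        b = read_nexus(int_path)
        assert (a.alignment.matrix == b.alignment.matrix).all()

    def test_missing_sets_block_yields_single_partition(self, tmp_path, rng):
        aln = _random_alignment(rng, 4, 30)
        path = tmp_path / "nosets.nex"
        text = write_nexus(
            PartitionedAlignment(aln, {"all": (0, 30)}), path
        )
        raw = path.read_text().split("BEGIN SETS;")[0]
        path.write_text(raw)
        back = read_nexus(path)
        assert back.partitions == {"all": (0, 30)}

    def test_charset_beyond_matrix_rejected(self, tmp_path, rng):
        aln = _random_alignment(rng, 4, 30)
        path = tmp_path / "bad.nex"
        write_nexus(PartitionedAlignment(aln, {"all": (0, 30)}), path)
        text = path.read_text().replace(
            "CHARSET all = 1-30;", "CHARSET all = 1-99;"
        )
        path.write_text(text)
        with pytest.raises(Exception):
            read_nexus(path)

    def test_overlapping_partitions_rejected(self, rng):
        aln = _random_alignment(rng, 4, 30)
        with pytest.raises(ValueError, match="overlap"):
            PartitionedAlignment(aln, {"a": (0, 20), "b": (10, 30)})


@pytest.fixture(scope="module")
def dataset():
    scenario = SimulationScenario(
        n_taxa=5, layout_template="vertebrate",
        scenario="congruent", length_scale=1.0, seed=9,
    )
    return generate_dataset(scenario)


class TestExtractPartition:
    def test_all_genes_is_identity(self, dataset):
        full = dataset.data.extract(dataset.data.gene_names)
        assert (full.matrix == dataset.data.alignment.matrix).all()

    def test_antigene_width_conservation(self, dataset):
        total = dataset.data.alignment.n_sites
        for g in ("COX1", "ATP8", "ND5"):
            anti = dataset.data.antigene_alignment(g)
            assert anti.n_sites == total - dataset.data.gene_width(g)

    def test_atp8_width_matches_template(self, dataset):
        assert dataset.data.extract(["ATP8"]).n_sites == 168
        assert vertebrate_layout().gene("ATP8").length == 168

    def test_order_stability_and_idempotence(self, dataset):
        a = dataset.data.extract(["ND5", "COX1"])  # request order
        b = dataset.data.extract(["COX1", "ND5"])  # swapped request
        assert (a.matrix == b.matrix).all()  # layout order wins

    def test_unknown_gene_rejected(self, dataset):
        with pytest.raises(KeyError, match="NADX"):
            dataset.data.extract(["NADX"])


@settings(max_examples=20, derandomize=True, deadline=None)
@given(
    n_taxa=st.integers(min_value=4, max_value=8),
    n_sites=st.integers(min_value=1, max_value=60),
    seed=st.integers(min_value=0, max_value=2**20),
)
def test_fasta_round_trip_property(tmp_path_factory, n_taxa, n_sites, seed):
    """write then read is the identity for arbitrary ACGT- matrices."""
    rng = np.random.default_rng(seed)
    mat = rng.choice(list("ACGT-N"), size=(n_taxa, n_sites))
    aln = Alignment([f"s{i}" for i in range(n_taxa)], mat)
    path = tmp_path_factory.mktemp("fa") / "x.fasta"
    write_fasta(aln, path)
    back = read_fasta(path)
    assert back.taxa == aln.taxa
    assert (back.matrix == aln.matrix).all()
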