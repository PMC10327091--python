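"""Reference curation, containment quantification, normalisation
invariances, embedding determinism/separation and the infection overlay."""

import numpy as np
import pytest
import scipy.sparse

import virocell as vc
from virocell.embedding import repeat_fraction
from virocell.io import ReadPair, SeqRecord
from virocell.screen import CellUMITable
from virocell.simulate import InfectionEntry


@pytest.fixture(scope="module")
def community():
    config = vc.CommunityConfig(
        taxon_names=["T1", "T2", "T3"],
        taxon_cell_fractions=[0.4, 0.35, 0.25],
        dominant_taxon="T1",
        family_names=["FamX", "FamY"],
        infection_table=[InfectionEntry("T2", "FamX", 0.5, 0.15)],
        ambient_viral_rate=0.0,
        doublet_rate=0.0,
        n_cells=90,
        reads_per_cell=("fixed", 600),
        n_18s_variants=1,
        seed=33,
    )
    refs = vc.simulate_references(config)
    reads, truth = vc.simulate_experiment(refs, config)
    return config, refs, reads, truth


def _reference(refs):
    host = [
        SeqRecord(r.id, r.sequence, r.description + " source=host")
        for r in refs.host_mrna + refs.host_18s
    ]
    viral = [
        SeqRecord(r.id, r.sequence, r.description + " source=viral")
        for r in refs.viral_genes
    ]
    return host + viral


class TestReferenceCuration:
    def test_pure_dinucleotide_repeat_removed(self):
        rep = SeqRecord("rep", "AT" * 100, "source=host")
        keep = SeqRecord("ok", "ACGGTTACGATCCGTAGGCT" * 10, "source=host")
        kept = vc.build_hostvirus_reference([rep, keep])
        assert [r.id for r in kept] == ["ok"]

    def test_identical_contigs_collapse_to_one(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
        a = SeqRecord("cellA_c1", seq, "source=host")
        b = SeqRecord("cellB_c1", seq, "source=host")
        kept = vc.build_hostvirus_reference([a, b])
        assert len(kept) == 1

    def test_near_duplicate_containment_keeps_longer(self, rng):
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])
        long = SeqRecord("long", seq, "source=host")
        short = SeqRecord("short", seq[50:350], "source=host")
        kept = vc.build_hostvirus_reference([long, short])
        assert [r.id for r in kept] == ["long"]

    def test_all_removed_errors(self):
        with pytest.raises(ValueError):
            vc.build_hostvirus_reference([SeqRecord("rep", "A" * 200, "")])

    def test_simulator_contigs_cover_infected_taxa(self, community):
        config, refs, reads, truth = community
        result = vc.run_pair_pipeline(reads, refs)
        contig_records = [
            SeqRecord(c.contig_id, c.sequence, "source=host")
            for contigs in result.contigs_by_cell.values()
            for c in contigs
        ]
        kept = vc.build_hostvirus_reference(contig_records, _reference(refs))
        searcher = vc.NucleotideSearcher(refs.host_18s)
        covered = set()
        for rec in kept:
            for h in searcher.search(rec.sequence, 99, 1e-10, 100):
                covered.add(h.group_label)
        infected_taxa = set(truth.cells.loc[truth.cells["infected"], "taxon"])
        assert infected_taxa <= covered


class TestQuantifyCells:
    def test_umi_collapse_and_unique_containment(self, community):
        _, refs, _, _ = community
        ref = _reference(refs)
        gene = refs.viral_genes[0]
        reads = [
            ReadPair("B" * 16, "A" * 12, gene.sequence[:60], "r0"),
            ReadPair("B" * 16, "A" * 12, gene.sequence[:60], "r1"),  # same UMI
            ReadPair("B" * 16, "C" * 12, gene.sequence[5:65], "r2"),
        ]
        table = vc.quantify_cells(reads, ref)
        assert table.total_umis().sum() == 2
        assert table.subset_source("viral").total_umis().sum() == 2

    def test_noise_free_totals_match_read_counts(self, community):
        _, refs, reads, truth = community
        table = vc.quantify_cells(reads[:2000], _reference(refs))
        # every simulated read is an exact substring of exactly one source
        assert table.total_umis().sum() == 2000


class TestNormalizeAndEmbed:
    def _toy_table(self, matrix):
        m = scipy.sparse.csr_matrix(np.asarray(matrix, dtype=np.int64))
        return CellUMITable(
            barcodes=[f"c{i}" for i in range(m.shape[0])],
            genes=[f"g{j}" for j in range(m.shape[1])],
            sources=["host"] * m.shape[1],
            counts=m,
        )

    def test_proportional_cells_normalize_identically(self):
        table = self._toy_table(
            [[2, 4, 6, 0]] * 4 + [[1, 2, 3, 0]] * 4 + [[5, 0, 1, 2]] * 4
        )
        # proportional count vectors become identical after library-size scaling
        X = table.counts.toarray().astype(float)
        X = X[:, (X > 0).sum(axis=0) >= 2]
        totals = X.sum(axis=1)
        X = X / totals[:, None] * np.median(totals)
        assert np.allclose(X[0], X[4])

    def test_min_cells_boundary(self):
        # gene g3 present in one cell only must be dropped; g2 in two kept
        table = self._toy_table(
            [
                [5, 1, 1, 0],
                [5, 1, 1, 1],
                [5, 1, 0, 0],
                [4, 1, 0, 0],
                [5, 2, 0, 0],
                [5, 1, 0, 0],
                [6, 1, 0, 0],
                [5, 1, 0, 0],
            ]
        )
        X = table.counts.toarray()
        keep = (X > 0).sum(axis=0) >= 2
        assert list(keep) == [True, True, True, False]

    def test_fewer_cells_than_neighbors_errors(self):
        table = self._toy_table([[1, 2, 3]] * 4)
        with pytest.raises(ValueError, match="n_neighbors"):
            vc.normalize_and_embed(table, n_neighbors=7)

    def test_embedding_deterministic_and_separates_taxa(self, community):
        config, refs, reads, truth = community
        table = vc.quantify_cells(reads, _reference(refs))
        table = vc.qc_filter_cells(table)
        taxa = dict(zip(truth.cells["barcode"], truth.cells["taxon"]))
        labels = [taxa[bc] for bc in table.barcodes]
        emb1 = vc.normalize_and_embed(table, seed=11, taxon_labels=labels)
        emb2 = vc.normalize_and_embed(table, seed=11, taxon_labels=labels)
        assert np.array_equal(emb1.coords, emb2.coords)
        # k=1 label agreement: nearest embedded neighbour shares the taxon
        from scipy.spatial import cKDTree

        tree = cKDTree(emb1.coords)
        _, nn = tree.query(emb1.coords, k=2)
        agree = np.mean(
            [labels[i] == labels[j] for i, j in enumerate(nn[:, 1])]
        )
        assert agree >= 0.95
        # and the 2-D silhouette over true labels is strong
        from sklearn.metrics import silhouette_score

        assert silhouette_score(emb1.coords, labels) > 0.5


class TestOverlay:
    def _viral_table(self, totals):
        m = scipy.sparse.csr_matrix(
            np.array(totals, dtype=np.int64).reshape(-1, 1)
        )
        return CellUMITable(
            barcodes=[f"c{i}" for i in range(len(totals))],
            genes=["PolB"],
            sources=["viral-marker"],
            counts=m,
        )

    def _embedding(self, n):
        return vc.EmbeddingResult(
            barcodes=[f"c{i}" for i in range(n)], coords=np.zeros((n, 2))
        )

    def test_boundary_10_vs_9(self):
        emb = vc.overlay_infection(self._embedding(2), self._viral_table([10, 9]))
        assert list(emb.infected_flags) == [True, False]

    def test_no_viral_genes_all_false(self):
        emb = vc.overlay_infection(self._embedding(3), self._viral_table([0, 0, 0]))
        assert not emb.infected_flags.any()

    def test_barcode_mismatch_errors(self):
        with pytest.raises(ValueError, match="missing"):
            vc.overlay_infection(self._embedding(3), self._viral_table([1, 2]))

    def test_flags_match_truth_noise_free(self, community):
        _, refs, reads, truth = community
        table = vc.quantify_cells(reads, _reference(refs))
        emb = vc.EmbeddingResult(
            barcodes=list(table.barcodes),
            coords=np.zeros((table.n_cells, 2)),
        )
        vc.overlay_infection(emb, table.subset_source("viral"))
        expected = {
            row["barcode"]: row["true_viral_umis"] >= 10
            for _, row in truth.cells.iterrows()
        }
        for bc, flag in zip(emb.barcodes, emb.infected_flags):
            assert flag == expected[bc]


def test_repeat_fraction_spectrum():
    assert repeat_fraction("AT" * 100) == 1.0
    assert repeat_fraction("A" * 200) == 1.0
    rng = np.random.default_rng(8)
    random_seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 300)])
    assert repeat_fraction(random_seq) < 0.5
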