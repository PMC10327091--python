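"""Link classification thresholds, profile normalisation, planted-pair
recovery and the viral gene-expression summary."""

import numpy as np
import pytest

import virocell as vc
from virocell.pairing import classify_links, profile_from_counts
from virocell.screen import InfectionCall
from virocell.simulate import InfectionEntry
from virocell.taxonomy import TaxonomyCall


def _host(group="groupK"):
    return TaxonomyCall("cell", "bc", group)


class TestViralProfile:
    def test_single_family_profile(self):
        p = profile_from_counts("bc", {"IM_07": 50})
        assert p.fractions == {"IM_07": 1.0}
        assert p.argmax_family == "IM_07"

    def test_empty_profile(self):
        p = profile_from_counts("bc", {})
        assert p.total_viral_reads == 0
        assert p.fractions == {} and p.argmax_family is None

    def test_fractions_sum_to_one(self, rng):
        counts = {f"F{i}": int(c) for i, c in enumerate(rng.integers(1, 50, 6))}
        p = profile_from_counts("bc", counts)
        assert abs(sum(p.fractions.values()) - 1.0) < 1e-12

    def test_noise_free_argmax_equals_planted_family(
        self, small_experiment, small_pipeline
    ):
        _, truth = small_experiment
        planted = dict(zip(truth.cells["barcode"], truth.cells["family"]))
        for bc in small_pipeline.highly_infected_barcodes:
            assert small_pipeline.profiles[bc].argmax_family == planted[bc]


class TestClassifyLinks:
    def test_90_10_boundaries_inclusive(self):
        links = classify_links(
            profile_from_counts("bc", {"IM_07": 45, "IM_01": 5}), _host()
        )
        by_family = {l.family: l for l in links}
        assert by_family["IM_07"].link_class == "unambiguous"
        assert by_family["IM_07"].fraction == pytest.approx(0.90)
        assert by_family["IM_01"].link_class == "ambiguous"
        assert by_family["IM_01"].fraction == pytest.approx(0.10)

    def test_fraction_just_below_90_is_ambiguous(self):
        links = classify_links(
            profile_from_counts("bc", {"A": 8999, "B": 1001}), _host()
        )
        assert {l.link_class for l in links if l.family == "A"} == {"ambiguous"}

    def test_count_below_10_ineligible(self):
        assert classify_links(
            profile_from_counts("bc", {"IM_01": 6, "IM_16": 3}), _host()
        ) == []

    def test_count_exactly_10_eligible(self):
        links = classify_links(profile_from_counts("bc", {"IM_01": 10}), _host())
        assert len(links) == 1 and links[0].link_class == "unambiguous"

    @pytest.mark.parametrize("group", ["omitted", "unassigned", "nonspecific"])
    def test_unidentifiable_host_gates_links(self, group):
        assert classify_links(
            profile_from_counts("bc", {"IM_07": 100}), _host(group)
        ) == []

    def test_superinfection_yields_multiple_ambiguous_links(self):
        links = classify_links(
            profile_from_counts("bc", {"A": 60, "B": 40}), _host()
        )
        assert len(links) == 2
        assert {l.link_class for l in links} == {"ambiguous"}


class TestBuildPairTable:
    def test_planted_pairs_recovered_unambiguously(self, small_experiment, small_pipeline, small_config):
        _, truth = small_experiment
        planted = truth.infected_pairs(exclude_family=small_config.dominant_family)
        planted = {
            (t, f)
            for t, f in planted
            if truth.cells.loc[
                (truth.cells["taxon"] == t) & (truth.cells["family"] == f),
                "true_viral_umis",
            ].max()
            >= 10
        }
        recovered = small_pipeline.recovered_pairs()
        # every recovered pair is planted
        assert recovered <= truth.infected_pairs()
        assert (small_pipeline.pairs["link_class"] == "unambiguous").all()
        # every well-covered planted pair with a host-assigned cell appears
        for taxon, family in planted:
            cells = truth.cells.loc[
                (truth.cells["taxon"] == taxon) & (truth.cells["family"] == family),
                "barcode",
            ]
            if any(
                small_pipeline.host_calls.get(bc)
                and small_pipeline.host_calls[bc].is_specific
                for bc in cells
            ):
                assert (taxon, family) in recovered

    def test_all_dominant_family_cells_gives_empty_table(self):
        calls = [InfectionCall("bc0", 2, 9, 20, True)]
        profiles = {"bc0": profile_from_counts("bc0", {"EhV": 20})}
        hosts = {"bc0": _host("groupA")}
        pairs, summary = vc.build_pair_table(calls, profiles, hosts, "EhV")
        assert len(pairs) == 0 and len(summary) == 0

    def test_sixty_forty_split_two_ambiguous_rows(self):
        calls = [InfectionCall("bc0", 2, 9, 20, True)]
        profiles = {"bc0": profile_from_counts("bc0", {"A": 60, "B": 40})}
        hosts = {"bc0": _host("groupA")}
        pairs, summary = vc.build_pair_table(calls, profiles, hosts, "EhV")
        assert len(pairs) == 2
        assert (pairs["link_class"] == "ambiguous").all()
        assert summary["n_unambiguous"].sum() == 0

    def test_deterministic_row_order(self):
        calls = [InfectionCall(f"bc{i}", 2, 9, 20, True) for i in range(3)]
        profiles = {
            "bc0": profile_from_counts("bc0", {"B": 20}),
            "bc1": profile_from_counts("bc1", {"A": 20}),
            "bc2": profile_from_counts("bc2", {"A": 20}),
        }
        hosts = {f"bc{i}": _host("g") for i in range(3)}
        pairs, _ = vc.build_pair_table(calls, profiles, hosts)
        assert list(pairs["family"]) == ["A", "A", "B"]
        assert list(pairs["barcode"])[:2] == ["bc1", "bc2"]


class TestViralGeneExpression:
    def _table(self, gene_totals):
        import scipy.sparse

        from virocell.screen import CellUMITable

        genes = sorted(gene_totals)
        counts = scipy.sparse.csr_matrix(
            np.array([[gene_totals[g] for g in genes]], dtype=np.int64)
        )
        return CellUMITable(
            barcodes=["bc0"],
            genes=genes,
            sources=["viral-marker"] * len(genes),
            counts=counts,
        )

    def test_log2_closed_form(self):
        table = self._table({"PolB": 7})
        out = vc.viral_gene_expression(table, ["bc0"])
        assert out.loc[0, "log2_expression"] == pytest.approx(3.0)

    def test_unexpressed_gene_zero(self):
        out = vc.viral_gene_expression(self._table({"PolB": 7, "MCP": 0}), ["bc0"])
        assert out.set_index("gene").loc["MCP", "log2_expression"] == 0.0

    def test_planted_chaperone_weights_rank_top_two(self):
        config = vc.CommunityConfig(
            taxon_names=["T1"],
            taxon_cell_fractions=[1.0],
            dominant_taxon="T1",
            family_names=["FamX"],
            marker_genes_per_family=5,
            infection_table=[InfectionEntry("T1", "FamX", 1.0, 0.3)],
            marker_gene_weights={"HSP70": 6.0, "HSP90": 6.0},
            ambient_viral_rate=0.0,
            doublet_rate=0.0,
            n_cells=12,
            reads_per_cell=("fixed", 200),
            seed=9,
        )
        refs = vc.simulate_references(config)
        reads, truth = vc.simulate_experiment(refs, config)
        table = vc.count_viral_umis(reads, refs.viral_proteins)
        out = vc.viral_gene_expression(table, truth.barcodes)
        assert set(out["gene"].head(2)) == {"HSP70", "HSP90"}
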