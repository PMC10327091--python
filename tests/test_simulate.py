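"""Simulator contracts: determinism, identity bands, planted-truth
consistency in the noise-free regime, and time-series structure."""

import numpy as np
import pytest

import virocell as vc
from virocell.homology import global_identity
from virocell.simulate import InfectionEntry, _translate0


def _one_taxon_config(**overrides):
    kwargs = dict(
        taxon_names=["TaxonA"],
        taxon_cell_fractions=[1.0],
        dominant_taxon="TaxonA",
        family_names=["FamX", "FamY"],
        infection_table=[InfectionEntry("TaxonA", "FamX", 1.0, 0.5)],
        ambient_viral_rate=0.0,
        doublet_rate=0.0,
        n_cells=3,
        reads_per_cell=("fixed", 100),
        seed=7,
    )
    kwargs.update(overrides)
    return vc.CommunityConfig(**kwargs)


class TestReferences:
    def test_seed_determinism_byte_identical(self, tmp_path):
        for name in ("a", "b"):
            refs = vc.simulate_references(_one_taxon_config(taxon_names=["T1", "T2"],
                                                            taxon_cell_fractions=[0.5, 0.5],
                                                            infection_table=[]))
            vc.write_fasta(refs.host_18s + refs.host_mrna + refs.viral_genes,
                           tmp_path / f"{name}.fa")
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()

    def test_cross_taxon_18s_identity_below_90(self, small_refs):
        recs = small_refs.host_18s
        for a in recs:
            for b in recs:
                ident = global_identity(a.sequence, b.sequence)
                if a.meta["group"] != b.meta["group"]:
                    assert ident < 90.0
                else:
                    assert ident >= 99.0

    def test_cross_taxon_contig_finds_only_own_18s_at_99_gate(self, small_refs):
        contig = small_refs.host_18s[0].sequence[500:900]
        hits = vc.search_nucleotide(contig, small_refs.host_18s, 99, 1e-10, 100)
        groups = {h.group_label for h in hits}
        assert groups == {small_refs.host_18s[0].meta["group"]}

    def test_proteins_are_frame0_translations(self, small_refs):
        by_id = {r.id: r for r in small_refs.viral_proteins}
        for gene in small_refs.viral_genes:
            assert _translate0(gene.sequence) == by_id[gene.id].sequence

    def test_cross_family_protein_identity_below_60(self, small_refs):
        prots = small_refs.viral_proteins
        for a in prots:
            for b in prots:
                if a.meta["family"] == b.meta["family"]:
                    continue
                n = min(len(a.sequence), len(b.sequence))
                ident = 100.0 * sum(
                    x == y for x, y in zip(a.sequence[:n], b.sequence[:n])
                ) / n
                assert ident < 60.0


class TestExperiment:
    def test_noise_free_planted_infection_recovered_exactly(self):
        config = _one_taxon_config()
        refs = vc.simulate_references(config)
        reads, truth = vc.simulate_experiment(refs, config)
        # viral share 0.5 of 100 reads, all infected
        assert truth.cells["infected"].all()
        assert truth.cells["true_viral_umis"].between(30, 70).all()
        table = vc.count_viral_umis(reads, refs.viral_proteins)
        totals = dict(zip(table.barcodes, table.total_umis().tolist()))
        for _, row in truth.cells.iterrows():
            assert totals.get(row["barcode"], 0) == row["true_viral_umis"]

    def test_zero_cells_gives_empty_outputs(self):
        config = _one_taxon_config(n_cells=0, infection_table=[])
        refs = vc.simulate_references(config)
        reads, truth = vc.simulate_experiment(refs, config)
        assert reads == [] and len(truth.cells) == 0

    def test_read_list_deterministic_under_seed(self):
        config = _one_taxon_config()
        refs = vc.simulate_references(config)
        r1, _ = vc.simulate_experiment(refs, config)
        r2, _ = vc.simulate_experiment(refs, config)
        assert r1 == r2

    def test_reads_are_exact_substrings_with_unique_umis(self, small_refs, small_experiment):
        reads, _ = small_experiment
        sources = [r.sequence for r in
                   small_refs.host_18s + small_refs.host_mrna + small_refs.viral_genes]
        rng = np.random.default_rng(4)
        for ri in rng.integers(0, len(reads), 200):
            cdna = reads[ri].cdna
            assert any(cdna in s for s in sources)
        per_bc: dict[str, set] = {}
        for r in reads:
            assert r.umi not in per_bc.setdefault(r.barcode, set())
            per_bc[r.barcode].add(r.umi)

    def test_doublet_barcodes_carry_two_taxa(self):
        config = _one_taxon_config(
            taxon_names=["T1", "T2"],
            taxon_cell_fractions=[0.5, 0.5],
            infection_table=[],
            doublet_rate=0.5,
            n_cells=20,
        )
        refs = vc.simulate_references(config)
        _, truth = vc.simulate_experiment(refs, config)
        doublets = truth.cells[truth.cells["doublet"]]
        assert len(doublets) == 10
        assert (doublets["taxon2"] != "").all()
        assert truth.cells["barcode"].is_unique


class TestRareClassRegime:
    def test_rare_focal_infected_cells_recovered_among_5000(self):
        """A 0.4% focal taxon among 5000 cells: every infected focal cell
        passes the infection screen, and pooling those cells identifies the
        focal species at the relaxed gate."""
        config = vc.default_config(
            n_cells=5000,
            reads_per_cell=("fixed", 300),
            infection_table=[
                InfectionEntry("Katablepharidaceae", "IM_07", 1.0, 0.08)
            ],
            ambient_viral_rate=0.0,
            doublet_rate=0.0,
            seed=70,
        )
        refs = vc.simulate_references(config)
        reads, truth = vc.simulate_experiment(refs, config)
        focal = truth.cells[truth.cells["taxon"] == "Katablepharidaceae"]
        assert 0 < len(focal) < 0.01 * config.n_cells
        trimmed = vc.trim_reads(reads)
        table = vc.count_viral_umis(trimmed, refs.viral_proteins)
        calls = {c.barcode: c for c in vc.call_highly_infected(table)}
        infected_focal = focal.loc[focal["infected"], "barcode"]
        assert len(infected_focal) > 0
        for bc in infected_focal:
            assert calls[bc].highly_infected
        species = vc.identify_pooled_subpopulation(
            list(infected_focal), trimmed, refs.host_18s
        )
        assert species.iloc[0]["species"] == "Katablepharidaceae_sp1"
        assert species.iloc[0]["best_identity"] >= 99.0


class TestTimeseries:
    def test_day_mismatch_errors(self):
        config = vc.default_config(seed=1)
        traj = vc.bloom_trajectory(config)
        with pytest.raises(ValueError, match="days"):
            vc.simulate_timeseries(config, [1, 2, 3], traj)

    def test_zero_infected_fraction_gives_no_infected_cells(self):
        config = vc.default_config(seed=1)
        traj = vc.bloom_trajectory(config)
        traj.infected_fraction = {d: 0.0 for d in traj.sc_days}
        _, experiments = vc.simulate_timeseries(config, traj.days, traj)
        for truth in experiments.values():
            assert not truth.cells["infected"].any()

    def test_metazoan_exclusion_renormalizes_to_one(self):
        config = vc.default_config(seed=2)
        traj = vc.bloom_trajectory(config, metazoan_fraction=0.5)
        asv, _ = vc.simulate_timeseries(config, traj.days, traj, n_asv_draws=5000)
        fractions = vc.relative_abundance(asv)
        assert np.allclose(fractions.sum(axis=1), 1.0)
        assert "Metazoa" not in fractions.columns

    def test_trajectory_recovered_within_sampling_error(self):
        config = vc.default_config(seed=5)
        traj = vc.bloom_trajectory(config)
        asv, _ = vc.simulate_timeseries(config, traj.days, traj, n_asv_draws=10_000)
        fractions = vc.relative_abundance(asv)
        focal = traj.focal_taxon
        for day in traj.days:
            fr = traj.fractions[day]
            non_met = sum(v for t, v in fr.items() if t != "Metazoa")
            expected = fr[focal] / non_met
            n_eff = asv.loc[(asv["day"] == day) & (asv["taxon"] != "Metazoa"), "count"].sum()
            se = np.sqrt(expected * (1 - expected) / n_eff)
            assert abs(fractions.loc[day, focal] - expected) <= 3 * se + 1e-12
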