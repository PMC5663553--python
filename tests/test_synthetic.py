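"""Generator sanity: determinism, planted-effect calibration, null rates."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mycnsig import synthetic
from mycnsig.screen import auc_score


def _amplified_mask(samples):
    return (samples.data["mycn_status"] == "amplified").to_numpy()


class TestGenerateCohort:
    def test_deterministic_for_fixed_seed(self, small_spec):
        m1, s1, t1 = synthetic.generate_cohort(small_spec)
        m2, s2, t2 = synthetic.generate_cohort(small_spec)
        assert m1.data.equals(m2.data)
        assert s1.data.equals(s2.data)
        assert t1.marker_directions == t2.marker_directions

    def test_amplified_count_follows_rounding_rule(self):
        spec = synthetic.CohortSpec(
            n_samples=200, frac_amplified=0.25, n_genes=10,
            marker_genes=("G00000",), seed=1,
        )
        _, samples, _ = synthetic.generate_cohort(spec)
        assert (samples.data["mycn_status"] == "amplified").sum() == 50

    def test_matrix_strictly_positive(self, small_cohort):
        matrix, _, _ = small_cohort
        assert (matrix.data.to_numpy() > 0).all()

    def test_controls_sit_at_baseline(self, small_cohort):
        matrix, samples, truth = small_cohort
        controls = samples.control_samples()
        tumors_wt = samples.data.loc[
            (samples.data["mycn_status"] == "wild_type"), "sample_id"
        ]
        gene = sorted(truth.marker_genes)[0]  # an up-marker
        diff = (
            np.log2(matrix.data.loc[gene, list(tumors_wt)]).mean()
            - np.log2(matrix.data.loc[gene, controls]).mean()
        )
        # wild-type tumors and controls share the baseline on marker genes
        assert abs(diff) < 4 * 0.5 / np.sqrt(6)

    def test_zero_effect_means_no_marker_shift(self, small_spec):
        spec = dataclasses.replace(small_spec, effect_log2=0.0)
        matrix, samples, truth = synthetic.generate_cohort(spec)
        amp = _amplified_mask(samples)[: spec.n_samples]
        tumor_cols = samples.tumor_samples()
        log2 = np.log2(matrix.data[tumor_cols].to_numpy())
        for gene in sorted(truth.marker_genes):
            row = log2[matrix.gene_ids.index(gene)]
            diff = row[amp].mean() - row[~amp].mean()
            n_eff = min(amp.sum(), (~amp).sum())
            assert abs(diff) < 4 * spec.noise_sd_log2 / np.sqrt(n_eff)

    def test_planted_effect_yields_large_t_statistic(self):
        """With a 4-fold shift at noise 0.5 and n=200 the marker t-statistic
        must dwarf 10 (analytic expectation ~22)."""
        genes = tuple(f"G{i:04d}" for i in range(20))
        for seed in range(3):
            spec = synthetic.CohortSpec(
                n_samples=200, frac_amplified=0.2, n_genes=20, gene_ids=genes,
                marker_genes=genes[:2], effect_log2=2.0, noise_sd_log2=0.5,
                seed=seed,
            )
            matrix, samples, truth = synthetic.generate_cohort(spec)
            amp = _amplified_mask(samples)
            up = sorted(truth.marker_genes)[0]
            vals = np.log2(matrix.data.loc[up].to_numpy())
            t, _ = stats.ttest_ind(vals[amp], vals[~amp])
            assert t > 10

    def test_half_markers_up_half_down(self, small_cohort):
        _, _, truth = small_cohort
        dirs = list(truth.marker_directions.values())
        assert dirs.count(1) == 4 and dirs.count(-1) == 4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 0},
            {"frac_amplified": 0.0},
            {"frac_amplified": 1.0},
            {"marker_genes": ()},
            {"noise_sd_log2": 0.0},
        ],
    )
    def test_invalid_specs_rejected(self, small_spec, kwargs):
        with pytest.raises(ValueError):
            dataclasses.replace(small_spec, **kwargs)

    def test_marker_outside_universe_rejected(self, small_spec):
        with pytest.raises(ValueError, match="universe"):
            dataclasses.replace(small_spec, marker_genes=("NOPE",))


class TestEffectCalibration:
    def test_mean_marker_auc_monotone_in_effect(self):
        """Across 100 simulated cohorts the mean AUC of a planted marker gene
        increases with the planted effect size."""
        genes = tuple(f"G{i:03d}" for i in range(10))
        mean_aucs = []
        for effect in (0.0, 0.5, 1.0, 2.0):
            aucs = []
            for seed in range(100):
                spec = synthetic.CohortSpec(
                    n_samples=60, frac_amplified=0.25, n_genes=10,
                    gene_ids=genes, marker_genes=genes[:2],
                    effect_log2=effect, noise_sd_log2=0.7, seed=seed,
                )
                matrix, samples, truth = synthetic.generate_cohort(spec)
                amp = _amplified_mask(samples)
                up = sorted(truth.marker_genes)[0]
                _, oriented, _ = auc_score(matrix.data.loc[up].to_numpy(), amp)
                aucs.append(oriented)
            mean_aucs.append(np.mean(aucs))
        assert mean_aucs == sorted(mean_aucs)
        assert mean_aucs[-1] > 0.95

    def test_null_pass_rate_matches_permutation_oracle(self):
        """At zero effect, the fraction of genes with oriented AUC >= 0.8
        matches the label-permutation rate of that event."""
        n, n_amp, n_genes = 40, 10, 2000
        genes = tuple(f"G{i:04d}" for i in range(n_genes))
        spec = synthetic.CohortSpec(
            n_samples=n, frac_amplified=n_amp / n, n_genes=n_genes,
            gene_ids=genes, marker_genes=genes[:1], effect_log2=0.0,
            noise_sd_log2=0.7, seed=11,
        )
        matrix, samples, _ = synthetic.generate_cohort(spec)
        amp = _amplified_mask(samples)
        from scipy.stats import rankdata

        values = matrix.data.to_numpy()
        ranks = rankdata(values, axis=1)
        u = ranks[:, amp].sum(axis=1) - n_amp * (n_amp + 1) / 2
        raw = u / (n_amp * (n - n_amp))
        observed_rate = float(np.mean(np.maximum(raw, 1 - raw) >= 0.8))

        # brute-force Monte-Carlo of the same event under label permutation
        rng = np.random.default_rng(5)
        reps = 4000
        vals = rng.normal(size=(reps, n))
        r = rankdata(vals, axis=1)
        labels = np.zeros(n, bool)
        labels[:n_amp] = True
        hits = 0
        for i in range(reps):
            perm = rng.permutation(labels)
            ui = r[i, perm].sum() - n_amp * (n_amp + 1) / 2
            a = ui / (n_amp * (n - n_amp))
            hits += max(a, 1 - a) >= 0.8
        oracle_rate = hits / reps
        se = np.sqrt(
            oracle_rate * (1 - oracle_rate) * (1 / n_genes + 1 / reps)
        )
        assert abs(observed_rate - oracle_rate) < 3 * max(se, 1e-3)


class TestPathwayDB:
    def test_marker_pathways_fully_enriched_at_one(self, small_cohort):
        _, _, truth = small_cohort
        db, truth2 = synthetic.generate_pathway_db(
            [f"G{i:03d}" for i in range(40)], truth,
            n_pathways=5, size_range=(5, 8), n_marker_pathways=2,
            marker_enrichment=1.0, seed=3,
        )
        for name in truth2.marker_pathways:
            assert set(db.members(name)) <= truth.marker_genes

    def test_no_marker_pathways_means_no_enrichment(self, small_cohort):
        _, _, truth = small_cohort
        universe = [f"G{i:03d}" for i in range(40)]
        db, _ = synthetic.generate_pathway_db(
            universe, truth, n_pathways=40, size_range=(10, 10),
            n_marker_pathways=0, seed=3,
        )
        expected = 10 * len(truth.marker_genes) / len(universe)
        for name in db.pathway_names:
            overlap = len(set(db.members(name)) & truth.marker_genes)
            assert overlap <= 2 * expected + 1

    def test_coherent_arr_signs_in_marker_pathways(self, small_cohort):
        _, _, truth = small_cohort
        db, truth2 = synthetic.generate_pathway_db(
            [f"G{i:03d}" for i in range(40)], truth,
            n_pathways=4, size_range=(6, 10), n_marker_pathways=4,
            marker_enrichment=0.8, seed=9,
        )
        for name in truth2.marker_pathways:
            for gene, arr in db.members(name).items():
                if gene in truth.marker_directions:
                    assert np.sign(arr) == truth.marker_directions[gene]

    def test_infeasible_enrichment_names_constraint(self, small_cohort):
        _, _, truth = small_cohort
        with pytest.raises(ValueError, match="enrichment infeasible"):
            synthetic.generate_pathway_db(
                [f"G{i:03d}" for i in range(40)], truth,
                n_pathways=2, size_range=(20, 20), n_marker_pathways=1,
                marker_enrichment=1.0, seed=0,
            )

    def test_fixed_seed_reproduces_database(self, small_cohort, tmp_path):
        from mycnsig.io import write_pathway_db

        _, _, truth = small_cohort
        paths = []
        for run in range(2):
            db, _ = synthetic.generate_pathway_db(
                [f"G{i:03d}" for i in range(40)], truth,
                n_pathways=6, size_range=(4, 9), n_marker_pathways=2,
                marker_enrichment=0.5, seed=13,
            )
            p = tmp_path / f"db{run}.tsv"
            write_pathway_db(db, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]


class TestNetwork:
    def test_star_topology_links_markers_through_connector(self):
        truth = synthetic.PlantedTruth(
            marker_genes={"A", "B", "C"}, connector_nodes={"X"}
        )
        g = synthetic.generate_network(["A", "B", "C", "X"], truth, mean_degree=0, seed=0)
        import networkx as nx

        for pair in (("A", "B"), ("A", "C"), ("B", "C")):
            assert nx.shortest_path_length(g, *pair) == 2
            assert nx.shortest_path(g, *pair)[1] == "X"

    def test_zero_background_gives_only_planted_edges(self):
        truth = synthetic.PlantedTruth(
            marker_genes={"A", "B"}, connector_nodes={"X", "Y"}
        )
        g = synthetic.generate_network(["A", "B", "X", "Y", "Z"], truth, mean_degree=0, seed=0)
        expected = {frozenset(e) for e in [("A", "X"), ("B", "Y"), ("X", "Y")]}
        assert {frozenset(e) for e in g.edges} == expected

    def test_fixed_seed_identical_edge_list(self):
        truth = synthetic.PlantedTruth(marker_genes={"A", "B"}, connector_nodes=set())
        nodes = [f"N{i}" for i in range(30)] + ["A", "B"]
        g1 = synthetic.generate_network(nodes, truth, mean_degree=3, seed=5)
        g2 = synthetic.generate_network(nodes, truth, mean_degree=3, seed=5)
        assert sorted(map(sorted, g1.edges)) == sorted(map(sorted, g2.edges))

    def test_connector_marker_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            synthetic.PlantedTruth(marker_genes={"A"}, connector_nodes={"A"})
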