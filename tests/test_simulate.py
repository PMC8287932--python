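"""The synthetic cohort generator: determinism, ground-truth consistency
and the hypoxia->APOBEC coupling."""

import numpy as np
import pytest

import tcwsig as t


class TestMakeGenome:
    def test_pure_gc_has_no_tcw_sites(self):
        g = t.make_genome(2000, 0.999999, seed=1)
        pos, _ = t.tcw_site_positions(g)
        assert len(pos) == 0

    def test_same_seed_identical_fasta(self, tmp_path):
        a, b = tmp_path / "a.fa", tmp_path / "b.fa"
        t.make_genome(5000, 0.45, seed=42).write_fasta(a)
        t.make_genome(5000, 0.45, seed=42).write_fasta(b)
        assert a.read_bytes() == b.read_bytes()

    def test_gc_fraction_within_sampling_error(self):
        L, g = 100_000, 0.45
        genome = t.make_genome(L, g, seed=3)
        seq = genome.sequences["chr1"]
        observed = (seq.count("G") + seq.count("C")) / L
        se = np.sqrt(g * (1 - g) / L)
        assert abs(observed - g) < 3 * se

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="1000"):
            t.make_genome(500, 0.5, seed=0)


class TestSimulateCohort:
    def test_byte_identical_outputs_under_seed(self, tmp_path):
        params = t.CohortParams(n_samples=10, genome_length=20_000, seed=99)
        t.simulate_cohort(params, outdir=tmp_path / "a")
        t.simulate_cohort(params, outdir=tmp_path / "b")
        for name in ("genome.fasta", "mutations.tsv", "mutations.vcf",
                     "expression.tsv", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_truth_counts_exact_with_collision_exclusion(self, shared_genome):
        params = t.CohortParams(n_samples=50, mean_mutations=100.0, seed=7)
        cohort = t.simulate_cohort(params, exclude_collisions=True,
                                   genome=shared_genome)
        counts = t.count_per_sample(cohort.genome, cohort.catalog)
        counted = counts.set_index("sample")["n_apobec"]
        truth = cohort.truth.apobec_count
        assert (counted.loc[truth.index] == truth).all()

    def test_counts_conserved_and_bounded(self, shared_genome):
        cohort = t.simulate_cohort(
            t.CohortParams(n_samples=20, seed=5), genome=shared_genome
        )
        counts = t.count_per_sample(cohort.genome, cohort.catalog)
        assert (counts["n_apobec"] <= counts["n_classifiable"]).all()
        assert (counts["n_classifiable"] <= counts["n_total"]).all()
        assert counts["n_total"].sum() == len(cohort.catalog)
        totals = cohort.truth.total_count
        assert (counts.set_index("sample")["n_total"].loc[totals.index] == totals).all()

    def test_injected_sites_are_distinct_per_sample(self, shared_genome):
        cohort = t.simulate_cohort(
            t.CohortParams(n_samples=10, seed=13), genome=shared_genome
        )
        for _, grp in cohort.catalog.frame.groupby("sample"):
            assert grp["pos"].is_unique

    def test_noise_free_score_is_monotone_in_hypoxia(self, shared_genome):
        cohort = t.simulate_cohort(
            t.CohortParams(n_samples=40, noise_sigma=0.0, n_filler_genes=0, seed=3),
            genome=shared_genome,
        )
        res = t.score_signature(cohort.expression, t.hypoxia_signature())
        rho = t.spearman(res.scores, cohort.truth.hypoxia.loc[res.scores.index]).rho
        assert rho == pytest.approx(1.0)

    def test_no_coupling_gives_centered_rho(self, shared_genome):
        rhos = []
        for seed in range(30):
            cohort = t.simulate_cohort(
                t.CohortParams(n_samples=80, slope=0.0, seed=1000 + seed),
                genome=shared_genome,
            )
            counts = t.count_per_sample(cohort.genome, cohort.catalog)
            scores = t.score_signature(cohort.expression, t.hypoxia_signature()).scores
            table = t.build_score_table({"hypsig": scores}, counts)
            rhos.append(t.spearman(table["hypsig"], table["n_apobec"]).rho)
        # mean of 30 null rhos ~ N(0, 1/sqrt(30*79)); 0.15 is ~7 SD
        assert abs(np.mean(rhos)) < 0.15

    def test_insufficient_tcw_sites_error(self):
        with pytest.raises(ValueError, match="TCW sites"):
            t.simulate_cohort(
                t.CohortParams(n_samples=5, genome_length=1000,
                               mean_mutations=500.0, seed=1)
            )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            t.CohortParams(genome_length=10)
        with pytest.raises(ValueError):
            t.CohortParams(gc_fraction=1.5)
        with pytest.raises(ValueError):
            t.CohortParams(noise_sigma=-1.0)


class TestSimulateCellAssay:
    def test_zero_mean_channel_all_negative(self):
        cells, _ = t.simulate_cell_assay(
            {"x": t.CellConditionSpec(foci_means={"53BP1": 0.0, "RPA": 0.0},
                                      n_cells=200)},
            seed=1,
        )
        _, summary = t.classify_cells(cells, "53BP1")
        assert summary.loc[0, "pct_positive"] == 0.0

    def test_unit_multiplier_ratio_near_one(self):
        cells, _ = t.simulate_cell_assay(
            {"x": t.CellConditionSpec(foci_means={"53BP1": 8.0, "RPA": 9.0},
                                      area_multiplier=1.0, n_cells=2000)},
            seed=4,
        )
        res = t.compare_nuclear_area(cells)
        means = res.groups.set_index("group")["mean"]
        assert means["double_positive"] / means["negative"] == pytest.approx(1.0, rel=0.05)

    def test_deterministic_under_seed(self):
        spec = {"x": t.CellConditionSpec(n_cells=50)}
        a, _ = t.simulate_cell_assay(spec, seed=7)
        b, _ = t.simulate_cell_assay(spec, seed=7)
        assert a.equals(b)

    def test_invalid_dispersion_rejected(self):
        with pytest.raises(ValueError, match="dispersion"):
            t.CellConditionSpec(foci_dispersion=0.0)


def test_coupling_strength_increases_median_rho(shared_genome):
    """The median cohort-level correlation rises monotonically with the
    hypoxia->APOBEC slope."""
    medians = []
    for b in (0.0, 1.0, 2.0):
        rhos = []
        for seed in range(12):
            cohort = t.simulate_cohort(
                t.CohortParams(n_samples=80, slope=b, seed=2000 + seed),
                genome=shared_genome,
            )
            counts = t.count_per_sample(cohort.genome, cohort.catalog)
            scores = t.score_signature(cohort.expression, t.hypoxia_signature()).scores
            table = t.build_score_table({"hypsig": scores}, counts)
            rhos.append(t.spearman(table["hypsig"], table["n_apobec"]).rho)
        medians.append(float(np.median(rhos)))
    assert medians[0] < medians[1] < medians[2]
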