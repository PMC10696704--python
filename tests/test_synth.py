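"""Synthetic generators: planted truth must be recoverable."""

import numpy as np
import pytest

from sipautotroph import (
    PopulationSpec,
    RunConfig,
    TracerSimSpec,
    call_labeling,
    call_labeling_table,
    classify_ko_table,
    dic_assimilation_rate,
    peak_density,
    simulate_fraction_taxa,
    simulate_gradient,
    simulate_ko_table,
    simulate_tracer,
)
from sipautotroph.synth import RHO_BASE, RHO_PER_GC, SHIFT_C13, SHIFT_N15

GRID = np.round(np.arange(1.675, 1.7651, 0.003), 6)


class TestGradientSim:
    def test_unlabeled_band_centers_on_gc_density(self):
        # band center 1.660 + 0.098*0.40 = 1.6992; nearest grid point wins
        pop = PopulationSpec("p", gc_content=0.40)
        prof = simulate_gradient([pop], GRID, noise_cv=0.0, seed=0)
        expected = GRID[np.argmin(np.abs(GRID - (RHO_BASE + RHO_PER_GC * 0.40)))]
        assert peak_density(prof) == pytest.approx(expected)

    def test_c13_shift_moves_peak_by_exactly_its_delta(self):
        base = PopulationSpec("p", gc_content=0.40)
        heavy = PopulationSpec("p", gc_content=0.40, labeling_state="C13")
        assert heavy.band_center() - base.band_center() == pytest.approx(SHIFT_C13)
        dual = PopulationSpec("p", gc_content=0.40, labeling_state="C13N15")
        assert dual.band_center() - base.band_center() == pytest.approx(
            SHIFT_C13 + SHIFT_N15
        )

    def test_seeding_contract(self):
        pop = [PopulationSpec("p", gc_content=0.45)]
        a = simulate_gradient(pop, GRID, noise_cv=0.2, seed=7)
        b = simulate_gradient(pop, GRID, noise_cv=0.2, seed=7)
        c = simulate_gradient(pop, GRID, noise_cv=0.2, seed=8)
        assert np.array_equal(a.copies, b.copies)
        assert not np.array_equal(a.copies, c.copies)

    def test_dual_labeled_population_mass_lands_in_uh(self, config):
        """Nearly all copies of a fully 13C+15N-labeled population fall in UH."""
        pop = PopulationSpec("p", gc_content=0.40, labeling_state="C13N15")
        prof = simulate_gradient([pop], GRID, noise_cv=0.0, seed=0)
        from sipautotroph import classify_fractions

        labels = classify_fractions(prof, config)
        in_uh = sum(
            f.copies for f, lab in zip(prof.fractions, labels) if lab == "UH"
        )
        assert in_uh / prof.copies.sum() >= 0.99

    def test_input_validation(self):
        pop = [PopulationSpec("p", gc_content=0.4)]
        with pytest.raises(ValueError, match="empty"):
            simulate_gradient([], GRID)
        with pytest.raises(ValueError, match="increasing"):
            simulate_gradient(pop, [1.7, 1.69, 1.71])


class TestTracerSim:
    def test_null_rate_identity(self):
        sim = simulate_tracer(TracerSimSpec(true_rate=0.0, delta_noise_sd=0.0))
        assert sim.incubation.delta_t == pytest.approx(sim.incubation.delta_0)
        assert sim.incubation.poc_t == pytest.approx(sim.incubation.poc_0)

    def test_noiseless_round_trip_recovers_rate(self):
        spec = TracerSimSpec(true_rate=0.0229, delta_noise_sd=0.0)
        sim = simulate_tracer(spec, seed=0)
        est = dic_assimilation_rate(sim.incubation)
        assert est.rate == pytest.approx(0.0229, rel=1e-9)

    def test_round_trip_identity_across_parameter_grid(self, rng):
        """Forward model then rate estimator is the identity at zero noise."""
        for _ in range(50):
            spec = TracerSimSpec(
                true_rate=float(rng.uniform(1e-3, 3.0)),
                poc_0=float(rng.uniform(2.0, 50.0)),
                delta_0=float(rng.uniform(-40.0, 0.0)),
                t=float(rng.uniform(0.25, 4.0)),
                ca_dic=float(rng.uniform(500.0, 5000.0)),
                cs_dic=float(rng.uniform(500.0, 5000.0)),
                delta_noise_sd=0.0,
            )
            sim = simulate_tracer(spec, seed=0)
            est = dic_assimilation_rate(sim.incubation)
            assert est.rate == pytest.approx(spec.true_rate, rel=1e-9)

    def test_endpoint_atom_fraction_bounded_by_tracer_pool(self):
        """Mass balance caps n_t below max(n_0, Cs/(Ca+Cs)), so it stays < 1."""
        from sipautotroph.isotopes import delta_to_atom_fraction

        spec = TracerSimSpec(true_rate=1e6, poc_0=0.01, t=100.0, delta_noise_sd=0.0)
        sim = simulate_tracer(spec)
        nt = delta_to_atom_fraction(sim.incubation.delta_t)
        bound = max(
            delta_to_atom_fraction(spec.delta_0),
            spec.cs_dic / (spec.ca_dic + spec.cs_dic),
        )
        assert nt < bound


class TestKOSim:
    def test_noiseless_core_only_recovery(self, config):
        triples, truth = simulate_ko_table(10, 0, 0, fold=4.0, noise_cv=0.0, seed=1)
        classes = classify_ko_table(triples, config, normalize=False)
        assert all(c.category == "core" for c in classes)
        assert len(classes) == 10

    def test_noiseless_enriched_recovery(self, config):
        triples, truth = simulate_ko_table(
            20, n_enriched=(5, 0, 0), fold=4.0, noise_cv=0.0, seed=2
        )
        classes = classify_ko_table(triples, config, normalize=False)
        got = {c.ko_id: c.category for c in classes}
        enr = [k for k, v in truth.items() if v == "enriched(1)"]
        assert len(enr) == 5
        assert all(got[k] == "enriched(1)" for k in enr)

    def test_noisy_recovery_above_95_percent(self, config):
        """cv 0.05 noise with fold 8 plants: >= 95% of 1000 KOs recovered."""
        triples, truth = simulate_ko_table(
            n_core=400,
            n_enriched=(100, 100, 100),
            n_diluted=(100, 100, 100),
            fold=8.0,
            noise_cv=0.05,
            seed=3,
        )
        classes = classify_ko_table(triples, config, normalize=False)
        hits = sum(c.category == truth[c.ko_id] for c in classes)
        assert hits / len(classes) >= 0.95

    def test_fold_at_or_below_threshold_rejected(self, config):
        with pytest.raises(ValueError, match="fold"):
            simulate_ko_table(5, fold=2.0, config=config)

    def test_deterministic_under_seed(self):
        a, _ = simulate_ko_table(5, 2, 2, fold=4.0, noise_cv=0.1, seed=9)
        b, _ = simulate_ko_table(5, 2, 2, fold=4.0, noise_cv=0.1, seed=9)
        assert [t.values for t in a] == [t.values for t in b]


class TestTaxaSim:
    def test_fraction_columns_sum_to_one(self):
        records, _ = simulate_fraction_taxa(["a", "b"], ["c"], seed=4)
        for col in ("rel_abundance_L", "rel_abundance_H", "rel_abundance_UH"):
            assert sum(getattr(r, col) for r in records) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_planted_recovery_mixed_community(self, config):
        records, truth = simulate_fraction_taxa(
            [f"l{i}" for i in range(6)], [f"u{i}" for i in range(4)], seed=5
        )
        calls = call_labeling_table(records, config, min_abundance=0.0)
        assert all(c.verdict == truth[c.taxon] for c in calls)

    def test_all_labeled_community_all_called_labeled(self, config):
        records, truth = simulate_fraction_taxa(
            [f"l{i}" for i in range(8)], [], seed=6
        )
        for rec in records:
            assert call_labeling(rec, config).verdict == "labeled"

    def test_labeled_taxa_enrich_heavy_unlabeled_decline_twofold(self):
        records, truth = simulate_fraction_taxa(["a"], ["b"], seed=7)
        by_name = {r.taxon: r for r in records}
        a, b = by_name["a"], by_name["b"]
        assert a.rel_abundance_H >= a.rel_abundance_L
        assert a.rel_abundance_UH >= a.rel_abundance_L
        assert b.rel_abundance_H <= b.rel_abundance_L / 2
        assert b.rel_abundance_UH <= b.rel_abundance_H

    def test_unlabeled_only_community_rejected(self):
        with pytest.raises(ValueError, match="closure"):
            simulate_fraction_taxa([], ["u1", "u2"], seed=8)

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError, match="at least one taxon"):
            simulate_fraction_taxa([], [], seed=0)
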