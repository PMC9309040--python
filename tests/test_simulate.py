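"""Synthetic-data generators: determinism, design sizes, known-truth recovery."""

import math

import numpy as np
import pytest

from nemapatch import (
    ConfigError,
    SimulationConfig,
    SpeciesParams,
    chao2,
    build_incidence,
    fit_zero_class,
    simulate_bait_experiment,
    simulate_collections,
    simulate_exclosure,
    simulate_gustavia_survey,
)
from nemapatch.simulate import BaitDesign


class TestConfigValidation:
    @pytest.mark.parametrize(
        "bad",
        [
            dict(species={"C. briggsae": SpeciesParams(lam=-1.0)}),
            dict(species={"C. briggsae": SpeciesParams(lam=1.0, sigma=-0.1)}),
            dict(patches_per_quadrat=0),
            dict(bait=BaitDesign(loss_prob=1.5)),
        ],
    )
    def test_invalid_config_rejected_before_generation(self, bad):
        with pytest.raises(ConfigError):
            simulate_collections(SimulationConfig(**bad))

    def test_yaml_round_trip(self, tmp_path):
        import yaml

        path = tmp_path / "sim.yaml"
        path.write_text(yaml.safe_dump({
            "seed": 7,
            "species": {"C. briggsae": {"lam": 0.5, "sigma": 0.0}},
        }))
        cfg = SimulationConfig.from_yaml(path)
        assert cfg.seed == 7
        assert cfg.species["C. briggsae"].lam == 0.5


class TestDeterminismAndDesign:
    def test_identical_seed_identical_output(self):
        a = simulate_collections(SimulationConfig(seed=13))
        b = simulate_collections(SimulationConfig(seed=13))
        assert a.records == b.records and a.truth.equals(b.truth)
        assert simulate_bait_experiment(SimulationConfig(seed=13)) == \
            simulate_bait_experiment(SimulationConfig(seed=13))
        assert simulate_exclosure(SimulationConfig(seed=13)) == \
            simulate_exclosure(SimulationConfig(seed=13))

    def test_different_seed_differs(self):
        a = simulate_gustavia_survey(SimulationConfig(seed=1))
        b = simulate_gustavia_survey(SimulationConfig(seed=2))
        assert a.records != b.records

    def test_design_sizes(self):
        cfg = SimulationConfig(seed=0)
        assert len(simulate_gustavia_survey(cfg).records) == 44
        assert len(simulate_bait_experiment(cfg)) == 210
        assert len(simulate_exclosure(cfg)) == 144

    def test_small_gustavia_design(self):
        cfg = SimulationConfig(seed=0, gustavia_quadrats=(1,),
                               flowers_per_quadrat=4)
        assert len(simulate_gustavia_survey(cfg).records) == 4

    def test_truth_sidecar_consistent_with_records(self):
        sim = simulate_gustavia_survey(SimulationConfig(seed=3))
        occupied = sim.truth[sim.truth.k >= 1]
        by_sample = occupied.groupby("sample_id")["species"].apply(set).to_dict()
        for rec in sim.records:
            assert set(rec.species_present) == by_sample.get(rec.sample_id, set())


class TestStatisticalStructure:
    def test_zero_intensity_gives_empty_world(self):
        cfg = SimulationConfig(seed=0, species={
            "C. briggsae": SpeciesParams(lam=0.0, sigma=0.0)})
        sim = simulate_collections(cfg)
        assert all(not r.species_present for r in sim.records)

    def test_homogeneous_occupancy_matches_closed_form(self, homogeneous_config):
        sim = simulate_collections(homogeneous_config)
        n = len(sim.records)
        occ = np.mean([bool(r.species_present) for r in sim.records])
        p = 1 - math.exp(-1.08)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(occ - p) < 3 * se

    def test_zero_class_recovers_lambda_homogeneous(self, homogeneous_config):
        sim = simulate_collections(homogeneous_config)
        n = len(sim.records)
        k = sum(bool(r.species_present) for r in sim.records)
        est = fit_zero_class(n, k)
        p = 1 - math.exp(-1.08)
        sd = math.sqrt(p / (n * (1 - p)))
        assert abs(est.lambda_hat - 1.08) < 3 * sd

    def test_heterogeneity_biases_zero_class_downward(self):
        """With lognormal patchiness the zero class is inflated, so the
        homogeneous estimator must underestimate λ in every replicate
        survey; the size of the bias (averaged over replicates, ± 3 SE of
        the replicate mean) is checked against a direct Monte-Carlo
        evaluation of the mixed-model occupancy."""
        lam, sigma = 1.08, 1.5
        lam_hats = []
        for seed in range(40):
            cfg = SimulationConfig(
                seed=seed, sites_per_locality=40, quadrats_per_site=4,
                patches_per_quadrat=5,
                species={"C. briggsae": SpeciesParams(lam=lam, sigma=sigma)},
            )
            sim = simulate_collections(cfg)
            n = len(sim.records)
            k = sum(bool(r.species_present) for r in sim.records)
            lam_hats.append(fit_zero_class(n, k).lambda_hat)
        lam_hats = np.array(lam_hats)
        assert np.all(lam_hats < lam)  # downward bias in every replicate
        # direct MC oracle for the mixed-model occupancy
        r = np.random.default_rng(99)
        eps = r.normal(0, sigma / math.sqrt(2), size=(2, 400_000)).sum(axis=0)
        p_occ = 1 - np.exp(-lam * np.exp(eps - sigma**2 / 2)).mean()
        lam_expected = -math.log1p(-p_occ)
        se = lam_hats.std(ddof=1) / math.sqrt(len(lam_hats))
        assert abs(lam_hats.mean() - lam_expected) < 3 * se

    def test_heterogeneity_increases_quadrat_variance(self):
        """Between-quadrat occupancy variance grows with σ at fixed λ."""
        def quadrat_variance(sigma, runs=200):
            vs = []
            for run in range(runs):
                cfg = SimulationConfig(
                    seed=run, species={
                        "C. briggsae": SpeciesParams(lam=1.0, sigma=sigma)},
                )
                sim = simulate_gustavia_survey(cfg)
                occ = {}
                for rec in sim.records:
                    key = (rec.site, rec.quadrat)
                    occ.setdefault(key, []).append(bool(rec.species_present))
                vs.append(np.var([np.mean(v) for v in occ.values()]))
            return float(np.mean(vs))

        assert quadrat_variance(2.0) > quadrat_variance(0.0)

    def test_bait_loss_mean_matches_binomial(self):
        """Mean number of lost baits across runs ≈ 210 · loss_prob."""
        runs = 400
        lost = [
            sum(not r.recovered for r in
                simulate_bait_experiment(SimulationConfig(seed=s)))
            for s in range(runs)
        ]
        expected = 29.0
        se = math.sqrt(210 * (29 / 210) * (1 - 29 / 210) / runs)
        assert abs(np.mean(lost) - expected) < 3 * se

    def test_loss_probability_one_loses_everything(self):
        cfg = SimulationConfig(seed=0, bait=BaitDesign(loss_prob=1.0))
        assert all(not r.recovered for r in simulate_bait_experiment(cfg))

    def test_chao2_on_simulated_assemblages_bounded_below(self):
        for seed in range(10):
            sim = simulate_collections(SimulationConfig(seed=seed))
            recs = [r for r in sim.records if r.species_present]
            if not recs:
                continue
            mat = build_incidence(recs)
            est = chao2(mat.incidence_frequencies, mat.m)
            assert est.chao2_point >= est.s_obs

    def test_all_species_common_collapses_to_observed(self):
        cfg = SimulationConfig(
            seed=0, sites_per_locality=10,
            species={"C. briggsae": SpeciesParams(lam=6.0, sigma=0.0),
                     "C. tropicalis": SpeciesParams(lam=6.0, sigma=0.0)},
        )
        sim = simulate_collections(cfg)
        mat = build_incidence(sim.records)
        est = chao2(mat.incidence_frequencies, mat.m)
        assert est.chao2_point == est.s_obs
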