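"""Synthetic-study generator: determinism, design structure, planted laws."""

import numpy as np
import pytest

from allomap.synth import (
    BackgroundError,
    GeneratorConfig,
    InvalidConfigError,
    generate_library,
    generate_observations,
    generate_structure,
    generate_study,
    generate_truth,
)
from allomap.thermo import AA_ALPHABET, MutationID


class TestGenerateTruth:
    def test_seeded_determinism(self):
        cfg = GeneratorConfig(n_positions=30, n_tiles=2)
        t1 = generate_truth(cfg, seed=1)
        t2 = generate_truth(cfg, seed=1)
        assert t1.wt_sequence == t2.wt_sequence
        assert t1.ddGf == t2.ddGf and t1.ddGa == t2.ddGa
        assert t1.affine == t2.affine

    def test_too_few_positions_rejected(self):
        with pytest.raises(InvalidConfigError):
            generate_truth(GeneratorConfig(n_positions=9, n_tiles=5), seed=0)

    def test_nineteen_substitutions_per_position(self):
        truth = generate_truth(GeneratorConfig(n_positions=24, n_tiles=2), seed=2)
        per_pos = {}
        for m in truth.ddGf:
            per_pos.setdefault(m.position, set()).add(m.mut_aa)
            assert m.wt_aa == truth.wt_sequence[m.position - 1]
            assert m.mut_aa != m.wt_aa
        assert set(per_pos) == set(range(1, 25))
        assert all(len(s) == 19 for s in per_pos.values())

    def test_every_position_in_exactly_one_tile(self):
        truth = generate_truth(GeneratorConfig(n_positions=47, n_tiles=5), seed=3)
        for m in truth.ddGf:
            assert truth.tile_of(m.position) in range(1, 6)

    def test_zero_allosteric_fraction_zeroes_ddga_outside_active_site(self):
        cfg = GeneratorConfig(
            n_positions=30, n_tiles=2, frac_allosteric=0.0, frac_activating=0.0
        )
        truth = generate_truth(cfg, seed=4)
        for m, v in truth.ddGa.items():
            if m.position not in truth.active_site:
                assert v == 0.0

    def test_planted_decay_slope_recovered_by_regression(self):
        """log of per-position mean |ddGa| regressed on distance gives k."""
        cfg = GeneratorConfig(
            n_positions=60,
            n_tiles=3,
            frac_allosteric=1.0,
            frac_activating=0.0,
            frac_core=0.0,
            decay_rate=-0.07,
            ddg_cap=1e9,  # uncapped so the planted law is exact
        )
        truth = generate_truth(cfg, seed=5)
        pos = sorted({m.position for m in truth.ddGa})
        d = np.array([truth.distance[p] for p in pos])
        mean_abs = np.array(
            [
                np.mean([abs(truth.ddGa[m]) for m in truth.ddGa if m.position == p])
                for p in pos
            ]
        )
        slope, _ = np.polyfit(d, np.log(mean_abs), 1)
        assert slope == pytest.approx(-0.07, abs=0.005)

    def test_noise_sd_positive(self):
        truth = generate_truth(GeneratorConfig(n_positions=20, n_tiles=2), seed=6)
        assert all(v > 0 for v in truth.noise_sd.values())


class TestGenerateLibrary:
    def test_single_tile_wt_background_combinatorics(self):
        cfg = GeneratorConfig(n_positions=10, n_tiles=1)
        truth = generate_truth(cfg, seed=1)
        genotypes = generate_library(truth, backgrounds_per_tile=1)
        orders = [g.order for g in genotypes]
        assert orders.count(0) == 1  # WT
        assert orders.count(1) == 190  # 10 positions x 19

    def test_every_single_in_every_background(self):
        cfg = GeneratorConfig(n_positions=10, n_tiles=1)
        truth = generate_truth(cfg, seed=1)
        genotypes = generate_library(truth, backgrounds_per_tile=2)
        bg = [g for g in genotypes if g.background_id != "WT"]
        # the non-WT background contributes doubles for every position
        # except its own, where substitutions replace it (other singles)
        doubles = [g for g in bg if g.order == 2]
        assert len({frozenset(g.mutations) for g in doubles}) == 9 * 19

    def test_background_single_yields_two_mutation_genotypes(self):
        cfg = GeneratorConfig(n_positions=10, n_tiles=1)
        truth = generate_truth(cfg, seed=1)
        m_bg = sorted(truth.ddGf, key=str)[0]
        genotypes = generate_library(truth, backgrounds=({1: [m_bg]}))
        doubles = [g for g in genotypes if g.order == 2]
        assert doubles and all(m_bg in g.mutations for g in doubles)

    def test_background_outside_tile_rejected(self):
        cfg = GeneratorConfig(n_positions=20, n_tiles=2)
        truth = generate_truth(cfg, seed=1)
        # a position-1 mutation is in tile 1, not tile 2
        m = next(m for m in truth.ddGf if m.position == 1)
        with pytest.raises(BackgroundError):
            generate_library(truth, backgrounds={2: [m]})

    def test_genotypes_unique_per_tile(self):
        cfg = GeneratorConfig(n_positions=20, n_tiles=2)
        truth = generate_truth(cfg, seed=1)
        genotypes = generate_library(truth, backgrounds_per_tile=4)
        keys = [(g.tile, frozenset(g.mutations)) for g in genotypes]
        assert len(keys) == len(set(keys))


class TestGenerateObservations:
    def test_noiseless_equals_model_prediction(self):
        from allomap.thermo import predict_fitness

        cfg = GeneratorConfig(n_positions=12, n_tiles=1, backgrounds_per_tile=3)
        truth = generate_truth(cfg, seed=2)
        genotypes = generate_library(truth, 3)
        obs = generate_observations(truth, genotypes, seed=0, noiseless=True)
        model = truth.to_energy_model()
        for o in obs[::17]:
            assert o.fitness == pytest.approx(
                predict_fitness(o.genotype, model, o.assay, o.block), abs=1e-12
            )

    def test_same_seed_identical_noise(self):
        cfg = GeneratorConfig(n_positions=12, n_tiles=1, backgrounds_per_tile=3)
        truth = generate_truth(cfg, seed=2)
        genotypes = generate_library(truth, 3)
        o1 = generate_observations(truth, genotypes, seed=9)
        o2 = generate_observations(truth, genotypes, seed=9)
        assert all(a.fitness == b.fitness for a, b in zip(o1, o2))

    def test_empirical_noise_sd_matches_configured(self):
        """Over ~10,000 draws the (observed - noiseless) sd is the set sd."""
        cfg = GeneratorConfig(n_positions=40, n_tiles=1, backgrounds_per_tile=7)
        truth = generate_truth(cfg, seed=3)
        genotypes = generate_library(truth, 7)
        clean = generate_observations(truth, genotypes, seed=0, noiseless=True)
        noisy = generate_observations(truth, genotypes, seed=11)
        resid = {}
        for c, n in zip(clean, noisy):
            resid.setdefault((n.assay, n.block), []).append(
                (n.fitness - c.fitness) / n.sigma
            )
        pooled = np.concatenate([np.asarray(v) for v in resid.values()])
        assert pooled.size >= 10000
        assert np.std(pooled) == pytest.approx(1.0, rel=0.03)

    def test_observation_count_structure(self):
        cfg = GeneratorConfig(n_positions=12, n_tiles=1, backgrounds_per_tile=3)
        truth = generate_truth(cfg, seed=2)
        genotypes = generate_library(truth, 3)
        obs = generate_observations(truth, genotypes, seed=0)
        assert len(obs) == 2 * len(genotypes)  # two assays per genotype
        assert all(o.sigma == truth.noise_sd[(o.assay, o.block)] for o in obs)


class TestGenerateStructure:
    def test_backbone_geometry(self):
        structure, active = generate_structure(60, seed=4)
        ca = np.array([r.ca for r in structure.residues])
        steps = np.linalg.norm(np.diff(ca, axis=0), axis=1)
        assert np.all((steps >= 3.0) & (steps <= 4.0))
        assert all(len(r.atoms) >= 4 for r in structure.residues)

    def test_active_site_is_a_tight_cluster(self):
        structure, active = generate_structure(60, seed=4)
        ca = {r.res_seq: r.ca for r in structure.residues}
        for i in active:
            for j in active:
                assert np.linalg.norm(ca[i] - ca[j]) < 12.0

    def test_seeded_determinism(self):
        s1, a1 = generate_structure(30, seed=8)
        s2, a2 = generate_structure(30, seed=8)
        assert a1 == a2
        np.testing.assert_array_equal(s1.residues[7].coords, s2.residues[7].coords)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            generate_structure(5, seed=0)


def test_generate_study_is_deterministic_and_consistent():
    cfg = GeneratorConfig(n_positions=20, n_tiles=2, backgrounds_per_tile=4)
    s1 = generate_study(cfg, seed=5)
    s2 = generate_study(cfg, seed=5)
    assert [o.fitness for o in s1.observations] == [o.fitness for o in s2.observations]
    # every genotype references mutations present in the truth
    for o in s1.observations:
        for m in o.genotype.mutations:
            assert m in s1.truth.ddGf and m in s1.truth.ddGa
    assert not s1.annotations.empty


def test_planted_decay_recovered_within_ci_across_seeds():
    """fit_exponential_decay recovers the generator's planted decay rate
    within its 95% CI in >= 90% of seeded replicates."""
    from allomap.spatial import fit_exponential_decay

    hits = 0
    for seed in range(20):
        cfg = GeneratorConfig(
            n_positions=60, n_tiles=3, frac_allosteric=0.6, frac_core=0.0,
            decay_rate=-0.07,
        )
        truth = generate_truth(cfg, seed=seed)
        pos = sorted({m.position for m, v in truth.ddGa.items() if v > 0})
        d = np.array([truth.distance[p] for p in pos])
        y = np.array(
            [np.mean([abs(truth.ddGa[m]) for m in truth.ddGa if m.position == p])
             for p in pos]
        )
        f = fit_exponential_decay(d, y)
        if f.rate - f.ci95_k <= -0.07 <= f.rate + f.ci95_k:
            hits += 1
    assert hits >= 18


def test_planted_dead_background_is_saturated_and_excludable():
    """The optional degenerate background has a much narrower fitness
    range than the others, and the fitter can drop it by id."""
    from allomap.fitting import fit as fit_model

    cfg = GeneratorConfig(
        n_positions=20, n_tiles=2, backgrounds_per_tile=5,
        plant_dead_background=True, noiseless=True,
    )
    study = generate_study(cfg, seed=2)
    truth = study.truth
    last_tile = len(truth.tile_bounds)
    ranges = {}
    for o in study.observations:
        if o.genotype.tile != last_tile:
            continue
        key = (o.genotype.background_id, o.assay)
        ranges.setdefault(key, []).append(o.fitness)
    spans = {k: max(v) - min(v) for k, v in ranges.items() if len(v) > 50}
    bgs = {bg for bg, _ in spans}
    # dead background: narrow range in BOTH assays simultaneously
    worst_span = {
        bg: max(spans[(bg, "activity")], spans[(bg, "abundance")]) for bg in bgs
    }
    dead = min(worst_span, key=worst_span.get)
    others = [v for bg, v in worst_span.items() if bg != dead]
    assert worst_span[dead] < 0.5 * float(np.median(others))
    fr = fit_model(study.observations, exclude_backgrounds=[dead],
                   record_trace=False)
    assert fr.n_obs < len(study.observations)
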