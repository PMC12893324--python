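"""Structure parsing, distances, decay fits and spatial tests."""

import math

import numpy as np
import pytest

from allomap.spatial import (
    DecayFit,
    PDBParseError,
    directional_decay,
    distance_corrected_effects,
    fit_exponential_decay,
    half_decay,
    matched_subsample_decay_test,
    min_distance_to_active_site,
    parse_pdb,
    site_clustering_test,
)
from allomap.synth import generate_structure

TWO_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.500   2.300   0.700  1.00  0.00           O
ATOM      5  H   ALA A   1       0.000   1.000   0.000  1.00  0.00           H
ATOM      6  N   GLY A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      7  CA AGLY A   2       4.000   2.700   0.000  1.00  0.00           C
ATOM      8  CA BGLY A   2       4.100   2.800   0.100  1.00  0.00           C
HETATM    9  PA  ANP A 401      10.000  10.000  10.000  1.00  0.00           P
HETATM   10  O1  HOH A 501      20.000  20.000  20.000  1.00  0.00           O
END
"""


class TestParsePDB:
    def test_minimal_fixture(self):
        s = parse_pdb(TWO_RES_PDB)
        assert len(s.residues) == 2
        # residue 1: N, CA, C, O retained; H dropped
        assert [a.name for a in s.residues[0].atoms] == ["N", "CA", "C", "O"]

    def test_altloc_a_only(self):
        s = parse_pdb(TWO_RES_PDB)
        gly = s.residues[1]
        cas = [a for a in gly.atoms if a.name == "CA"]
        assert len(cas) == 1 and cas[0].xyz[0] == pytest.approx(4.0)

    def test_hetatm_ligand_exposed_water_dropped(self):
        s = parse_pdb(TWO_RES_PDB)
        assert "ANP" in s.ligands and "HOH" not in s.ligands

    def test_malformed_record_reports_line(self):
        bad = "ATOM      1  CA  ALA A   1     bad-x   0.000   0.000\n"
        with pytest.raises(PDBParseError, match="line 1"):
            parse_pdb(bad)


class TestMinDistance:
    def test_euclidean_between_single_atoms(self):
        pdb = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  ALA A   2       3.000   4.000   0.000  1.00  0.00           C\n"
        )
        s = parse_pdb(pdb)
        d = min_distance_to_active_site(s, [("residue", 1)])
        assert d[2] == pytest.approx(5.0)

    def test_reference_residue_distance_zero(self):
        s, active = generate_structure(30, seed=1)
        d = min_distance_to_active_site(s, [("residue", r) for r in active])
        assert all(d[r] == 0.0 for r in active)

    def test_matches_brute_force(self):
        s, active = generate_structure(25, seed=2)
        refs = [("residue", r) for r in active]
        d = min_distance_to_active_site(s, refs)
        ref_xyz = np.vstack([s.residue(r).coords for r in active])
        for res in s.residues:
            if res.res_seq in active:
                continue
            brute = min(
                math.dist(a.xyz, tuple(rx)) for a in res.atoms for rx in ref_xyz
            )
            assert d[res.res_seq] == pytest.approx(brute, abs=1e-9)

    def test_missing_reference_named(self):
        s, _ = generate_structure(20, seed=3)
        with pytest.raises(KeyError, match="999"):
            min_distance_to_active_site(s, [("residue", 999)])

    def test_rigid_motion_invariance(self):
        s, active = generate_structure(25, seed=4)
        refs = [("residue", r) for r in active]
        d1 = min_distance_to_active_site(s, refs)
        # a rotation about z plus a translation
        th = 0.7
        rot = np.array(
            [
                [math.cos(th), -math.sin(th), 0],
                [math.sin(th), math.cos(th), 0],
                [0, 0, 1],
            ]
        )
        d2 = min_distance_to_active_site(s.transformed(rot, np.array([5.0, -3.0, 11.0])), refs)
        for r in d1:
            assert d1[r] == pytest.approx(d2[r], abs=1e-9)


class TestExponentialDecay:
    def test_noiseless_exact(self):
        d = np.linspace(0, 40, 60)
        y = 2.5 * np.exp(-0.07 * d)
        f = fit_exponential_decay(d, y)
        assert f.amplitude == pytest.approx(2.5, abs=1e-6)
        assert f.rate == pytest.approx(-0.07, abs=1e-6)

    def test_constant_y_flat_fit(self):
        d = np.linspace(0, 30, 40)
        f = fit_exponential_decay(d, np.full(40, 1.3))
        assert abs(f.rate) < 1e-8
        assert not np.isfinite(f.d_half) or f.d_half > 1e6

    def test_d_half_identity_on_every_fit(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            d = np.sort(rng.uniform(0, 30, 50))
            y = rng.uniform(0.5, 3) * np.exp(rng.uniform(-0.2, -0.02) * d)
            f = fit_exponential_decay(d, y)
            assert abs(f.d_half * abs(f.rate) - math.log(2)) < 1e-12

    def test_ci_coverage_in_simulation(self):
        """95% CI contains the planted rate in >= 90% of 20 replicates."""
        rng = np.random.default_rng(7)
        a, k, n, sd = 2.0, -0.06, 250, 0.05
        hits = 0
        for _ in range(20):
            d = rng.uniform(0, 30, n)
            y = np.clip(a * np.exp(k * d) + rng.normal(0, sd, n), 0, None)
            f = fit_exponential_decay(d, y)
            if f.rate - f.ci95_k <= k <= f.rate + f.ci95_k:
                hits += 1
        assert hits >= 18

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_exponential_decay([0, 1], [1, 0.5])


class TestHalfDecay:
    @pytest.mark.parametrize(
        "k,expected",
        [
            (-0.038, 18.24),
            (-0.035, 19.80),
            (-0.045, 15.40),
            (-0.074, 9.37),
            (-0.215, 3.22),
            (-0.6931, 1.00),
        ],
    )
    def test_printed_pairs(self, k, expected):
        assert half_decay(k) == pytest.approx(expected, abs=0.005)

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            half_decay(0.0)


def _isotropic_field(structure, active, a=2.0, k=-0.07):
    from allomap.spatial import min_distance_to_active_site

    d = min_distance_to_active_site(structure, [("residue", r) for r in active])
    return {r: a * math.exp(k * v) for r, v in d.items()}


class TestDirectionalDecay:
    def test_isotropic_field_similar_rates(self, structure100):
        structure, active = structure100
        refs = [("residue", r) for r in active]
        effects = _isotropic_field(structure, active)
        fits = {}
        for axis in "xyz":
            for sign in "+-":
                try:
                    fits[axis + sign] = directional_decay(
                        structure, effects, refs, axis, sign, slab=12.0
                    )
                except ValueError:
                    pass
        assert len(fits) >= 4
        rates = np.array([f.rate for f in fits.values()])
        cis = np.array([f.ci95_k for f in fits.values()])
        # every pair of directional estimates overlaps within joint CIs
        for i in range(len(rates)):
            for j in range(len(rates)):
                assert abs(rates[i] - rates[j]) <= cis[i] + cis[j] + 0.02

    def test_planted_anisotropy_detected(self, structure100):
        structure, active = structure100
        refs = [("residue", r) for r in active]
        ref_xyz = np.vstack([structure.residue(r).coords for r in active])
        origin = ref_xyz.mean(axis=0)
        effects = {}
        for res in structure.residues:
            dx, dy, dz = np.abs(res.coords.mean(axis=0) - origin)
            effects[res.res_seq] = 2.0 * math.exp(-0.25 * dx - 0.02 * dy - 0.02 * dz)
        k_fast = directional_decay(structure, effects, refs, "x", None, slab=8.0).rate
        k_y = directional_decay(structure, effects, refs, "y", None, slab=8.0).rate
        k_z = directional_decay(structure, effects, refs, "z", None, slab=8.0).rate
        assert abs(k_fast) > abs(k_y) and abs(k_fast) > abs(k_z)

    def test_infinite_slab_reproduces_global_fit(self, structure100):
        structure, active = structure100
        refs = [("residue", r) for r in active]
        effects = _isotropic_field(structure, active)
        ref_xyz = np.vstack([structure.residue(r).coords for r in active])
        origin = ref_xyz.mean(axis=0)
        got = directional_decay(structure, effects, refs, "x", None, slab=np.inf)
        dx = [abs(r.coords.mean(axis=0)[0] - origin[0]) for r in structure.residues]
        y = [effects[r.res_seq] for r in structure.residues]
        expected = fit_exponential_decay(dx, y)
        assert got.rate == pytest.approx(expected.rate, abs=1e-12)
        assert got.n_points == expected.n_points


class TestMatchedSubsampling:
    def test_exchangeable_sets_give_half_on_average(self):
        """When 'activating' is just a relabelled random subsample of the
        inactivating set, p is uniform; its mean over draws is 0.5."""
        rng = np.random.default_rng(2)
        n_in = 800
        d_in = rng.uniform(0, 30, n_in)
        y_in = np.abs(rng.normal(1.0, 0.4, n_in)) * np.exp(-0.05 * d_in)
        ps = []
        for rep in range(60):
            pick = rng.choice(n_in, 80, replace=False)
            p, _ = matched_subsample_decay_test(
                (d_in, y_in), (d_in[pick], -y_in[pick]), n_subsamples=200, seed=rep
            )
            ps.append(p)
        assert abs(np.mean(ps) - 0.5) <= 0.08

    def test_flat_activating_vs_decaying_inactivating(self):
        rng = np.random.default_rng(3)
        d_in = rng.uniform(0, 30, 900)
        y_in = np.abs(rng.normal(0, 0.2, 900)) + 1.5 * np.exp(-0.12 * d_in)
        d_ac = rng.uniform(0, 30, 90)
        y_ac = -(np.abs(rng.normal(0, 0.2, 90)) + 0.75)  # distance-flat
        p, med_k = matched_subsample_decay_test(
            (d_in, y_in), (d_ac, y_ac), n_subsamples=400, seed=0
        )
        assert p <= 0.01
        assert med_k < 0

    def test_seeded_determinism(self):
        rng = np.random.default_rng(4)
        d_in, y_in = rng.uniform(0, 30, 300), np.abs(rng.normal(1, 0.3, 300))
        d_ac, y_ac = rng.uniform(0, 30, 40), -np.abs(rng.normal(1, 0.3, 40))
        r1 = matched_subsample_decay_test((d_in, y_in), (d_ac, y_ac), 200, seed=5)
        r2 = matched_subsample_decay_test((d_in, y_in), (d_ac, y_ac), 200, seed=5)
        assert r1 == r2

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            matched_subsample_decay_test((np.array([]), np.array([])), (np.ones(3), np.ones(3)))


class TestSiteClustering:
    def test_all_residues_gives_p_one(self, structure100):
        structure, _ = structure100
        p = site_clustering_test(structure.res_seqs, structure, n_random=50, seed=0)
        assert p == 1.0

    def test_tight_cluster_significant(self, structure100):
        structure, _ = structure100
        ca = structure.ca_coords()
        center = structure.residues[40].ca
        sites = sorted(
            structure.res_seqs, key=lambda r: float(np.linalg.norm(ca[r] - center))
        )[:8]
        for mode in ("pairwise", "connectivity"):
            p = site_clustering_test(sites, structure, n_random=200, mode=mode, seed=1)
            assert p <= 0.01

    def test_missing_site_rejected(self, structure100):
        structure, _ = structure100
        with pytest.raises(KeyError):
            site_clustering_test([1, 99999], structure)


class TestDistanceCorrection:
    def test_exponential_trend_removed(self):
        rng = np.random.default_rng(5)
        d = np.sort(rng.uniform(0, 30, 300))
        y = 2.0 * np.exp(-0.08 * d)
        resid = distance_corrected_effects(d, y, span=0.3)
        for dec in np.array_split(np.arange(300), 10):
            assert abs(np.median(resid[dec])) < 0.02

    def test_planted_group_offset_detected(self):
        rng = np.random.default_rng(6)
        d = np.sort(rng.uniform(0, 30, 400))
        y = 2.0 * np.exp(-0.08 * d) + rng.normal(0, 0.02, 400)
        group = rng.random(400) < 0.3
        y[group] -= 0.3
        resid = distance_corrected_effects(d, y, span=0.5)
        assert np.median(resid[group]) < np.median(resid[~group]) - 0.1

    def test_span_validated(self):
        with pytest.raises(ValueError):
            distance_corrected_effects(np.arange(20.0), np.arange(20.0), span=1.5)
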