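"""Angles, state classification, PMFs, non-bonded energies, Metropolis ddG."""

import math

import numpy as np
import pytest

from foldsense import conformation as conf
from foldsense import synthetic_data as sd
from foldsense.errors import ConvergenceError, MissingAtomsError, ParameterError

KT = conf.KT_298


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _ideal_helix(n=12):
    t = np.arange(n)
    return np.column_stack([
        2.3 * np.cos(np.radians(100) * t),
        2.3 * np.sin(np.radians(100) * t),
        1.5 * t,
    ])


class TestHelixAxis:
    def test_ideal_helix_along_z(self):
        axis = conf.helix_axis(_ideal_helix())
        assert axis[2] == pytest.approx(1.0, abs=1e-3)

    def test_rotation_equivariance(self):
        from scipy.spatial.transform import Rotation

        coords = _ideal_helix()
        rot = Rotation.from_euler("xyz", [30, -50, 110], degrees=True)
        a1 = rot.apply(conf.helix_axis(coords))
        a2 = conf.helix_axis(rot.apply(coords))
        np.testing.assert_allclose(a1, a2, atol=1e-9)

    def test_matches_brute_force_eigenvector(self):
        rng = np.random.default_rng(5)
        coords = rng.normal(size=(40, 3)) * np.array([1.0, 2.0, 6.0])
        axis = conf.helix_axis(coords)
        cov = np.cov((coords - coords.mean(0)).T)
        evals, evecs = np.linalg.eigh(cov)
        lead = evecs[:, np.argmax(evals)]
        assert abs(abs(np.dot(axis, lead)) - 1.0) < 1e-9

    def test_too_few_points_rejected(self):
        with pytest.raises(ParameterError):
            conf.helix_axis(np.zeros((3, 3)))


class TestSidechainAngle:
    @pytest.mark.parametrize("angle", [0.0, 90.0, 100.0, 180.0])
    def test_configured_angle_recovered(self, angle):
        atoms = sd.make_toy_complex(angle, include_partner=False)
        rid = atoms.res_id[atoms.atom_name == "TIP"][0]
        assert conf.sidechain_angle(atoms, rid) == pytest.approx(angle, abs=0.5)

    def test_trp_ring_centroid_rule(self):
        """A tryptophan-style residue uses the six-membered-ring centroid."""
        import biotite.structure as struc

        helix = _ideal_helix()
        ring_names = conf.TIP_RULES["TRP"]
        anchor = helix[5]
        centroid = anchor + np.array([3.0, 0.0, 0.0])  # perpendicular to z
        n = len(helix) + 1 + len(ring_names)
        arr = struc.AtomArray(n)
        for i, pos in enumerate(helix):
            arr.atom_name[i] = "CA"
            arr.res_name[i] = "ALA"
            arr.res_id[i] = i + 1
            arr.coord[i] = pos
        base = len(helix)
        arr.atom_name[base] = "CA"
        arr.res_name[base] = "TRP"
        arr.res_id[base] = 6
        arr.coord[base] = anchor
        rng = np.random.default_rng(0)
        offsets = rng.normal(0, 0.8, size=(len(ring_names), 3))
        offsets -= offsets.mean(axis=0)  # centroid exactly at target
        for j, name in enumerate(ring_names):
            arr.atom_name[base + 1 + j] = name
            arr.res_name[base + 1 + j] = "TRP"
            arr.res_id[base + 1 + j] = 6
            arr.coord[base + 1 + j] = centroid + offsets[j]
        # helix CA of residue 6 duplicates res_id, drop original helix row 5
        arr = arr[np.arange(n) != 5]
        assert conf.sidechain_angle(arr, 6) == pytest.approx(90.0, abs=0.5)

    def test_missing_tip_atoms_listed(self):
        atoms = sd.make_toy_complex("N", include_partner=False)
        rid = atoms.res_id[atoms.atom_name == "TIP"][0]
        with pytest.raises(MissingAtomsError, match="CZ"):
            conf.sidechain_angle(atoms, rid, tip_rule=("CZ",))


# ---------------------------------------------------------------------------
# state classification
# ---------------------------------------------------------------------------

class TestClassifyStates:
    def test_population_counting_with_explicit_boundary(self):
        theta = np.concatenate([np.full(966, 100.0), np.full(34, 40.0)])
        st = conf.classify_states(
            conf.AngleTrajectory(theta), boundaries=75.0
        )
        assert st.populations == {"T": 0.034, "N": 0.966}
        assert abs(sum(st.populations.values()) - 1.0) < 1e-12

    def test_single_state_has_zero_transitions(self):
        st = conf.classify_states(
            conf.AngleTrajectory(np.full(100, 100.0)), boundaries=75.0
        )
        assert st.n_transitions == 0
        assert math.isnan(st.mean_dwell["T"])

    def test_alternating_states_maximal_transitions(self):
        theta = np.tile([100.0, 40.0], 50)
        st = conf.classify_states(conf.AngleTrajectory(theta), boundaries=75.0)
        assert st.n_transitions == theta.size - 1

    def test_label_swap_is_exact_permutation(self):
        rng = np.random.default_rng(2)
        theta = rng.uniform(0, 180, 5000)
        a = conf.classify_states(conf.AngleTrajectory(theta), boundaries=80.0)
        b = conf.classify_states(
            conf.AngleTrajectory(theta), boundaries=80.0, t_below=False
        )
        assert a.populations["T"] == b.populations["N"]
        assert a.n_transitions == b.n_transitions

    def test_auto_boundary_splits_two_wells(self):
        rng = np.random.default_rng(3)
        theta = np.concatenate([
            rng.normal(40, 6, 4000), rng.normal(100, 6, 6000)
        ]).clip(0, 180)
        rng.shuffle(theta)
        st = conf.classify_states(conf.AngleTrajectory(theta), boundaries="auto")
        assert 55 < st.boundary < 85
        assert st.populations["T"] == pytest.approx(0.4, abs=0.02)

    def test_auto_single_well_suggests_explicit(self):
        rng = np.random.default_rng(4)
        theta = rng.normal(90, 5, 5000).clip(0, 180)
        with pytest.raises(ParameterError, match="explicit"):
            conf.classify_states(conf.AngleTrajectory(theta), boundaries="auto")


# ---------------------------------------------------------------------------
# PMFs
# ---------------------------------------------------------------------------

class TestPmfBoltzmann:
    def test_two_bin_free_energy_difference(self):
        theta = np.concatenate([np.full(900, 45.0), np.full(100, 135.0)])
        pmf = conf.pmf_boltzmann(conf.AngleTrajectory(theta), bins=2, kT=0.5925)
        delta = pmf.free_energy[1] - pmf.free_energy[0]
        assert delta == pytest.approx(-0.5925 * math.log(100 / 900), rel=1e-12)
        assert np.nanmin(pmf.free_energy) == 0.0

    def test_uniform_samples_give_flat_pmf(self):
        rng = np.random.default_rng(6)
        theta = rng.uniform(0, 180, 100_000)
        pmf = conf.pmf_boltzmann(conf.AngleTrajectory(theta), bins=18)
        # multinomial bound: dF ~ kT * dp/p, 3 sigma ~ 3 kT sqrt(bins/n)
        bound = 4 * 3 * KT * math.sqrt(18 / 100_000)
        assert np.nanmax(pmf.free_energy) < bound

    def test_unvisited_bins_marked_undefined_not_zero(self):
        theta = np.full(1000, 100.0)
        pmf = conf.pmf_boltzmann(conf.AngleTrajectory(theta), bins=36)
        assert (~pmf.defined).sum() == 35
        assert np.all(np.isnan(pmf.free_energy[~pmf.defined]))

    def test_sampling_error_shrinks_with_n(self):
        """Sup-norm error of the inverted PMF decreases ~ n^-1/2 for samples
        drawn exactly from a known density."""
        pot = sd.DoubleWellPotential.w344r_preset()
        grid = np.linspace(0, 180, 14401)
        w = np.exp(-pot(grid) / KT)
        p = w / w.sum()
        f_exact = None
        errs = {}
        for n in (10**3, 10**4, 10**5):
            rng = np.random.default_rng(100 + n)
            theta = rng.choice(grid, size=n, p=p)
            pmf = conf.pmf_boltzmann(conf.AngleTrajectory(theta), bins=18)
            if f_exact is None:
                edges = np.linspace(0, 180, 19)
                pb = np.array([
                    p[(grid >= lo) & (grid < hi)].sum()
                    for lo, hi in zip(edges[:-1], edges[1:])
                ])
                f_exact = -KT * np.log(np.where(pb > 1e-3, pb, np.nan))
                f_exact -= np.nanmin(f_exact)
            # compare over well-populated bins; rare-bin noise dominates the
            # sup norm otherwise
            common = pmf.defined & np.isfinite(f_exact)
            errs[n] = np.nanmax(np.abs(pmf.free_energy - f_exact)[common])
        assert errs[10**5] < errs[10**3]

    def test_all_samples_outside_range_rejected(self):
        with pytest.raises(ParameterError):
            conf.pmf_boltzmann(
                conf.AngleTrajectory(np.full(10, 170.0)), bins=4,
                angle_range=(0.0, 90.0),
            )


class TestPmfWham:
    def test_single_unbiased_window_equals_boltzmann_inversion(self):
        pot = sd.DoubleWellPotential.w344r_preset()
        traj = sd.simulate_double_well_trajectory(
            pot, n_steps=20_000, theta0=40.0, seed=31
        )
        wham = conf.pmf_wham([conf.UmbrellaWindow(traj, 90.0, 0.0)], bins=36)
        boltz = conf.pmf_boltzmann(traj, bins=36)
        np.testing.assert_array_equal(wham.defined, boltz.defined)
        assert np.nanmax(np.abs(wham.free_energy - boltz.free_energy)) <= 1e-10

    def test_window_order_invariance(self):
        pot = sd.DoubleWellPotential.w344r_preset()
        windows = sd.simulate_umbrella_windows(
            pot, np.linspace(20, 160, 15), 0.05, n_steps=2000, seed=32
        )
        f1 = conf.pmf_wham(windows, bins=30).free_energy
        f2 = conf.pmf_wham(windows[::-1], bins=30).free_energy
        np.testing.assert_allclose(f1, f2, atol=1e-9)

    def test_harmonic_potential_curvature_recovered(self):
        """Umbrella windows on a harmonic base potential recover the analytic
        quadratic PMF curvature within 5%."""
        base = sd.HarmonicPotential(center=90.0, k=0.01)
        # coarse dt decorrelates the window samples; at dt = 0.05 the
        # in-window relaxation time (~700 steps) starves the fit
        windows = sd.simulate_umbrella_windows(
            base, np.linspace(40, 140, 9), 0.02, dt=0.25, n_steps=100_000,
            seed=33,
        )
        pmf = conf.pmf_wham(windows, bins=45)
        ok = pmf.defined & (np.abs(pmf.bin_centers - 90.0) < 35.0)
        coeffs = np.polyfit(pmf.bin_centers[ok], pmf.free_energy[ok], 2)
        assert 2 * coeffs[0] == pytest.approx(0.01, rel=0.05)

    def test_double_well_depth_difference_matches_quadrature(self):
        """The WHAM well-depth difference agrees with direct Boltzmann
        quadrature of the landscape within 3 standard errors (estimated over
        independent repeats)."""
        pot = sd.DoubleWellPotential.w344r_preset()
        edges = np.linspace(0, 180, 37)
        grid = np.linspace(0, 180, 14401)
        w = np.exp(-pot(grid) / KT)
        pb = np.array([
            np.trapezoid(np.where((grid >= lo) & (grid < hi), w, 0.0), grid)
            for lo, hi in zip(edges[:-1], edges[1:])
        ])
        f_oracle = -KT * np.log(pb / pb.sum())
        centers = 0.5 * (edges[:-1] + edges[1:])
        below = centers < pot.theta_barrier
        oracle_diff = f_oracle[below].min() - f_oracle[~below].min()

        diffs = []
        for rep in range(5):
            windows = sd.simulate_umbrella_windows(
                pot, np.linspace(10, 170, 22), 0.05, n_steps=8000,
                seed=40 + rep,
            )
            pmf = conf.pmf_wham(windows, bins=36)
            diffs.append(pmf.well_depth_difference(pot.theta_barrier))
        mean = np.mean(diffs)
        sem = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
        assert abs(mean - oracle_diff) < 3 * sem + 0.02

    def test_nonconvergence_raises(self):
        pot = sd.DoubleWellPotential.w344r_preset()
        traj = sd.simulate_double_well_trajectory(
            pot, n_steps=2000, theta0=40.0, seed=35
        )
        with pytest.raises(ConvergenceError):
            conf.pmf_wham(
                [conf.UmbrellaWindow(traj, 40.0, 0.05),
                 conf.UmbrellaWindow(traj, 100.0, 0.05)],
                bins=36, max_iter=1,
            )


# ---------------------------------------------------------------------------
# non-bonded energies
# ---------------------------------------------------------------------------

def _params(q, eps, rmin_half):
    return conf.AtomParameters(np.atleast_1d(q), np.atleast_1d(eps),
                               np.atleast_1d(rmin_half))


class TestNonbondedEnergy:
    def test_beyond_cutoff_is_zero(self):
        e = conf.nonbonded_energy(
            np.array([[0.0, 0, 0]]), np.array([[13.0, 0, 0]]),
            _params(1.0, 0.1, 2.0), _params(1.0, 0.1, 2.0),
        )
        assert e == 0.0

    def test_coulomb_constant(self):
        """Unit charges at 3.320636 A give exactly 100 kcal/mol."""
        e = conf.nonbonded_energy(
            np.array([[0.0, 0, 0]]), np.array([[3.320636, 0, 0]]),
            _params(1.0, 0.0, 1.0), _params(1.0, 0.0, 1.0),
        )
        assert e == pytest.approx(100.0, rel=1e-9)

    def test_lj_minimum(self):
        e = conf.nonbonded_energy(
            np.array([[0.0, 0, 0]]), np.array([[4.0, 0, 0]]),
            _params(0.0, 0.2, 2.0), _params(0.0, 0.2, 2.0),
        )
        assert e == pytest.approx(-0.2, rel=1e-12)

    def test_symmetric_and_matches_brute_force(self):
        rng = np.random.default_rng(7)
        ca = rng.uniform(0, 15, size=(40, 3))
        cb = rng.uniform(5, 20, size=(50, 3))
        pa = _params(rng.uniform(-0.5, 0.5, 40), rng.uniform(0.05, 0.2, 40),
                     rng.uniform(1.5, 2.2, 40))
        pb = _params(rng.uniform(-0.5, 0.5, 50), rng.uniform(0.05, 0.2, 50),
                     rng.uniform(1.5, 2.2, 50))
        opts = conf.NonbondedParams(cutoff=12.0, dielectric=2.0)
        e = conf.nonbonded_energy(ca, cb, pa, pb, opts)
        e_swapped = conf.nonbonded_energy(cb, ca, pb, pa, opts)
        brute = 0.0
        for i in range(40):
            for j in range(50):
                r = np.linalg.norm(ca[i] - cb[j])
                if r > 12.0:
                    continue
                eps = math.sqrt(pa.epsilon[i] * pb.epsilon[j])
                rmin = pa.rmin_half[i] + pb.rmin_half[j]
                brute += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
                brute += 332.0636 * pa.charge[i] * pb.charge[j] / (2.0 * r)
        assert e == pytest.approx(brute, rel=1e-10)
        assert e_swapped == pytest.approx(e, rel=1e-12)

    def test_overlapping_atoms_rejected(self):
        with pytest.raises(ParameterError, match="overlap"):
            conf.nonbonded_energy(
                np.array([[0.0, 0, 0]]), np.array([[0.05, 0, 0]]),
                _params(0.0, 0.1, 2.0), _params(0.0, 0.1, 2.0),
            )

    def test_missing_parameters_listed(self):
        with pytest.raises(MissingAtomsError, match="XX"):
            conf.AtomParameters.from_table(["CA", "XX"], {"CA": (0.0, 0.1, 2.0)})


class TestAverageSnapshotEnergy:
    def test_identical_snapshots_zero_sd(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[4.0, 0, 0]])
        pairs = [(a, b)] * 5
        mean, sdev = conf.average_snapshot_energy(
            pairs, _params(0.0, 0.2, 2.0), _params(0.0, 0.2, 2.0)
        )
        assert mean == pytest.approx(-0.2, rel=1e-12)
        assert sdev == 0.0

    def test_mean_matches_direct_loop(self):
        rng = np.random.default_rng(8)
        pa = _params(rng.uniform(-0.3, 0.3, 5), rng.uniform(0.05, 0.2, 5),
                     rng.uniform(1.5, 2.0, 5))
        pb = _params(rng.uniform(-0.3, 0.3, 6), rng.uniform(0.05, 0.2, 6),
                     rng.uniform(1.5, 2.0, 6))
        pairs = [
            (rng.uniform(0, 8, (5, 3)), rng.uniform(4, 12, (6, 3)))
            for _ in range(4)
        ]
        mean, _ = conf.average_snapshot_energy(pairs, pa, pb)
        direct = np.mean([
            conf.nonbonded_energy(a, b, pa, pb) for a, b in pairs
        ])
        assert mean == pytest.approx(direct, rel=1e-12)


# ---------------------------------------------------------------------------
# Metropolis ensemble ddG
# ---------------------------------------------------------------------------

class TestMetropolisDdg:
    def test_acceptance_rate_for_unit_uphill_move(self):
        """Forced uphill moves of dE = kT accept at rate 1/e (binomial 3 sigma
        at 1e5 trials)."""
        rng = np.random.default_rng(9)
        n = 100_000
        accepted = sum(
            conf.metropolis_accept(1.2, 1.2, u) for u in rng.random(n)
        )
        p = math.exp(-1.0)
        assert abs(accepted / n - p) < 3 * math.sqrt(p * (1 - p) / n)

    def test_identical_models_matched_seeds_give_exactly_zero(self):
        model = conf.ToyBindingModel(sd.DoubleWellPotential.wt_preset())
        res = conf.metropolis_ensemble_ddg(
            model, model, n_runs=4, n_moves=2000, seed=51
        )
        assert res.ddg == 0.0
        assert res.ddg == res.dg_mut - res.dg_wt

    def test_more_favorable_mutant_interaction_gives_negative_ddg(self):
        """With the mutant's bound-state term more favorable, ddG < 0 under
        the convention that positive ddG means stronger WT binding."""
        wt = conf.ToyBindingModel(
            sd.DoubleWellPotential.wt_preset(),
            interaction_n=-20.0, interaction_t=-10.0,
        )
        mut = conf.ToyBindingModel(
            sd.DoubleWellPotential.w344r_preset(),
            interaction_n=-76.0, interaction_t=-16.0,
        )
        res = conf.metropolis_ensemble_ddg(
            wt, mut, n_runs=6, n_moves=3000, seed=52
        )
        assert res.ddg < 0.0

    def test_ddg_is_difference_of_run_means(self):
        wt = conf.ToyBindingModel(sd.DoubleWellPotential.wt_preset())
        mut = conf.ToyBindingModel(
            sd.DoubleWellPotential.w344r_preset(), interaction_n=-30.0
        )
        res = conf.metropolis_ensemble_ddg(
            wt, mut, n_runs=5, n_moves=1000, seed=53
        )
        assert res.ddg == pytest.approx(
            res.dg_mut_runs.mean() - res.dg_wt_runs.mean(), abs=1e-12
        )

    def test_quadratic_energy_reproduces_boltzmann_variance(self):
        """A Metropolis chain on E = k x^2 / 2 equilibrates to variance
        kT_mc / k within 5% at 1e6 moves."""
        k_spring, kt = 1.0, 1.2
        rng = np.random.default_rng(10)
        n = 1_000_000
        prop = rng.uniform(-2.5, 2.5, n)
        uni = rng.random(n)
        x = 0.0
        xs = np.empty(n)
        for m in range(n):
            new = x + prop[m]
            de = 0.5 * k_spring * (new * new - x * x)
            if de <= 0.0 or uni[m] < math.exp(-de / kt):
                x = new
            xs[m] = x
        assert np.var(xs[10_000:]) == pytest.approx(kt / k_spring, rel=0.05)

    def test_invalid_temperature_rejected(self):
        model = conf.ToyBindingModel(sd.DoubleWellPotential.wt_preset())
        with pytest.raises(ParameterError):
            conf.metropolis_ensemble_ddg(
                model, model, n_runs=2, n_moves=10, kT_mc=0.0, seed=1
            )
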