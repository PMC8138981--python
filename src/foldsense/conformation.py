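"""Side-chain orientation analysis and free-energy estimation.

This module quantifies the two-state behaviour of a side chain relative to
its helix: the inclination angle theta between the helix axis and the
C-alpha-to-tip vector, classification of frames into native-like (N) and
tilted (T) orientations, potentials of mean force by direct Boltzmann
inversion and by WHAM over umbrella windows, pairwise non-bonded
(Lennard-Jones + Coulomb) interaction energies with a plain distance cutoff,
and an ensemble Metropolis protocol that estimates a binding delta-delta-G as
ddG = mean(dG_mutant runs) - mean(dG_wt runs); under this sign convention a
positive ddG means the wild type binds more strongly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.spatial.distance import cdist

from .errors import ConvergenceError, MissingAtomsError, ParameterError

#: kT in kcal/mol at 298 K.
KT_298 = 0.5925

#: Coulomb constant in kcal/mol * Angstrom / e^2.
COULOMB_K = 332.0636


# ---------------------------------------------------------------------------
# Trajectories and state assignment
# ---------------------------------------------------------------------------

@dataclass
class AngleTrajectory:
    """Time series of the helix-axis / side-chain inclination angle.

    ``theta`` is in degrees, constrained to [0, 180] (an inclination between
    two vectors, not a periodic dihedral).  ``dt`` is the time per frame in
    arbitrary units.
    """

    theta: np.ndarray
    dt: float = 1.0
    provenance: str = "simulated"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size == 0:
            raise ParameterError("trajectory is empty")
        if not np.all(np.isfinite(self.theta)):
            raise ParameterError("trajectory contains non-finite angles")
        if self.theta.min() < 0.0 or self.theta.max() > 180.0:
            raise ParameterError("angles must lie in [0, 180] degrees")

    def __len__(self) -> int:
        return self.theta.size


@dataclass
class UmbrellaWindow:
    """One umbrella-sampling window: a biased trajectory plus its bias."""

    trajectory: AngleTrajectory
    center: float
    spring_k: float  # kcal/mol/deg^2


@dataclass
class StateAssignment:
    """Per-frame N/T labels with populations, transitions and dwell times."""

    labels: np.ndarray  # array of "N"/"T"
    boundary: float
    populations: dict
    n_transitions: int
    mean_dwell: dict  # state -> mean dwell time (trajectory time units)


def classify_states(
    traj: AngleTrajectory,
    boundaries: float | str = "auto",
    *,
    t_below: bool = True,
    nbins: int = 90,
    smooth_sigma: float = 2.0,
) -> StateAssignment:
    """Assign each frame to the N or T orientation.

    With ``boundaries="auto"`` the angle histogram is smoothed, the two
    highest modes located, and the split placed at the intervening minimum
    (equivalently the maximum of -log(hist) between the two deepest minima).
    An explicit float places the boundary directly.  ``t_below`` selects which
    side is the tilted state (default: T at smaller angles).
    """
    theta = traj.theta
    if isinstance(boundaries, str):
        if boundaries != "auto":
            raise ParameterError(f"unknown boundary mode {boundaries!r}")
        counts, edges = np.histogram(theta, bins=nbins, range=(0.0, 180.0))
        smooth = gaussian_filter1d(counts.astype(float), smooth_sigma)
        peaks, props = find_peaks(smooth, prominence=smooth.max() * 0.01)
        if peaks.size < 2:
            raise ParameterError(
                "auto mode found fewer than 2 wells; supply an explicit boundary"
            )
        top2 = np.sort(peaks[np.argsort(smooth[peaks])[-2:]])
        split_bin = top2[0] + int(np.argmin(smooth[top2[0]: top2[1] + 1]))
        boundary = 0.5 * (edges[split_bin] + edges[split_bin + 1])
    else:
        boundary = float(boundaries)

    is_t = theta < boundary if t_below else theta >= boundary
    labels = np.where(is_t, "T", "N")
    n = labels.size
    count_t = int(is_t.sum())
    populations = {"T": count_t / n, "N": (n - count_t) / n}
    changes = labels[1:] != labels[:-1]
    n_transitions = int(changes.sum())
    mean_dwell = {}
    run_starts = np.flatnonzero(np.concatenate(([True], changes)))
    run_lengths = np.diff(np.concatenate((run_starts, [labels.size])))
    run_labels = labels[run_starts]
    for state in ("N", "T"):
        mask = run_labels == state
        mean_dwell[state] = (
            float(run_lengths[mask].mean() * traj.dt) if mask.any() else math.nan
        )
    return StateAssignment(labels, boundary, populations, n_transitions, mean_dwell)


# ---------------------------------------------------------------------------
# Potentials of mean force
# ---------------------------------------------------------------------------

@dataclass
class PMF:
    """Free-energy profile F(theta), min-shifted to zero over defined bins.

    Bins never visited have no defined free energy and are reported as NaN
    with ``defined`` False, never as zero.
    """

    bin_centers: np.ndarray
    free_energy: np.ndarray  # kcal/mol, NaN where undefined
    defined: np.ndarray
    kT: float
    method: str

    def well_depth_difference(self, boundary: float) -> float:
        """F difference between the minima below and above ``boundary``."""
        below = self.defined & (self.bin_centers < boundary)
        above = self.defined & (self.bin_centers >= boundary)
        if not below.any() or not above.any():
            raise ParameterError("no defined bins on one side of the boundary")
        return float(
            np.nanmin(self.free_energy[below]) - np.nanmin(self.free_energy[above])
        )


def pmf_boltzmann(
    traj: AngleTrajectory,
    bins: int = 36,
    kT: float = KT_298,
    angle_range: tuple[float, float] = (0.0, 180.0),
) -> PMF:
    """Potential of mean force by direct Boltzmann inversion, F = -kT ln p."""
    counts, edges = np.histogram(traj.theta, bins=bins, range=angle_range)
    if counts.sum() == 0:
        raise ParameterError("no samples fall inside the requested range")
    centers = 0.5 * (edges[:-1] + edges[1:])
    defined = counts > 0
    p = counts / counts.sum()
    f = np.full(centers.shape, np.nan)
    f[defined] = -kT * np.log(p[defined])
    f[defined] -= f[defined].min()
    return PMF(centers, f, defined, kT, "boltzmann_inversion")


def pmf_wham(
    windows: list[UmbrellaWindow],
    bins: int = 36,
    kT: float = KT_298,
    *,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    angle_range: tuple[float, float] = (0.0, 180.0),
) -> PMF:
    """Unbiased PMF from harmonically biased windows by self-consistent WHAM.

    Iterates the window free energies f_i until the largest change falls
    below ``tol`` (kcal/mol):

        p(b)  =  sum_i h_ib / sum_i N_i exp((f_i - w_i(b)) / kT)
        f_i   = -kT ln sum_b p(b) exp(-w_i(b) / kT)

    A single window with zero bias degenerates exactly to Boltzmann
    inversion.  Non-overlapping adjacent windows trigger a warning; failure
    to converge raises :class:`ConvergenceError`.
    """
    if not windows:
        raise ParameterError("at least one window required")
    edges = np.linspace(angle_range[0], angle_range[1], bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    hists = np.array(
        [np.histogram(w.trajectory.theta, bins=edges)[0] for w in windows],
        dtype=float,
    )
    n_i = hists.sum(axis=1)
    if np.any(n_i == 0):
        raise ParameterError("a window has no samples inside the range")

    # adjacent-window overlap check (>= 1% shared normalized mass expected)
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        ha = hists[a] / n_i[a]
        hb = hists[b] / n_i[b]
        if np.minimum(ha, hb).sum() < 0.01:
            warnings.warn(
                f"umbrella windows at {windows[a].center:g} and "
                f"{windows[b].center:g} deg share <1% histogram mass"
            )

    bias = np.array(
        [0.5 * w.spring_k * (centers - w.center) ** 2 for w in windows]
    )
    boltz = np.exp(-bias / kT)  # (n_windows, n_bins)
    total = hists.sum(axis=0)
    f_i = np.zeros(len(windows))
    for _ in range(int(max_iter)):
        denom = (n_i[:, None] * np.exp(f_i / kT)[:, None] * boltz).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            p = np.where(denom > 0, total / denom, 0.0)
        s = p.sum()
        if s == 0:
            raise ConvergenceError("WHAM produced an all-zero distribution")
        p /= s
        f_new = -kT * np.log((p[None, :] * boltz).sum(axis=1))
        delta = np.max(np.abs(f_new - f_i))
        f_i = f_new
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max free-energy change {delta:.3g} kcal/mol)"
        )
    defined = total > 0
    f = np.full(centers.shape, np.nan)
    f[defined] = -kT * np.log(p[defined])
    f[defined] -= f[defined].min()
    return PMF(centers, f, defined, kT, "wham")


# ---------------------------------------------------------------------------
# Geometry from coordinates
# ---------------------------------------------------------------------------

def helix_axis(backbone_coords: np.ndarray) -> np.ndarray:
    """Principal axis of a C-alpha point cloud, oriented toward the C-terminus.

    The axis is the leading eigenvector of the coordinate covariance; its sign
    is fixed so that it points from the first toward the last residue.
    Requires at least 4 positions.
    """
    coords = np.asarray(backbone_coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] < 4:
        raise ParameterError("need at least 4 C-alpha positions of shape (n, 3)")
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    span = coords[-1] - coords[0]
    if np.dot(axis, span) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


#: Default side-chain tip rules: terminal heavy atoms whose centroid defines
#: the tip.  Trp uses its six-membered-ring atoms, Arg the guanidinium carbon.
TIP_RULES = {
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "ARG": ("CZ",),
}

_BACKBONE = {"N", "CA", "C", "O", "OXT", "H", "HA"}


def sidechain_angle(structure, residue_id: int, tip_rule=None) -> float:
    """Angle (degrees, [0, 180]) between the helix axis and C-alpha -> tip.

    ``structure`` is a biotite AtomArray.  The helix axis is computed from all
    C-alpha atoms; the tip is the centroid of the atoms selected by
    ``tip_rule`` (a sequence of atom names), by the residue-type default in
    :data:`TIP_RULES`, or, failing those, of all non-backbone heavy atoms of
    the residue (which covers pseudo-atom side chains).
    """
    ca_mask = structure.atom_name == "CA"
    if ca_mask.sum() < 4:
        raise MissingAtomsError("fewer than 4 C-alpha atoms in structure")
    ca_order = np.argsort(structure.res_id[ca_mask], kind="stable")
    axis = helix_axis(structure.coord[ca_mask][ca_order])

    res = structure[structure.res_id == residue_id]
    if res.array_length() == 0:
        raise MissingAtomsError(f"residue {residue_id} not found")
    ca = res.coord[res.atom_name == "CA"]
    if ca.shape[0] == 0:
        raise MissingAtomsError(f"residue {residue_id}: missing CA")
    if tip_rule is None:
        tip_rule = TIP_RULES.get(str(res.res_name[0]))
    if tip_rule is not None:
        sel = np.isin(res.atom_name, list(tip_rule))
        missing = sorted(set(tip_rule) - set(res.atom_name[sel]))
        if missing:
            raise MissingAtomsError(
                f"residue {residue_id}: missing tip atoms {missing}"
            )
    else:
        sel = ~np.isin(res.atom_name, list(_BACKBONE))
        if not sel.any():
            raise MissingAtomsError(
                f"residue {residue_id}: no side-chain atoms for tip"
            )
    tip = res.coord[sel].mean(axis=0)
    v = tip - ca[0]
    norm = np.linalg.norm(v)
    if norm == 0:
        raise ParameterError("tip coincides with C-alpha")
    cosang = np.clip(np.dot(v / norm, axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


# ---------------------------------------------------------------------------
# Non-bonded interaction energies
# ---------------------------------------------------------------------------

@dataclass
class AtomParameters:
    """Per-atom charges (e) and Lennard-Jones parameters for one selection."""

    charge: np.ndarray       # e
    epsilon: np.ndarray      # kcal/mol, >= 0
    rmin_half: np.ndarray    # Angstrom

    def __post_init__(self) -> None:
        self.charge = np.atleast_1d(np.asarray(self.charge, dtype=float))
        self.epsilon = np.atleast_1d(np.asarray(self.epsilon, dtype=float))
        self.rmin_half = np.atleast_1d(np.asarray(self.rmin_half, dtype=float))
        if not (self.charge.shape == self.epsilon.shape == self.rmin_half.shape):
            raise ParameterError("parameter arrays must share one shape")
        if np.any(self.epsilon < 0):
            raise ParameterError("epsilon must be non-negative")

    @classmethod
    def from_table(cls, atom_names, table: dict) -> "AtomParameters":
        """Build per-atom parameters from a name -> (q, eps, rmin/2) mapping."""
        missing = sorted({n for n in atom_names if n not in table})
        if missing:
            raise MissingAtomsError(f"no parameters for atoms {missing}")
        rows = np.array([table[n] for n in atom_names], dtype=float)
        return cls(rows[:, 0], rows[:, 1], rows[:, 2])


@dataclass
class NonbondedParams:
    """Options for pairwise non-bonded energies."""

    cutoff: float = 12.0      # Angstrom
    dielectric: float = 1.0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ParameterError("cutoff must be positive")


def nonbonded_energy(
    coords_a: np.ndarray,
    coords_b: np.ndarray,
    params_a: AtomParameters,
    params_b: AtomParameters,
    options: NonbondedParams | None = None,
) -> float:
    """Pairwise LJ + Coulomb energy between two disjoint selections (kcal/mol).

    E = sum over cross pairs within the cutoff of
        eps_ij [ (rmin_ij/r)^12 - 2 (rmin_ij/r)^6 ]  +  332.0636 q_i q_j / (D r)

    with geometric-mean epsilon and rmin_ij = rmin_half_i + rmin_half_j.
    Atoms closer than 0.1 Angstrom raise an error (overlapping input).
    """
    opts = options or NonbondedParams()
    a = np.atleast_2d(np.asarray(coords_a, dtype=float))
    b = np.atleast_2d(np.asarray(coords_b, dtype=float))
    if a.shape[0] != params_a.charge.size or b.shape[0] != params_b.charge.size:
        raise ParameterError("coordinates and parameters disagree in length")
    r = cdist(a, b)
    if np.any(r < 0.1):
        raise ParameterError("overlapping atoms (r < 0.1 Angstrom)")
    mask = r <= opts.cutoff
    if not mask.any():
        return 0.0
    eps = np.sqrt(np.outer(params_a.epsilon, params_b.epsilon))[mask]
    rmin = np.add.outer(params_a.rmin_half, params_b.rmin_half)[mask]
    qq = np.outer(params_a.charge, params_b.charge)[mask]
    rr = r[mask]
    sr6 = (rmin / rr) ** 6
    lj = eps * (sr6**2 - 2.0 * sr6)
    coul = COULOMB_K * qq / (opts.dielectric * rr)
    return float(lj.sum() + coul.sum())


def average_snapshot_energy(
    snapshot_pairs,
    params_a: AtomParameters,
    params_b: AtomParameters,
    options: NonbondedParams | None = None,
) -> tuple[float, float]:
    """Mean and sd of the cross non-bonded energy over structure snapshots.

    ``snapshot_pairs`` is a sequence of (coords_a, coords_b) coordinate pairs,
    one per snapshot.  The sd is the sample standard deviation (ddof=1), NaN
    for a single snapshot.
    """
    energies = [
        nonbonded_energy(ca, cb, params_a, params_b, options)
        for ca, cb in snapshot_pairs
    ]
    if not energies:
        raise ParameterError("at least one snapshot required")
    arr = np.asarray(energies)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else math.nan
    return float(arr.mean()), sd


# ---------------------------------------------------------------------------
# Ensemble Metropolis ddG
# ---------------------------------------------------------------------------

@dataclass
class DdgResult:
    """Ensemble Metropolis binding ddG = mean(dG_mut) - mean(dG_wt)."""

    dg_wt_runs: np.ndarray
    dg_mut_runs: np.ndarray
    dg_wt: float
    dg_mut: float
    ddg: float
    n_runs: int
    kT_mc: float
    seed: int


@dataclass
class ToyBindingModel:
    """Minimal two-state binding energy model on (theta, perturbation) space.

    The state is the side-chain angle theta plus ``n_perturb`` auxiliary
    perturbation angles phi_i (the stand-in for small backbone moves).  The
    bound-complex energy is the intrinsic double-well U(theta) plus a
    state-dependent interaction term (``interaction_n`` when theta is on the
    native side of ``boundary``, ``interaction_t`` otherwise) plus harmonic
    penalties 0.5 k phi^2; the separated energy lacks the interaction term, so
    the per-snapshot binding energy is exactly the interaction term.

    All energies are toy scores in arbitrary units; the default interaction
    magnitudes for the WT and mutant presets are configuration constants, not
    reproduced physical values.
    """

    potential: object  # callable U(theta) with the DoubleWellPotential API
    interaction_n: float = -20.0
    interaction_t: float = -10.0
    boundary: float = 70.0
    n_perturb: int = 8
    k_perturb: float = 0.05
    t_below: bool = True

    def binding_energy(self, theta: float) -> float:
        is_t = theta < self.boundary if self.t_below else theta >= self.boundary
        return self.interaction_t if is_t else self.interaction_n

    def theta_energy(self, theta: float) -> float:
        return self.potential(theta) + self.binding_energy(theta)

    def perturb_energy(self, phi: float) -> float:
        return 0.5 * self.k_perturb * phi * phi


def metropolis_accept(delta_e: float, kT_mc: float, u: float) -> bool:
    """Metropolis criterion: accept iff u < exp(-delta_e / kT_mc)."""
    if kT_mc <= 0:
        raise ParameterError("kT_mc must be positive")
    return delta_e <= 0.0 or u < math.exp(-delta_e / kT_mc)


def _run_chain(model: ToyBindingModel, n_moves, move_size, kT_mc,
               snapshot_every, rng) -> float:
    theta = float(getattr(model.potential, "theta_n", 90.0))
    phi = [0.0] * model.n_perturb
    n_coords = 1 + model.n_perturb
    idx = rng.integers(0, n_coords, size=n_moves)
    prop = rng.uniform(-move_size, move_size, size=n_moves)
    uni = rng.random(size=n_moves)
    snaps = []
    e_theta = model.theta_energy(theta)
    for m in range(n_moves):
        j = idx[m]
        if j == 0:
            new = theta + prop[m]
            if new < 0.0:
                new = -new
            elif new > 180.0:
                new = 360.0 - new
            e_new = model.theta_energy(new)
            if metropolis_accept(e_new - e_theta, kT_mc, uni[m]):
                theta, e_theta = new, e_new
        else:
            old = phi[j - 1]
            new = old + prop[m]
            de = model.perturb_energy(new) - model.perturb_energy(old)
            if metropolis_accept(de, kT_mc, uni[m]):
                phi[j - 1] = new
        if (m + 1) % snapshot_every == 0:
            snaps.append(model.binding_energy(theta))
    return float(np.mean(snaps))


def metropolis_ensemble_ddg(
    model_wt: ToyBindingModel,
    model_mut: ToyBindingModel,
    *,
    n_runs: int = 50,
    n_moves: int = 50_000,
    move_size: float = 8.0,
    kT_mc: float = 1.2,
    snapshot_every: int | None = None,
    seed: int,
) -> DdgResult:
    """Ensemble Metropolis estimate of the binding ddG.

    For each variant, ``n_runs`` independent chains of ``n_moves``
    single-coordinate perturbation moves are run with the Metropolis criterion
    at temperature ``kT_mc`` (a dimensionless score temperature, default 1.2).
    State snapshots are taken every ``snapshot_every`` moves (default
    n_moves/10, i.e. 10 snapshots per run); the per-run dG is the snapshot
    mean of (E_complex - E_separated), and

        ddG = mean(dG over mutant runs) - mean(dG over WT runs).

    Both variants consume identical per-run random streams derived from
    ``seed``, so identical models give ddG = 0 exactly.
    """
    if kT_mc <= 0:
        raise ParameterError("kT_mc must be positive")
    if n_runs < 2:
        raise ParameterError("n_runs must be at least 2")
    if snapshot_every is None:
        snapshot_every = max(1, n_moves // 10)
    run_seeds = np.random.SeedSequence(seed).spawn(n_runs)
    dg = {"wt": np.empty(n_runs), "mut": np.empty(n_runs)}
    for name, model in (("wt", model_wt), ("mut", model_mut)):
        for i, ss in enumerate(run_seeds):
            rng = np.random.default_rng(ss)
            dg[name][i] = _run_chain(
                model, n_moves, move_size, kT_mc, snapshot_every, rng
            )
    dg_wt = float(dg["wt"].mean())
    dg_mut = float(dg["mut"].mean())
    return DdgResult(
        dg["wt"], dg["mut"], dg_wt, dg_mut, dg_mut - dg_wt, n_runs, kT_mc, seed
    )
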