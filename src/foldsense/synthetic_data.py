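"""Synthetic inputs with known ground truth for every pipeline stage.

Generators here emulate the data the analysis consumes: Gaussian fluorophore
reference spectra, multi-band emission stacks of donor/acceptor mixtures at
known FRET efficiency, overdamped Langevin sampling of a double-well
side-chain-angle landscape (including umbrella-biased windows), toy
helix + side-chain + partner coordinate sets, and arrest-peptide tether
libraries with a known stalling-release profile.  Every generator is
deterministic given its parameters and seed; seeds are explicit arguments,
never global state.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.polynomial.polynomial as npoly
from scipy.optimize import brentq

from .conformation import KT_298, AngleTrajectory, UmbrellaWindow
from .errors import ParameterError
from .spectral_fret import SpectralStack, default_band_edges

logger = logging.getLogger(__name__)

DEFAULT_GRID_START = 450.0
DEFAULT_GRID_STOP = 610.0
DEFAULT_GRID_STEP = 5.0


# ---------------------------------------------------------------------------
# Fluorophore spectra
# ---------------------------------------------------------------------------

@dataclass
class FluorophoreSpectrum:
    """Excitation/emission shapes plus photophysics for one fluorophore.

    Invariants: wavelengths strictly increasing with uniform step; emission
    integrates (trapezoid) to 1; excitation peaks at exactly 1; quantum yield
    in [0, 1].
    """

    name: str
    wavelengths: np.ndarray     # nm
    excitation: np.ndarray      # unitless, max 1
    emission: np.ndarray        # nm^-1, unit area
    quantum_yield: float
    extinction_coeff: float     # M^-1 cm^-1 at the excitation peak

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.excitation = np.asarray(self.excitation, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ParameterError("wavelengths must be strictly increasing")
        if not 0.0 <= self.quantum_yield <= 1.0:
            raise ParameterError("quantum yield must lie in [0, 1]")
        area = np.trapezoid(self.emission, self.wavelengths)
        if abs(area - 1.0) > 1e-9:
            raise ParameterError(f"emission area is {area}, expected 1")
        if abs(self.excitation.max() - 1.0) > 1e-9:
            raise ParameterError("excitation maximum must equal 1")

    def excitation_at(self, wavelength: float) -> float:
        return float(np.interp(
            wavelength, self.wavelengths, self.excitation, left=0.0, right=0.0
        ))

    def emission_band_fraction(self, lo: float, hi: float, n: int = 33) -> float:
        """Fraction of emission captured in the band [lo, hi] (trapezoid)."""
        wl = np.linspace(lo, hi, n)
        em = np.interp(wl, self.wavelengths, self.emission, left=0.0, right=0.0)
        return float(np.trapezoid(em, wl))


def make_fluorophore(
    name: str,
    ex_peak: float,
    em_peak: float,
    width: float,
    quantum_yield: float,
    extinction_coeff: float,
    *,
    grid_step: float = DEFAULT_GRID_STEP,
    n_widths: float = 4.0,
) -> FluorophoreSpectrum:
    """Gaussian stand-in spectrum with the given peaks and width (sigma, nm).

    The wavelength grid is the 450-610 nm / 5 nm detection lattice, extended
    (on the same lattice) whenever a peak +- ``n_widths`` sigma falls outside
    it; the extension is logged.  Emission is normalized to unit area and
    excitation to unit maximum after sampling.
    """
    if width <= 0:
        raise ParameterError("width must be positive")
    if em_peak <= ex_peak:
        raise ParameterError("emission peak must be red of excitation peak")
    lo_needed = min(ex_peak, em_peak) - n_widths * width
    hi_needed = max(ex_peak, em_peak) + n_widths * width
    lo = DEFAULT_GRID_START
    hi = DEFAULT_GRID_STOP
    if lo_needed < lo:
        lo = lo - math.ceil((lo - lo_needed) / grid_step) * grid_step
    if hi_needed > hi:
        hi = hi + math.ceil((hi_needed - hi) / grid_step) * grid_step
    if lo != DEFAULT_GRID_START or hi != DEFAULT_GRID_STOP:
        logger.warning(
            "%s: wavelength grid extended to [%g, %g] nm to cover peaks",
            name, lo, hi,
        )
    wl = np.arange(lo, hi + 0.5 * grid_step, grid_step)
    ex = np.exp(-0.5 * ((wl - ex_peak) / width) ** 2)
    ex /= ex.max()
    em = np.exp(-0.5 * ((wl - em_peak) / width) ** 2)
    em /= np.trapezoid(em, wl)
    return FluorophoreSpectrum(name, wl, ex, em, quantum_yield, extinction_coeff)


def mcfp() -> FluorophoreSpectrum:
    """Monomeric CFP stand-in (QY 0.41)."""
    return make_fluorophore("mCFP", 433.0, 475.0, 20.0, 0.41, 32_500.0)


def mcitrine() -> FluorophoreSpectrum:
    """Monomeric Citrine (YFP) stand-in (QY 0.74)."""
    return make_fluorophore("mCitrine", 516.0, 529.0, 15.0, 0.74, 77_000.0)


def mtfp1() -> FluorophoreSpectrum:
    """mTFP1 stand-in (QY 0.85)."""
    return make_fluorophore("mTFP1", 462.0, 492.0, 15.0, 0.85, 64_000.0)


def mcpvenus() -> FluorophoreSpectrum:
    """mcpVenus stand-in (QY 0.64)."""
    return make_fluorophore("mcpVenus", 515.0, 528.0, 15.0, 0.64, 92_000.0)


def reference_vector(
    spectrum: FluorophoreSpectrum, band_edges: np.ndarray
) -> np.ndarray:
    """Band-integrated emission reference (one entry per detection band)."""
    edges = np.asarray(band_edges, dtype=float)
    return np.array([
        spectrum.emission_band_fraction(lo, hi)
        for lo, hi in zip(edges[:-1], edges[1:])
    ])


# ---------------------------------------------------------------------------
# Spectral stacks at known efficiency
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthScene:
    """Known per-sample truth for a simulated spectral stack."""

    efficiency_map: np.ndarray
    donor_abundance: np.ndarray
    acceptor_abundance: np.ndarray
    noise_model: str = "none"          # none | gaussian | poisson
    seed: int = 0
    noise_scale: float = 1.0           # gaussian sigma, or poisson counts/a.u.

    def __post_init__(self) -> None:
        self.efficiency_map = np.asarray(self.efficiency_map, dtype=float)
        self.donor_abundance = np.asarray(self.donor_abundance, dtype=float)
        self.acceptor_abundance = np.asarray(self.acceptor_abundance, dtype=float)
        if not (
            self.efficiency_map.shape
            == self.donor_abundance.shape
            == self.acceptor_abundance.shape
        ):
            raise ParameterError("scene maps must share one shape")
        if np.any(self.efficiency_map < 0) or np.any(self.efficiency_map > 1):
            raise ParameterError("efficiency map must lie in [0, 1]")
        if np.any(self.donor_abundance < 0) or np.any(self.acceptor_abundance < 0):
            raise ParameterError("abundances must be non-negative")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ParameterError(f"unknown noise model {self.noise_model!r}")


def simulate_spectral_stack(
    donor: FluorophoreSpectrum,
    acceptor: FluorophoreSpectrum,
    scene: GroundTruthScene,
    laser: float = 405.0,
    band_edges: np.ndarray | None = None,
    *,
    cross_excitation: bool = True,
) -> SpectralStack:
    """Forward-model a multi-band emission stack at known FRET efficiency.

    Per band b, with donor abundance d, acceptor abundance a and efficiency E:

        signal_b = d X_D(laser) QY_D (1 - E) B_D(b)
                 + [ d X_D(laser) QY_A E + a X_A(laser) QY_A ] B_A(b)

    where X are excitation shapes at the laser line and B the band-integrated
    emission shapes.  The acceptor cross-excitation term a X_A QY_A is the
    direct (non-FRET) acceptor signal and can be switched off.  Noise follows
    the scene's model; the ground truth travels with the returned stack.
    """
    if band_edges is None:
        band_edges = default_band_edges()
    edges = np.asarray(band_edges, dtype=float)
    if not (donor.wavelengths[0] <= laser <= donor.wavelengths[-1]):
        raise ParameterError(
            f"laser {laser} nm outside the donor grid "
            f"[{donor.wavelengths[0]}, {donor.wavelengths[-1]}]"
        )
    e = scene.efficiency_map.ravel()
    d = scene.donor_abundance.ravel()
    a = scene.acceptor_abundance.ravel()
    b_d = reference_vector(donor, edges)
    b_a = reference_vector(acceptor, edges)
    x_d = donor.excitation_at(laser)
    x_a = acceptor.excitation_at(laser)
    donor_amp = d * x_d * donor.quantum_yield * (1.0 - e)
    acceptor_amp = d * x_d * acceptor.quantum_yield * e
    if cross_excitation:
        acceptor_amp = acceptor_amp + a * x_a * acceptor.quantum_yield
    data = np.outer(donor_amp, b_d) + np.outer(acceptor_amp, b_a)
    if scene.noise_model != "none":
        rng = np.random.default_rng(scene.seed)
        if scene.noise_model == "gaussian":
            data = data + rng.normal(0.0, scene.noise_scale, size=data.shape)
        else:  # poisson, scale = expected counts per arbitrary unit
            data = rng.poisson(
                np.clip(data, 0.0, None) * scene.noise_scale
            ) / scene.noise_scale
    truth = {
        "efficiency": scene.efficiency_map.copy(),
        "donor_abundance": scene.donor_abundance.copy(),
        "acceptor_abundance": scene.acceptor_abundance.copy(),
        "donor_amp": donor_amp,
        "acceptor_amp": acceptor_amp,
    }
    return SpectralStack(data, edges, laser, label="simulated", truth=truth)


# ---------------------------------------------------------------------------
# Double-well angle landscape and Langevin sampling
# ---------------------------------------------------------------------------

@dataclass
class DoubleWellPotential:
    """Quartic double well in the side-chain inclination angle (degrees).

    Parameterized by the two minima positions, the well depths (the depth
    difference fixes the asymmetry; the deeper well is shifted to zero) and
    the barrier height above the shallower well.  The quartic through these
    constraints is solved at construction.
    """

    theta_n: float = 100.0
    theta_t: float = 40.0
    depth_n: float = 3.0       # kcal/mol
    depth_t: float = 3.0       # kcal/mol
    barrier_height: float = 1.0  # kcal/mol above the shallower well

    _coeffs: np.ndarray = field(init=False, repr=False)
    _dcoeffs: tuple = field(init=False, repr=False)
    theta_barrier: float = field(init=False)

    def __post_init__(self) -> None:
        if self.theta_n == self.theta_t:
            raise ParameterError("the two minima must differ")
        for th in (self.theta_n, self.theta_t):
            if not 0.0 <= th <= 180.0:
                raise ParameterError("minima must lie in [0, 180] degrees")
        if self.barrier_height <= 0:
            raise ParameterError("barrier height must be positive")
        if min(self.depth_n, self.depth_t) < 0:
            raise ParameterError("well depths must be non-negative")
        t_lo, t_hi = sorted((self.theta_n, self.theta_t))
        depth_lo = self.depth_n if t_lo == self.theta_n else self.depth_t
        depth_hi = self.depth_n + self.depth_t - depth_lo
        delta = abs(self.depth_n - self.depth_t)
        # barrier above each well for the target landscape
        h_lo = self.barrier_height + (delta if depth_lo > depth_hi else 0.0)
        h_hi = self.barrier_height + (delta if depth_hi > depth_lo else 0.0)

        # Solve in the shifted coordinate u = theta - t_lo, where the quartic
        # with U'(u) = 4 A u (u - m)(u - w), w = t_hi - t_lo, has closed-form
        # barrier heights (for A = 1):
        #   above the low well  a_lo = m^3 (2w - m) / 3
        #   above the high well a_hi = a_lo - w^3 (2m - w) / 3
        # The barrier position m is fixed by a_lo / a_hi = h_lo / h_hi.
        w = t_hi - t_lo

        def mismatch(m):
            a_lo = m**3 * (2.0 * w - m) / 3.0
            a_hi = a_lo - w**3 * (2.0 * m - w) / 3.0
            return a_lo * h_hi - a_hi * h_lo

        eps = 1e-9 * w
        m = brentq(mismatch, eps, w - eps, xtol=1e-12)
        a_lo = m**3 * (2.0 * w - m) / 3.0
        amp = h_lo / a_lo
        # U(u) = A [u^4 - (4/3)(m + w) u^3 + 2 m w u^2] + const
        coeffs = np.array([
            0.0, 0.0, 2.0 * amp * m * w, -(4.0 / 3.0) * amp * (m + w), amp,
        ])
        u_min = min(npoly.polyval(0.0, coeffs), npoly.polyval(w, coeffs))
        coeffs[0] -= u_min
        self._offset = t_lo
        self._coeffs = coeffs
        self._dcoeffs = tuple(npoly.polyder(coeffs))
        self.theta_barrier = float(t_lo + m)

    def __call__(self, theta):
        return npoly.polyval(np.asarray(theta, dtype=float) - self._offset,
                             self._coeffs)

    def grad(self, theta: float) -> float:
        u = theta - self._offset
        d = self._dcoeffs
        return ((d[3] * u + d[2]) * u + d[1]) * u + d[0]

    @classmethod
    def wt_preset(cls) -> "DoubleWellPotential":
        """Deep native well: the N orientation is strongly preferred and the
        barrier out of N (~6.5 kcal/mol, ~11 kT at 298 K) suppresses N->T
        transitions on accessible simulation lengths."""
        return cls(theta_n=100.0, theta_t=40.0, depth_n=6.5, depth_t=1.5,
                   barrier_height=1.5)

    @classmethod
    def w344r_preset(cls) -> "DoubleWellPotential":
        """Tilted-state-favoring landscape: T is modestly deeper than N and
        the barrier is low (~2 kT), so both states are visited with T
        dominating."""
        return cls(theta_n=100.0, theta_t=40.0, depth_n=1.0, depth_t=1.7,
                   barrier_height=1.2)


@dataclass
class HarmonicPotential:
    """Simple harmonic angle potential, used as an analytic PMF reference."""

    center: float = 90.0
    k: float = 0.01  # kcal/mol/deg^2

    def __call__(self, theta):
        d = np.asarray(theta, dtype=float) - self.center
        out = 0.5 * self.k * d * d
        return float(out) if out.ndim == 0 else out

    def grad(self, theta: float) -> float:
        return self.k * (theta - self.center)


@dataclass
class _BiasedPotential:
    base: object
    center: float
    spring_k: float

    def __call__(self, theta):
        d = theta - self.center
        return self.base(theta) + 0.5 * self.spring_k * d * d

    def grad(self, theta: float) -> float:
        return self.base.grad(theta) + self.spring_k * (theta - self.center)


def boltzmann_state_weights(
    pot, kT: float, boundary: float, *, n_grid: int = 20_001
) -> tuple[float, float]:
    """Numeric Boltzmann weights of the (theta < boundary, theta >= boundary)
    halves of [0, 180]; the quadrature oracle for sampler checks."""
    theta = np.linspace(0.0, 180.0, n_grid)
    w = np.exp(-(pot(theta) - np.min(pot(theta))) / kT)
    below = np.trapezoid(np.where(theta < boundary, w, 0.0), theta)
    total = np.trapezoid(w, theta)
    return float(below / total), float(1.0 - below / total)


def simulate_double_well_trajectory(
    pot,
    kT: float = KT_298,
    friction: float = 1.0,
    dt: float = 0.05,
    n_steps: int = 100_000,
    theta0: float = 100.0,
    *,
    seed: int,
) -> AngleTrajectory:
    """Overdamped Langevin sampling of an angle potential on [0, 180] deg.

    Euler-Maruyama update theta <- theta - U'(theta) dt/gamma
    + sqrt(2 kT dt/gamma) xi with reflective boundaries at 0 and 180 degrees
    (the angle is an inclination, not a dihedral).  ``seed`` is mandatory;
    with kT = 0 the update is pure gradient descent.

    Raises
    ------
    ParameterError
        If kT < 0, or dt is too coarse (deterministic drift at the barrier
        would exceed 5 degrees/step).
    RuntimeError
        If an instability is detected at run time (|step| > 30 degrees).
    """
    if kT < 0:
        raise ParameterError("kT must be non-negative")
    if dt <= 0 or friction <= 0:
        raise ParameterError("dt and friction must be positive")
    # drift check over the inter-well region (or around theta0 for other
    # potentials)
    if hasattr(pot, "theta_n") and hasattr(pot, "theta_t"):
        lo, hi = sorted((pot.theta_n, pot.theta_t))
    else:
        lo, hi = max(0.0, theta0 - 45.0), min(180.0, theta0 + 45.0)
    grid = np.linspace(lo, hi, 181)
    max_drift = max(abs(pot.grad(g)) for g in grid) * dt / friction
    if max_drift >= 5.0:
        raise ParameterError(
            f"dt={dt} too coarse: deterministic drift up to {max_drift:.2f} "
            "deg/step at the barrier (limit 5)"
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n_steps) * math.sqrt(2.0 * kT * dt / friction)
    inv_gamma_dt = dt / friction
    out = np.empty(n_steps)
    theta = float(theta0)
    grad = pot.grad
    for i in range(n_steps):
        step = -grad(theta) * inv_gamma_dt + noise[i]
        if abs(step) > 30.0:
            raise RuntimeError(
                f"integration instability (|step| {abs(step):.1f} deg) at "
                f"frame {i}; reduce dt={dt}"
            )
        theta += step
        if theta < 0.0:
            theta = -theta
        elif theta > 180.0:
            theta = 360.0 - theta
        out[i] = theta
    return AngleTrajectory(out, dt=dt, provenance="simulated", seed=seed)


def simulate_umbrella_windows(
    pot,
    centers,
    spring_k: float,
    *,
    kT: float = KT_298,
    friction: float = 1.0,
    dt: float = 0.05,
    n_steps: int = 20_000,
    seed: int,
) -> list[UmbrellaWindow]:
    """Sample harmonically biased windows U(theta) + k/2 (theta - c)^2.

    ``spring_k = 0`` degenerates to unbiased sampling.  Each window starts at
    its center and uses an independent seed derived deterministically from
    ``seed``.  Adjacent windows sharing <1% histogram mass trigger a warning.
    """
    if spring_k < 0:
        raise ParameterError("spring_k must be non-negative")
    centers = np.asarray(centers, dtype=float)
    child_seeds = np.random.SeedSequence(seed).generate_state(centers.size)
    windows = []
    for c, s in zip(centers, child_seeds):
        biased = _BiasedPotential(pot, float(c), spring_k)
        traj = simulate_double_well_trajectory(
            biased, kT=kT, friction=friction, dt=dt, n_steps=n_steps,
            theta0=float(np.clip(c, 0.0, 180.0)), seed=int(s % 2**31),
        )
        windows.append(UmbrellaWindow(traj, float(c), spring_k))
    edges = np.linspace(0.0, 180.0, 91)
    order = np.argsort(centers)
    for a, b in zip(order[:-1], order[1:]):
        ha = np.histogram(windows[a].trajectory.theta, bins=edges)[0]
        hb = np.histogram(windows[b].trajectory.theta, bins=edges)[0]
        shared = np.minimum(ha / ha.sum(), hb / hb.sum()).sum()
        if shared < 0.01:
            warnings.warn(
                f"umbrella windows at {centers[a]:g} and {centers[b]:g} deg "
                f"share {100 * shared:.2f}% histogram mass (<1%)"
            )
    return windows


# ---------------------------------------------------------------------------
# Toy helix / side-chain / partner coordinates
# ---------------------------------------------------------------------------

ORIENTATION_ANGLES = {"N": 100.0, "T": 40.0}


def make_toy_complex(
    orientation: str | float = "N",
    include_partner: bool = True,
    *,
    n_residues: int = 18,
    sidechain_residue: int | None = None,
    sidechain_length: float = 4.0,
    partner_distance: float = 7.0,
    partner_spread: float = 1.2,
    n_partner_atoms: int = 24,
    seed: int = 0,
):
    """Idealized helix with a pseudo side chain at a configured inclination.

    Builds an alpha-helical C-alpha trace along +z (rise 1.5 A, 100 deg per
    residue, radius 2.3 A), places a single side-chain pseudo-atom (name
    ``TIP``) at ``sidechain_length`` A from the mid-helix C-alpha, inclined at
    the configured angle from the helix axis, and optionally scatters a
    partner-lobe pseudo-atom cloud (residue name ``PRT``) around a point
    ``partner_distance`` A beyond the tip.  Returns a biotite AtomArray
    (PDB-writable); recomputing the angle from the emitted coordinates
    returns the configured angle to within 0.5 degrees.
    """
    import biotite.structure as struc

    if isinstance(orientation, str):
        try:
            angle = ORIENTATION_ANGLES[orientation]
        except KeyError:
            raise ParameterError(
                f"orientation must be one of {sorted(ORIENTATION_ANGLES)} "
                "or an angle in degrees"
            ) from None
    else:
        angle = float(orientation)
    if sidechain_residue is None:
        sidechain_residue = n_residues // 2

    from .conformation import helix_axis

    rise, twist, radius = 1.5, math.radians(100.0), 2.3
    ca = np.array([
        (radius * math.cos(twist * i), radius * math.sin(twist * i), rise * i)
        for i in range(n_residues)
    ])
    # place the tip at the configured inclination from the axis the analysis
    # will actually measure (the finite helix's principal axis, which tilts
    # slightly off the geometric z axis)
    axis = helix_axis(ca)
    anchor = ca[sidechain_residue - 1]
    radial = anchor - np.array([0.0, 0.0, anchor[2]])
    radial -= np.dot(radial, axis) * axis
    radial /= np.linalg.norm(radial)
    a = math.radians(angle)
    tip_dir = math.cos(a) * axis + math.sin(a) * radial
    tip = anchor + sidechain_length * tip_dir

    atoms = []
    for i, pos in enumerate(ca, start=1):
        atoms.append(("CA", "GLY", i, "A", pos, "C"))
    atoms.append(("TIP", "SCH", sidechain_residue, "A", tip, "C"))
    if include_partner:
        rng = np.random.default_rng(seed)
        center = anchor + (sidechain_length + partner_distance) * tip_dir
        cloud = center + rng.normal(0.0, partner_spread, size=(n_partner_atoms, 3))
        for j, pos in enumerate(cloud, start=1):
            atoms.append(("PRT", "PRT", n_residues + j, "B", pos, "C"))

    arr = struc.AtomArray(len(atoms))
    for k, (name, res, rid, chain, pos, elem) in enumerate(atoms):
        arr.atom_name[k] = name
        arr.res_name[k] = res
        arr.res_id[k] = rid
        arr.chain_id[k] = chain
        arr.coord[k] = pos
        arr.element[k] = elem
        arr.hetero[k] = name in ("TIP", "PRT")
    return arr


# ---------------------------------------------------------------------------
# Arrest-peptide force-profile scenarios
# ---------------------------------------------------------------------------

#: Tether lengths (residues past the conserved arrest-peptide proline,
#: arrest-peptide residues included) of the default construct library.
DEFAULT_TETHER_LENGTHS = (18, 22, 24, 27, 34, 40, 50)


@dataclass
class FPAScenario:
    """Ground-truth description of an arrest-peptide tether library.

    The noiseless full-length ratio rises linearly from ``onset_length`` (the
    tether at which folding can first generate enough force to relieve
    arrest) to ``peak_length``, then decays exponentially at ``decay_rate``
    per residue; ``amplitude`` is the peak height above ``baseline_ratio``.
    Without the folding partner (``chaperone_present=False``) the ratio stays
    at baseline everywhere.
    """

    tether_lengths: tuple = DEFAULT_TETHER_LENGTHS
    onset_length: float = 20.0
    peak_length: float = 22.0
    decay_rate: float = 0.4        # per residue
    chaperone_present: bool = True
    baseline_ratio: float = 0.1
    amplitude: float = 0.8
    noise_sd: float = 0.05
    n_replicates: int = 3
    condition: str = "+CaM"

    def __post_init__(self) -> None:
        lengths = np.asarray(self.tether_lengths, dtype=float)
        if np.any(lengths <= 0) or np.any(np.diff(lengths) <= 0):
            raise ParameterError(
                "tether lengths must be positive and strictly increasing"
            )
        if self.onset_length > self.peak_length:
            raise ParameterError("onset_length must not exceed peak_length")
        if self.decay_rate < 0 or self.noise_sd < 0:
            raise ParameterError("decay_rate and noise_sd must be non-negative")

    def mean_ratio(self, length) -> np.ndarray:
        """Noiseless full-length ratio at the given tether length(s)."""
        L = np.asarray(length, dtype=float)
        if not self.chaperone_present:
            shape = np.zeros_like(L)
        else:
            rising = np.clip(
                (L - self.onset_length)
                / max(self.peak_length - self.onset_length, 1e-12),
                0.0, 1.0,
            )
            decay = np.exp(-self.decay_rate * np.clip(L - self.peak_length, 0, None))
            shape = np.where(L <= self.peak_length, rising, decay)
            shape = np.where(L < self.onset_length, 0.0, shape)
        out = self.baseline_ratio + self.amplitude * shape
        return float(out) if out.ndim == 0 else out


def wt_fpa_scenario(chaperone_present: bool = True) -> FPAScenario:
    """Sharp WT-like profile peaking at a 22-residue tether."""
    return FPAScenario(
        onset_length=20.0, peak_length=22.0, decay_rate=0.4,
        chaperone_present=chaperone_present,
        condition="+CaM" if chaperone_present else "-CaM",
    )


def w344r_fpa_scenario(chaperone_present: bool = True) -> FPAScenario:
    """Broad, damped mutant-like profile with no resolvable sharp peak."""
    return FPAScenario(
        onset_length=18.0, peak_length=27.0, decay_rate=0.0, amplitude=0.25,
        chaperone_present=chaperone_present,
        condition="+CaM" if chaperone_present else "-CaM",
    )


def simulate_fpa_profile(scn: FPAScenario, *, seed: int):
    """Simulate a construct library and assemble its force profile.

    Returns ``(profile, constructs, truth)`` where ``profile`` is the
    replicate-averaged :class:`foldsense.force_profile.ForceProfile`,
    ``constructs`` the underlying per-replicate construct records, and
    ``truth`` the noiseless ratios plus the generator's peak length (None
    when no folding partner is present).
    """
    from .force_profile import FPAConstruct, build_profile

    rng = np.random.default_rng(seed)
    constructs = []
    for rep in range(scn.n_replicates):
        for L in scn.tether_lengths:
            ratio = scn.mean_ratio(L) + rng.normal(0.0, scn.noise_sd)
            ratio = max(ratio, 0.0)
            donor = 100.0
            constructs.append(FPAConstruct(
                construct_id=f"L{L}_r{rep}",
                tether_length=int(L),
                condition=scn.condition,
                replicate=rep,
                donor_peak=donor,
                acceptor_peak=ratio * donor,
            ))
    profile = build_profile(constructs)
    truth = {
        "mean_ratios": scn.mean_ratio(np.asarray(scn.tether_lengths, float)),
        "peak_length": scn.peak_length if scn.chaperone_present else None,
    }
    return profile, constructs, truth
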