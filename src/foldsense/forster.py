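"""Förster theory and index-to-efficiency transfer functions.

Covers the spectral overlap integral J, the Förster radius R0, the
efficiency-distance law E = 1/(1+(r/R0)^6), and the calibration step that
turns a donor/acceptor pair into a transfer function E = a + b*x/(x+c)
mapping a measured FRET index x to an efficiency: noiseless forward-simulated
stacks over a grid of true efficiencies are unmixed, indexed, and fitted.

Units: wavelengths nm, extinction M^-1 cm^-1, J in M^-1 cm^-1 nm^4, R0 in
Angstrom with the standard prefactor 0.211 for these units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import ConvergenceError, ParameterError

#: Prefactor of the sixth-root law for J in M^-1 cm^-1 nm^4 and R0 in Angstrom.
R0_PREFACTOR = 0.211


@dataclass
class TransferFunction:
    """Parameters of E = a + b * x / (x + c) mapping FRET index x to efficiency.

    ``c`` is the half-saturation index; for b > 0 the map is strictly
    increasing.  Fitted instances carry ``r_squared`` and a provenance string.
    """

    a: float
    b: float
    c: float
    r_squared: float | None = None
    provenance: str = "preset"

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ParameterError("transfer function requires c > 0")

    def __call__(self, fret_index):
        x = np.asarray(fret_index, dtype=float)
        e = self.a + self.b * x / (x + self.c)
        return float(e) if np.ndim(fret_index) == 0 else e


#: Transfer function calibrated for the living-cell mCFP/mCitrine experiments.
HEK_CFP_YFP = TransferFunction(0.001, 1.0022, 2.11, provenance="preset:hek_cfp_yfp")

#: Transfer function calibrated for the bacterial mTFP1/mcpVenus experiments.
BACT_TFP_VENUS = TransferFunction(
    -0.9279, 1.9335, 0.6821, provenance="preset:bact_tfp_venus"
)

PRESETS = {
    "hek_cfp_yfp": HEK_CFP_YFP,
    "bact_tfp_venus": BACT_TFP_VENUS,
}


def get_preset(name: str) -> TransferFunction:
    """Return a named transfer-function preset."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ParameterError(
            f"unknown transfer preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


@dataclass
class ForsterPair:
    """A donor/acceptor pair with its overlap integral and Förster radius."""

    donor: "FluorophoreSpectrum"
    acceptor: "FluorophoreSpectrum"
    kappa2: float = 2.0 / 3.0
    refractive_index: float = 1.4
    J: float = field(init=False)
    R0: float = field(init=False)

    def __post_init__(self) -> None:
        self.J = overlap_integral(self.donor, self.acceptor)
        self.R0 = forster_radius(
            self.J, self.donor.quantum_yield, self.kappa2, self.refractive_index
        )


def overlap_integral(donor, acceptor) -> float:
    """Spectral overlap J = integral f_D(l) eps_A(l) l^4 dl.

    ``f_D`` is the donor emission shape normalized to unit area (nm^-1) and
    ``eps_A(l)`` the acceptor extinction spectrum, taken as the acceptor
    excitation shape scaled by its peak extinction coefficient.  Spectra on
    different grids are linearly resampled to the finer step over the shared
    wavelength range; trapezoidal quadrature.
    """
    lo = max(donor.wavelengths[0], acceptor.wavelengths[0])
    hi = min(donor.wavelengths[-1], acceptor.wavelengths[-1])
    if hi <= lo:
        warnings.warn("donor and acceptor grids do not overlap; J = 0")
        return 0.0
    step = min(
        np.min(np.diff(donor.wavelengths)), np.min(np.diff(acceptor.wavelengths))
    )
    wl = np.arange(lo, hi + 0.5 * step, step)
    f_d = np.interp(wl, donor.wavelengths, donor.emission, left=0.0, right=0.0)
    eps = acceptor.extinction_coeff * np.interp(
        wl, acceptor.wavelengths, acceptor.excitation, left=0.0, right=0.0
    )
    return float(np.trapezoid(f_d * eps * wl**4, wl))


def forster_radius(
    J: float, qy_donor: float, kappa2: float = 2.0 / 3.0, n: float = 1.4
) -> float:
    """Förster radius R0 (Angstrom) = 0.211 * (kappa2 n^-4 QY_D J)^(1/6)."""
    if J < 0 or qy_donor < 0 or kappa2 < 0:
        raise ParameterError("J, quantum yield and kappa2 must be non-negative")
    if n <= 0:
        raise ParameterError("refractive index must be positive")
    return R0_PREFACTOR * (kappa2 * n**-4 * qy_donor * J) ** (1.0 / 6.0)


def efficiency_from_distance(r: float, R0: float):
    """FRET efficiency at donor-acceptor distance r: E = 1 / (1 + (r/R0)^6)."""
    if R0 <= 0:
        raise ParameterError("R0 must be positive")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ParameterError("distance must be non-negative")
    e = 1.0 / (1.0 + (r / R0) ** 6)
    return float(e) if e.ndim == 0 else e


def derive_transfer_function(
    donor,
    acceptor,
    laser: float = 405.0,
    band_edges: np.ndarray | None = None,
    *,
    stoichiometry: float = 1.0,
    efficiency_grid: np.ndarray | None = None,
    cross_excitation: bool = True,
) -> TransferFunction:
    """Calibrate an index-to-efficiency transfer function for a pair.

    For each efficiency on the grid, a noiseless single-sample stack is
    forward-simulated (donor abundance 1, acceptor abundance =
    ``stoichiometry``), unmixed against the pair's reference shapes, and the
    integral FRET index computed; (index, efficiency) pairs are then fitted to
    E = a + b*x/(x+c) by unweighted least squares initialized at
    (0, 1, median(x)).

    Returns a fitted :class:`TransferFunction` carrying r_squared.  A warning
    is raised if r_squared < 0.99.
    """
    from . import synthetic_data as sd
    from . import spectral_fret as sf

    if efficiency_grid is None:
        efficiency_grid = np.arange(0.0, 1.0, 0.05)
    e_grid = np.asarray(efficiency_grid, dtype=float)
    if e_grid.size < 5:
        raise ParameterError("efficiency grid needs at least 5 points")
    if band_edges is None:
        band_edges = sf.default_band_edges()

    d_ref = sd.reference_vector(donor, band_edges)
    a_ref = sd.reference_vector(acceptor, band_edges)

    x = np.empty_like(e_grid)
    for i, e in enumerate(e_grid):
        scene = sd.GroundTruthScene(
            efficiency_map=np.array([e]),
            donor_abundance=np.array([1.0]),
            acceptor_abundance=np.array([stoichiometry]),
            noise_model="none",
            seed=0,
        )
        stack = sd.simulate_spectral_stack(
            donor, acceptor, scene, laser=laser, band_edges=band_edges,
            cross_excitation=cross_excitation,
        )
        um = sf.unmix(stack, d_ref, a_ref)
        x[i] = sf.fret_index_integral(um)

    def model(xx, a, b, c):
        return a + b * xx / (xx + c)

    try:
        popt, _ = curve_fit(
            model, x, e_grid, p0=(0.0, 1.0, float(np.median(x[x > 0])) or 1.0),
            maxfev=20000,
        )
    except RuntimeError as exc:  # pragma: no cover - defensive
        raise ConvergenceError(f"transfer-function fit did not converge: {exc}")
    resid = e_grid - model(x, *popt)
    ss_tot = float(np.sum((e_grid - e_grid.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    if not r2 > 0.99:
        warnings.warn(f"transfer-function fit quality low: R^2 = {r2:.4f}")
    prov = (
        f"fitted(donor={donor.name}, acceptor={acceptor.name}, laser={laser}, "
        f"n_bands={len(band_edges) - 1}, n_grid={e_grid.size})"
    )
    return TransferFunction(*popt, r_squared=r2, provenance=prov)


def invert_transfer(tf: TransferFunction, efficiency):
    """Analytic inverse of the transfer function: x = c (E-a) / (a+b-E).

    Defined on the open interval a < E < a + b.
    """
    e = np.asarray(efficiency, dtype=float)
    if np.any(e <= tf.a) or np.any(e >= tf.a + tf.b):
        raise ParameterError(
            f"efficiency outside invertible range ({tf.a}, {tf.a + tf.b})"
        )
    x = tf.c * (e - tf.a) / (tf.a + tf.b - e)
    return float(x) if np.ndim(efficiency) == 0 else x
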