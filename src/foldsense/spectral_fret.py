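"""Quantify FRET from multi-band emission spectra.

The measurement chain mirrors spectral confocal practice: a 32-band emission
stack (5-nm bands, 450-610 nm) is unmixed against donor/acceptor reference
emission shapes with non-negative least squares, a FRET index is computed
either as the ratio of unmixed integrals or as a peak-emission ratio, samples
are gated on an expression window, and a calibrated transfer function
E = a + b*x/(x+c) maps the index to FRET efficiency.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import ParameterError, UndefinedIndexError

logger = logging.getLogger(__name__)

#: Default detection bands: 32 contiguous 5-nm bands covering 450-610 nm.
DEFAULT_BAND_EDGES = np.arange(450.0, 615.0, 5.0)


def default_band_edges() -> np.ndarray:
    """Return a fresh copy of the 32-band default edge grid (33 edges)."""
    return DEFAULT_BAND_EDGES.copy()


@dataclass
class SpectralStack:
    """Multi-band emission intensities for one or more samples/pixels.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_bands)
        Emission intensity per sample and band, arbitrary units.
    band_edges : ndarray, shape (n_bands + 1,)
        Strictly increasing, contiguous band edges in nm.
    laser : float
        Excitation laser line in nm.
    label : str
        Free-text acquisition label.
    truth : dict or None
        Optional ground truth carried alongside simulated stacks.
    """

    data: np.ndarray
    band_edges: np.ndarray
    laser: float
    label: str = ""
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.band_edges = np.asarray(self.band_edges, dtype=float)
        if self.data.shape[1] != self.band_edges.size - 1:
            raise ParameterError(
                f"data has {self.data.shape[1]} bands but band_edges defines "
                f"{self.band_edges.size - 1}"
            )
        if np.any(np.diff(self.band_edges) <= 0):
            raise ParameterError("band_edges must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_bands(self) -> int:
        return self.data.shape[1]

    @property
    def band_centers(self) -> np.ndarray:
        return 0.5 * (self.band_edges[:-1] + self.band_edges[1:])

    def clipped(self) -> "SpectralStack":
        """Return a copy with negative intensities clipped to zero."""
        return SpectralStack(
            np.clip(self.data, 0.0, None), self.band_edges.copy(), self.laser,
            self.label, self.truth,
        )


@dataclass
class UnmixResult:
    """Per-sample non-negative decomposition into two reference shapes."""

    donor_coeff: np.ndarray
    acceptor_coeff: np.ndarray
    residual_norm: np.ndarray
    condition_number: float
    references: np.ndarray  # (2, n_bands), rows = donor, acceptor


@dataclass
class FretMeasurement:
    """A FRET index and the efficiency derived from it."""

    fret_index: float
    efficiency: float
    method: str  # "integral_405" | "peak_ratio"
    clamped: bool = False
    bands: tuple | None = None


def unmix(
    stack: SpectralStack,
    donor_ref: np.ndarray,
    acceptor_ref: np.ndarray,
    *,
    normalize_refs: bool = True,
    max_condition: float = 1e6,
) -> UnmixResult:
    """Non-negative least-squares unmixing of a stack against two references.

    References are emission shapes sampled on the stack's bands (as measured
    from samples expressing donor or acceptor alone).  With
    ``normalize_refs=True`` each reference is scaled to unit sum over the
    detection bands, the common convention for measured reference shapes, so
    the returned coefficients are total detected intensities per fluorophore.

    Raises
    ------
    ParameterError
        If reference grids mismatch the stack or the reference matrix is
        near-collinear (condition number above ``max_condition``).
    """
    d_ref = np.asarray(donor_ref, dtype=float)
    a_ref = np.asarray(acceptor_ref, dtype=float)
    if d_ref.shape != (stack.n_bands,) or a_ref.shape != (stack.n_bands,):
        raise ParameterError(
            "reference shapes must be sampled on the stack's bands "
            f"(expected length {stack.n_bands})"
        )
    if normalize_refs:
        d_ref = d_ref / d_ref.sum()
        a_ref = a_ref / a_ref.sum()
    A = np.column_stack([d_ref, a_ref])
    cond = np.linalg.cond(A)
    if cond > max_condition:
        raise ParameterError(
            f"references are near-collinear (condition number {cond:.3g})"
        )
    n = stack.n_samples
    donor = np.empty(n)
    acceptor = np.empty(n)
    resid = np.empty(n)
    for i in range(n):
        coeffs, r = nnls(A, stack.data[i])
        donor[i], acceptor[i] = coeffs
        resid[i] = r
    return UnmixResult(donor, acceptor, resid, cond, np.vstack([d_ref, a_ref]))


def fret_index_integral(
    um: UnmixResult,
    donor_ref_area: float = 1.0,
    acceptor_ref_area: float = 1.0,
) -> np.ndarray | float:
    """FRET index as the ratio of unmixed emission integrals.

    index = (acceptor_coeff * acceptor reference area)
          / (donor_coeff * donor reference area)

    With unit-area references this reduces to the coefficient ratio.  Samples
    with zero donor coefficient have no defined index: a scalar input raises
    :class:`UndefinedIndexError`; in arrays the sample is excluded (NaN) and
    logged.
    """
    d = np.atleast_1d(np.asarray(um.donor_coeff, dtype=float))
    a = np.atleast_1d(np.asarray(um.acceptor_coeff, dtype=float))
    # a donor coefficient at numerical zero leaves the index undefined
    bad = d <= 1e-12 * np.maximum(a, 1.0)
    if bad.all() and d.size == 1:
        raise UndefinedIndexError("donor coefficient is zero; index undefined")
    out = np.full(d.shape, np.nan)
    np.divide(a * acceptor_ref_area, d * donor_ref_area, out=out, where=~bad)
    if bad.any():
        logger.warning(
            "%d sample(s) excluded from FRET index: zero donor coefficient",
            int(bad.sum()),
        )
    return float(out[0]) if out.size == 1 else out


def fret_index_peak(
    wavelengths: np.ndarray,
    intensities: np.ndarray,
    donor_band: tuple[float, float],
    acceptor_band: tuple[float, float],
) -> float:
    """Peak-ratio FRET index: mean acceptor-band / mean donor-band intensity.

    Bands are half-open intervals [lo, hi) in nm so that band membership is
    unambiguous on a regular grid.
    """
    wl = np.asarray(wavelengths, dtype=float)
    iv = np.asarray(intensities, dtype=float)

    def band_mean(band):
        lo, hi = band
        if lo >= hi:
            raise ParameterError(f"band {band} is empty")
        mask = (wl >= lo) & (wl < hi)
        if not mask.any():
            raise ParameterError(f"band {band} contains no grid points")
        return iv[mask].mean()

    donor = band_mean(donor_band)
    if donor <= 0:
        raise UndefinedIndexError("zero donor-band signal; index undefined")
    return band_mean(acceptor_band) / donor


def qc_expression_window(
    fret_channel: np.ndarray,
    acceptor_channel: np.ndarray,
    low: float = 20.0,
    high: float = 170.0,
    *,
    inclusive: bool = True,
) -> np.ndarray:
    """Expression-window gate on two per-sample channel summaries.

    A sample is included iff both summaries (emission under the FRET laser and
    under the acceptor laser) fall in [low, high].  Boundaries are inclusive by
    default; set ``inclusive=False`` for the open-interval convention.
    """
    f = np.asarray(fret_channel, dtype=float)
    a = np.asarray(acceptor_channel, dtype=float)
    if f.shape != a.shape:
        raise ParameterError("channel summaries must have matching shapes")
    if inclusive:
        return (f >= low) & (f <= high) & (a >= low) & (a <= high)
    return (f > low) & (f < high) & (a > low) & (a < high)


def apply_transfer(tf, fret_index, *, clamp: bool = False):
    """Map FRET index to efficiency through E = a + b*x/(x+c).

    ``tf`` is any object with attributes a, b, c (see
    :class:`foldsense.forster.TransferFunction`).  Clamping to [0, 1] is off by
    default so that negative intercepts remain visible; when on, the clamp is
    applied after evaluation.
    """
    if tf.c <= 0:
        raise ParameterError("invalid transfer function: c must be positive")
    x = np.asarray(fret_index, dtype=float)
    e = tf.a + tf.b * x / (x + tf.c)
    if clamp:
        e = np.clip(e, 0.0, 1.0)
    return float(e) if np.ndim(fret_index) == 0 else e


def band_ratio(intensity_a: float, intensity_b: float) -> float:
    """Ratio of two band intensities, a/b.  Shared densitometry kernel."""
    if intensity_b == 0:
        raise ParameterError("denominator intensity is zero")
    return intensity_a / intensity_b
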