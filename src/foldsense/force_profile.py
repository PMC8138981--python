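"""Arrest-peptide force-profile assembly and solubility quantification.

A stalled (arrested) construct yields a truncated product carrying only the
N-terminal donor fluorophore; a full-length product carries both donor and
acceptor.  The acceptor/donor peak-emission ratio therefore reads out the
full-length fraction per construct, and plotting it against tether length
gives a co-translational folding force profile.  Solubility is quantified as
the supernatant fraction of gel band intensities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .spectral_fret import band_ratio, fret_index_peak

#: Default emission-peak bands (nm) for the donor (mTFP1) and acceptor
#: (mcpVenus) reporters; half-open [lo, hi).
DONOR_PEAK_BAND = (489.5, 494.5)
ACCEPTOR_PEAK_BAND = (525.5, 530.5)


@dataclass
class FPAConstruct:
    """One replicate measurement of one tether-length construct.

    ``tether_length`` counts residues from the C-terminal conserved proline
    of the arrest peptide, arrest-peptide residues included.
    """

    construct_id: str
    tether_length: int
    condition: str
    replicate: int
    donor_peak: float
    acceptor_peak: float

    def __post_init__(self) -> None:
        if self.tether_length <= 0:
            raise ParameterError("tether_length must be positive")


@dataclass
class ForceProfile:
    """Replicate-averaged full-length ratio vs tether length."""

    tether_lengths: np.ndarray
    ratios: np.ndarray
    sd: np.ndarray              # NaN where only one replicate exists
    n_replicates: np.ndarray
    condition: str

    def __post_init__(self) -> None:
        self.tether_lengths = np.asarray(self.tether_lengths)
        self.ratios = np.asarray(self.ratios, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_replicates = np.asarray(self.n_replicates)
        if np.any(np.diff(self.tether_lengths) <= 0):
            raise ParameterError("tether lengths must be strictly increasing")
        if np.any(self.ratios < 0):
            raise ParameterError("ratios must be non-negative")


def full_length_fraction(donor_peak: float, acceptor_peak: float) -> float:
    """Full-length readout: acceptor-peak / donor-peak intensity.

    A purely truncated product emits no acceptor signal and returns 0.
    """
    if donor_peak <= 0:
        raise ParameterError("donor peak intensity must be positive")
    return band_ratio(acceptor_peak, donor_peak)


def full_length_fraction_spectrum(
    wavelengths: np.ndarray,
    intensities: np.ndarray,
    donor_band: tuple[float, float] = DONOR_PEAK_BAND,
    acceptor_band: tuple[float, float] = ACCEPTOR_PEAK_BAND,
) -> float:
    """Full-length readout from an emission spectrum via peak-band means."""
    return fret_index_peak(wavelengths, intensities, donor_band, acceptor_band)


def build_profile(constructs: list[FPAConstruct]) -> ForceProfile:
    """Aggregate per-replicate constructs into a force profile.

    Ratios are averaged per tether length with the sample sd (ddof=1) across
    replicates; a single replicate has sd marked unavailable (NaN), never 0.
    Mixed conditions or duplicate construct ids are errors; input order is
    irrelevant.
    """
    if len({c.tether_length for c in constructs}) < 2:
        raise ParameterError("need at least 2 distinct tether lengths")
    conditions = {c.condition for c in constructs}
    if len(conditions) != 1:
        raise ParameterError(f"mixed conditions in one profile: {sorted(conditions)}")
    ids = [c.construct_id for c in constructs]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParameterError(f"duplicate construct ids: {dupes}")

    by_length: dict[int, list[float]] = {}
    for c in constructs:
        ratio = full_length_fraction(c.donor_peak, c.acceptor_peak)
        by_length.setdefault(c.tether_length, []).append(ratio)
    lengths = np.array(sorted(by_length))
    means = np.array([np.mean(by_length[L]) for L in lengths])
    sds = np.array([
        np.std(by_length[L], ddof=1) if len(by_length[L]) > 1 else math.nan
        for L in lengths
    ])
    n_rep = np.array([len(by_length[L]) for L in lengths])
    return ForceProfile(lengths, means, sds, n_rep, conditions.pop())


def profile_peak(profile: ForceProfile, k: float = 2.0):
    """Tether length of the unique significant maximum, or None.

    The maximum (interior or boundary) is significant when it exceeds every
    neighbouring point by at least ``k`` times the pooled replicate sd of the
    two points compared (quadrature sum; unavailable sds count as zero).  A
    tied maximum or any failed comparison returns None, the "no resolvable
    peak" outcome.
    """
    r = profile.ratios
    if r.size < 3:
        raise ParameterError("profile needs at least 3 points")
    i = int(np.argmax(r))
    if np.sum(np.isclose(r, r[i], rtol=0.0, atol=1e-12)) > 1:
        return None
    for j in (i - 1, i + 1):
        if j < 0 or j >= r.size:
            continue
        s_i = 0.0 if math.isnan(profile.sd[i]) else profile.sd[i]
        s_j = 0.0 if math.isnan(profile.sd[j]) else profile.sd[j]
        pooled = math.hypot(s_i, s_j)
        if r[i] - r[j] < k * pooled or r[i] <= r[j]:
            return None
    return profile.tether_lengths[i]


def soluble_fraction(supernatant_intensity: float, pellet_intensity: float) -> float:
    """Soluble fraction SN / (SN + P) from gel band intensities."""
    if supernatant_intensity < 0 or pellet_intensity < 0:
        raise ParameterError("band intensities must be non-negative")
    total = supernatant_intensity + pellet_intensity
    if total == 0:
        raise ParameterError("both band intensities are zero")
    return supernatant_intensity / total
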