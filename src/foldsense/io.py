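"""File formats: CSV spectra and tables, multi-page TIFF stacks, PDB, JSON.

Conventions
-----------
- Spectra CSV: columns wavelength_nm, excitation, emission, extinction.  On
  load the emission is renormalized to unit area, the excitation to unit
  maximum, and the peak of the extinction column becomes the extinction
  coefficient.
- Stacks: multi-page TIFF (page k = band [450+5k, 455+5k) nm by default) with
  band edges and laser stored in the image description, or long-format CSV
  (sample, band, wavelength_lo, wavelength_hi, intensity).
- Angle trajectories: CSV (frame, theta_deg).
- PMFs: CSV (bin_center_deg, free_energy_kcal, defined_flag).
- Transfer functions: JSON {a, b, c, r_squared, provenance}.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conformation import PMF, AngleTrajectory
from .errors import ParameterError
from .force_profile import FPAConstruct, ForceProfile
from .forster import TransferFunction
from .spectral_fret import SpectralStack
from .synthetic_data import FluorophoreSpectrum


# -- spectra ---------------------------------------------------------------

def write_spectrum_csv(spectrum: FluorophoreSpectrum, path) -> None:
    ext = spectrum.extinction_coeff * spectrum.excitation
    pd.DataFrame({
        "wavelength_nm": spectrum.wavelengths,
        "excitation": spectrum.excitation,
        "emission": spectrum.emission,
        "extinction": ext,
    }).to_csv(path, index=False)


def read_spectrum_csv(path, name=None, quantum_yield=1.0) -> FluorophoreSpectrum:
    df = pd.read_csv(path)
    required = {"wavelength_nm", "excitation", "emission", "extinction"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"spectrum CSV missing columns: {sorted(missing)}")
    wl = df["wavelength_nm"].to_numpy(float)
    ex = df["excitation"].to_numpy(float)
    em = df["emission"].to_numpy(float)
    ext = df["extinction"].to_numpy(float)
    em = em / np.trapezoid(em, wl)
    ex = ex / ex.max()
    return FluorophoreSpectrum(
        name or Path(path).stem, wl, ex, em, quantum_yield, float(ext.max())
    )


# -- spectral stacks -------------------------------------------------------

def write_stack_tiff(stack: SpectralStack, path) -> None:
    """Write one page per band (shape (n_samples, 1) images)."""
    import tifffile

    meta = {"band_edges": stack.band_edges.tolist(), "laser": stack.laser,
            "label": stack.label}
    pages = stack.data.T[:, :, None].astype(np.float32)  # (bands, samples, 1)
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_stack_tiff(path) -> SpectralStack:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        pages = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    data = pages.reshape(pages.shape[0], -1).T
    return SpectralStack(
        data, np.asarray(meta["band_edges"]), meta["laser"], meta.get("label", "")
    )


def write_stack_csv(stack: SpectralStack, path) -> None:
    n, b = stack.data.shape
    sample = np.repeat(np.arange(n), b)
    band = np.tile(np.arange(b), n)
    pd.DataFrame({
        "sample": sample,
        "band": band,
        "wavelength_lo": stack.band_edges[:-1][band],
        "wavelength_hi": stack.band_edges[1:][band],
        "intensity": stack.data.ravel(),
        "laser": stack.laser,
    }).to_csv(path, index=False)


def read_stack_csv(path) -> SpectralStack:
    df = pd.read_csv(path)
    n = int(df["sample"].max()) + 1
    b = int(df["band"].max()) + 1
    data = np.empty((n, b))
    data[df["sample"], df["band"]] = df["intensity"]
    first = df.sort_values("band").drop_duplicates("band")
    edges = np.append(first["wavelength_lo"].to_numpy(float),
                      first["wavelength_hi"].to_numpy(float)[-1])
    return SpectralStack(data, edges, float(df["laser"].iloc[0]))


# -- trajectories and PMFs -------------------------------------------------

def write_trajectory_csv(traj: AngleTrajectory, path) -> None:
    pd.DataFrame({
        "frame": np.arange(len(traj)), "theta_deg": traj.theta,
    }).to_csv(path, index=False)


def read_trajectory_csv(path, dt: float = 1.0) -> AngleTrajectory:
    df = pd.read_csv(path)
    return AngleTrajectory(
        df["theta_deg"].to_numpy(float), dt=dt, provenance=f"file:{path}"
    )


def write_pmf_csv(pmf: PMF, path) -> None:
    pd.DataFrame({
        "bin_center_deg": pmf.bin_centers,
        "free_energy_kcal": pmf.free_energy,
        "defined_flag": pmf.defined.astype(int),
    }).to_csv(path, index=False)


# -- structures ------------------------------------------------------------

def write_pdb(atoms, path) -> None:
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_pdb(path, model: int | None = None):
    import biotite.structure.io.pdb as pdb

    return pdb.PDBFile.read(str(path)).get_structure(model=model or 1)


# -- force-field parameters ------------------------------------------------

def read_param_csv(path) -> dict:
    """Read a parameter table CSV (atom_name, charge_e, epsilon_kcal,
    rmin_half_A) into a name -> (q, eps, rmin/2) mapping."""
    df = pd.read_csv(path)
    required = {"atom_name", "charge_e", "epsilon_kcal", "rmin_half_A"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"parameter CSV missing columns: {sorted(missing)}")
    return {
        str(r.atom_name): (float(r.charge_e), float(r.epsilon_kcal),
                           float(r.rmin_half_A))
        for r in df.itertuples()
    }


# -- force profiles --------------------------------------------------------

def read_constructs_csv(path) -> list[FPAConstruct]:
    df = pd.read_csv(path)
    required = {"construct_id", "tether_length", "condition", "replicate",
                "donor_peak", "acceptor_peak"}
    missing = required - set(df.columns)
    if missing:
        raise ParameterError(f"construct CSV missing columns: {sorted(missing)}")
    return [
        FPAConstruct(
            str(r.construct_id), int(r.tether_length), str(r.condition),
            int(r.replicate), float(r.donor_peak), float(r.acceptor_peak),
        )
        for r in df.itertuples()
    ]


def write_profile_csv(profile: ForceProfile, path) -> None:
    pd.DataFrame({
        "tether_length": profile.tether_lengths,
        "full_length_ratio": profile.ratios,
        "sd": profile.sd,
        "n_replicates": profile.n_replicates,
        "condition": profile.condition,
    }).to_csv(path, index=False)


# -- transfer functions ----------------------------------------------------

def write_transfer_json(tf: TransferFunction, path) -> None:
    with open(path, "w") as fh:
        json.dump({"a": tf.a, "b": tf.b, "c": tf.c, "r_squared": tf.r_squared,
                   "provenance": tf.provenance}, fh, indent=2, sort_keys=True)


def read_transfer_json(path) -> TransferFunction:
    with open(path) as fh:
        d = json.load(fh)
    return TransferFunction(
        d["a"], d["b"], d["c"], d.get("r_squared"),
        d.get("provenance", f"file:{path}"),
    )
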