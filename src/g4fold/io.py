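"""File writers and readers beyond the 3-column .dat format.

PDB bead models go through biotite (one pseudo-atom per bead);
time-resolved and spectral series are stored as plain CSV matrices.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from biotite.structure import Atom, array as atom_array
from biotite.structure.io.pdb import PDBFile

from .datatypes import BeadModel, ScatteringCurve, ScatteringSeries, SpectraSeries


def write_pdb_beads(model: BeadModel, path) -> None:
    """Write a bead model as pseudo-atoms (one P per bead, chain A)."""
    atoms = []
    for i in range(model.n_beads):
        atoms.append(
            Atom(
                model.coords[i],
                atom_name="P",
                element="P",
                res_id=i + 1,
                res_name="BEA",
                chain_id="A",
                hetero=True,
            )
        )
    pdb = PDBFile()
    pdb.set_structure(atom_array(atoms))
    pdb.write(path)


def read_pdb_beads(path, bead_radius: float = 4.0) -> BeadModel:
    """Read pseudo-atom coordinates back into a bead model."""
    pdb = PDBFile.read(path)
    structure = pdb.get_structure(model=1)
    return BeadModel(
        coords=structure.coord,
        radii=np.full(len(structure), bead_radius),
        labels=[f"{rn}{ri}" for rn, ri in zip(structure.res_name, structure.res_id)],
    )


def series_to_csv(series: ScatteringSeries, path) -> None:
    """times x q intensity matrix as CSV (first column q, one column per time)."""
    df = pd.DataFrame(
        series.intensity_matrix(),
        index=pd.Index(series.q, name="q"),
        columns=[f"{t:.8g}" for t in series.times],
    )
    df.to_csv(path)


def series_from_csv(path, noise_frac: float = 0.01) -> ScatteringSeries:
    """Read a q x times CSV back into a series; sigma is reconstructed as
    noise_frac * |I| (CSV matrices carry no uncertainty column)."""
    df = pd.read_csv(path, index_col=0)
    q = df.index.to_numpy(dtype=float)
    times = np.array([float(c) for c in df.columns])
    curves = []
    for j, t in enumerate(times):
        I = df.iloc[:, j].to_numpy(dtype=float)
        sigma = np.maximum(noise_frac * np.abs(I), 1e-12 * np.max(np.abs(I)))
        curves.append(ScatteringCurve(q, I, sigma, label=f"t={t:g}s"))
    return ScatteringSeries(times=times, curves=curves)


def spectra_to_csv(series: SpectraSeries, path) -> None:
    """wavelengths x times matrix as CSV (first column wavelength)."""
    df = pd.DataFrame(
        series.values,
        index=pd.Index(series.wavelengths, name="wavelength_nm"),
        columns=[f"{t:.8g}" for t in series.times],
    )
    df.to_csv(path)


def spectra_from_csv(path) -> SpectraSeries:
    df = pd.read_csv(path, index_col=0)
    return SpectraSeries(
        wavelengths=df.index.to_numpy(dtype=float),
        times=np.array([float(c) for c in df.columns]),
        values=df.to_numpy(dtype=float),
    )
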