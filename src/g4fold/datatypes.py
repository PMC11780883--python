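"""Shared data containers for the SAXS/CD folding pipeline.

The universal currency is the one-dimensional scattering profile
(momentum transfer q in 1/Angstrom, intensity I in arbitrary units,
per-point uncertainty sigma).  Time-resolved experiments stack profiles
that share one q-grid; CD kinetics stack spectra that share one
wavelength grid.  Coarse-grained coordinate models (one bead per
nucleotide) stand in for atomic conformers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class BeadModel:
    """Coarse-grained coordinate model: one spherical bead per residue."""

    coords: np.ndarray  # (N, 3) Angstrom
    radii: np.ndarray  # (N,) Angstrom, all > 0
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = _as_float_array(self.coords, "coords").reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("BeadModel needs at least one bead")
        self.radii = np.broadcast_to(
            _as_float_array(self.radii, "radii"), (n,)
        ).copy()
        if np.any(self.radii <= 0):
            raise ValueError("bead radii must be positive")
        if not self.labels:
            self.labels = [f"B{i+1}" for i in range(n)]
        if len(self.labels) != n:
            raise ValueError("labels length must match bead count")

    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]


@dataclass
class ScatteringCurve:
    """One (q, I, sigma) scattering profile."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        self.q = _as_float_array(self.q, "q")
        self.I = _as_float_array(self.I, "I")
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if self.q.size == 0:
            raise ValueError("empty q grid")
        if np.any(self.q < 0):
            raise ValueError("q must be non-negative")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = _as_float_array(self.sigma, "sigma")
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive wherever present")

    def __len__(self) -> int:
        return self.q.size

    def require_sigma(self) -> np.ndarray:
        if self.sigma is None:
            raise ValueError(f"curve {self.label!r} carries no uncertainties")
        return self.sigma

    def copy(self) -> "ScatteringCurve":
        return ScatteringCurve(
            self.q.copy(),
            self.I.copy(),
            None if self.sigma is None else self.sigma.copy(),
            self.label,
        )


@dataclass
class ScatteringSeries:
    """Time-stamped stack of scattering curves on one shared q-grid."""

    times: np.ndarray  # seconds, strictly increasing
    curves: list[ScatteringCurve]

    def __post_init__(self) -> None:
        self.times = _as_float_array(self.times, "times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.curves) != self.times.size:
            raise ValueError("one curve per time point required")
        q0 = self.curves[0].q
        for c in self.curves[1:]:
            if c.q.shape != q0.shape or not np.allclose(c.q, q0):
                raise ValueError("all curves must share one q-grid")

    @property
    def q(self) -> np.ndarray:
        return self.curves[0].q

    def intensity_matrix(self) -> np.ndarray:
        """(n_q, n_t) intensity matrix."""
        return np.column_stack([c.I for c in self.curves])

    def sigma_matrix(self) -> np.ndarray:
        """(n_q, n_t) uncertainty matrix (requires sigma on every frame)."""
        return np.column_stack([c.require_sigma() for c in self.curves])

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SpectraSeries:
    """Wavelength x time matrix of CD spectra (mdeg or delta-epsilon)."""

    wavelengths: np.ndarray  # nm, strictly increasing
    times: np.ndarray  # s, strictly increasing
    values: np.ndarray  # (n_wavelength, n_time)

    def __post_init__(self) -> None:
        self.wavelengths = _as_float_array(self.wavelengths, "wavelengths")
        self.times = _as_float_array(self.times, "times")
        self.values = _as_float_array(self.values, "values")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (self.wavelengths.size, self.times.size):
            raise ValueError("values must be (n_wavelength, n_time)")
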