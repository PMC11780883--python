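"""Hydrophobic-collapse energetics of oligonucleotide folding.

The unfolded chain's conformational freedom (about seven rotameric
states per backbone unit) opposes folding with an entropic barrier
dG_conf = -T dS; the driving force is hydrophobic: burying solvent
accessible surface area (SASA) releases heat capacity, dCp = 0.134 dSASA
(cal/K-mol per A^2), and the Spolar-Record relation dG_hyd = 80 dCp
converts that into a hydrophobic free energy.  Sign convention is the
folding direction: buried surface, released heat capacity and the
hydrophobic free energy are all negative.

Units: entropies and heat capacities in cal/(K mol), free energies in
kcal/mol, areas in A^2.  All cal <-> kcal conversion lives in
CAL_PER_KCAL; it is never inlined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

GAS_CONSTANT_CAL = 1.987  # cal/(K mol)
CAL_PER_KCAL = 1000.0
SPOLAR_RECORD_SLOPE = 80.0  # dG_hyd (cal/mol) per dCp (cal/K-mol)
DCP_PER_DSASA = 0.134  # cal/(K mol) per A^2 (Hadzi-Lah correlation)
DEFAULT_T = 298.15  # K


@dataclass
class ThermoResult:
    S_conf: float  # cal/(K mol)
    dG_conf: float  # kcal/mol, positive barrier
    dCp: float  # cal/(K mol)
    dG_hyd: float  # kcal/mol
    dSASA: float  # A^2 (negative when folding buries surface)
    T: float  # K
    provenance: dict = field(default_factory=dict)


def conformational_entropy(n: int, states_per_unit: int = 7) -> float:
    """Boltzmann conformational entropy S = R (n-1) ln(states_per_unit)
    of an n-unit chain, in cal/(K mol)."""
    if n < 1 or states_per_unit < 1:
        raise ValueError("n and states_per_unit must be >= 1")
    return GAS_CONSTANT_CAL * (n - 1) * np.log(states_per_unit)


def entropic_barrier(dS: float, T: float = DEFAULT_T) -> float:
    """Free-energy barrier dG_conf = T dS (kcal/mol), reported as a
    positive barrier for a positive unfolded-state entropy."""
    if T <= 0:
        raise ValueError("T must be positive")
    return T * dS / CAL_PER_KCAL


def hydrophobic_dG(dCp: float) -> float:
    """Spolar-Record hydrophobic free energy dG_hyd = 80 dCp, in kcal/mol
    for dCp in cal/(K mol)."""
    return SPOLAR_RECORD_SLOPE * dCp / CAL_PER_KCAL


def dcp_from_dsasa(dSASA: float) -> float:
    """Heat-capacity change from buried surface area: dCp = 0.134 dSASA."""
    return DCP_PER_DSASA * dSASA


def dsasa_from_dcp(dCp: float) -> float:
    """Exact inverse of dcp_from_dsasa."""
    return dCp / DCP_PER_DSASA


def weighted_dsasa(ensemble_sasas, weights, folded_sasa: float) -> float:
    """Change in SASA upon collapse, folded minus ensemble-weighted
    unfolded: dSASA = SASA_folded - sum_i w_i SASA_i (negative when the
    collapse buries surface)."""
    sasas = np.asarray(ensemble_sasas, dtype=float)
    w = np.asarray(weights, dtype=float)
    if sasas.shape != w.shape:
        raise ValueError("sasas and weights must have equal length")
    if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must be non-negative and sum to 1")
    return float(folded_sasa - np.sum(w * sasas))


def collapse_energetics(
    n: int = 24,
    dS_measured: float | None = None,
    dCp_measured: float | None = None,
    ensemble_sasas=None,
    weights=None,
    folded_sasa: float | None = None,
    T: float = DEFAULT_T,
) -> ThermoResult:
    """Full energetic account of the collapse.

    dSASA comes from the EOM-weighted ensemble when SASA inputs are given,
    otherwise from the measured dCp through the Hadzi-Lah inverse; dCp
    follows from dSASA unless a calorimetric value is supplied; dG_hyd
    follows from dCp; the entropic barrier uses the measured unfolding
    entropy when available, else the chain estimate.
    """
    S_conf = conformational_entropy(n)
    prov: dict[str, str] = {"S_conf": "chain estimate, 7 states/unit"}
    if ensemble_sasas is not None:
        dSASA = weighted_dsasa(ensemble_sasas, weights, folded_sasa)
        prov["dSASA"] = "ensemble-weighted SASA difference"
        dCp = dCp_measured if dCp_measured is not None else dcp_from_dsasa(dSASA)
        prov["dCp"] = "measured" if dCp_measured is not None else "from dSASA"
    elif dCp_measured is not None:
        dCp = dCp_measured
        dSASA = dsasa_from_dcp(dCp)
        prov["dCp"] = "measured"
        prov["dSASA"] = "from measured dCp"
    else:
        raise ValueError("need either SASA inputs or a measured dCp")
    dS = dS_measured if dS_measured is not None else S_conf
    prov["dS"] = "measured" if dS_measured is not None else "chain estimate"
    return ThermoResult(
        S_conf=float(S_conf),
        dG_conf=float(entropic_barrier(dS, T)),
        dCp=float(dCp),
        dG_hyd=float(hydrophobic_dG(dCp)),
        dSASA=float(dSASA),
        T=T,
        provenance=prov,
    )
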