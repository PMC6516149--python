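"""Thermodynamically balanced ODE model of neuronal oxidative phosphorylation.

The model follows the Beard family of mitochondrial respiratory-chain models:
every reaction/transport flux is written as an activity constant multiplying a
mass-action bracket whose apparent equilibrium constant is assembled from the
standard free energy of the reaction, the proton-motive terms (F*dpsi and the
transmembrane pH gradient) and the chemical protons consumed or released in the
matrix.  A flux is therefore exactly zero at its thermodynamic equilibrium and
its sign always equals the sign of its driving force.  A cytosolic ATP-turnover
flux closes the energy budget so the model describes an intact neuron rather
than an isolated mitochondrion.

Compartments: matrix (x), intermembrane space (i), cytosol (c).  The outer
membrane is modelled as a fast permeation barrier for adenine nucleotides and
phosphate.  Oxygen is held constant (plate and imaging experiments run at
saturating O2).

Units are SI throughout: concentrations in M, time in s, membrane potential in
mV (with the Faraday constant expressed in kJ mol^-1 mV^-1 so free energies are
in kJ/mol).  Reporting layers convert to mV, minutes and fold changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.integrate import solve_ivp
from scipy.optimize import root

__all__ = [
    "ModelParameters",
    "ModelState",
    "FluxVector",
    "TimeCourse",
    "compute_fluxes",
    "time_derivatives",
    "simulate",
    "find_steady_state",
    "load_profile",
    "wtsim_parameters",
    "wtsim_initial_state",
    "STATE_NAMES",
    "FLUX_NAMES",
    "ACTIVITY_NAMES",
]

# ---------------------------------------------------------------------------
# constants and naming
# ---------------------------------------------------------------------------

STATE_NAMES: tuple[str, ...] = (
    "dpsi", "NADH_x", "QH2", "Cred",
    "ATP_x", "ADP_x", "Pi_x",
    "ATP_i", "ADP_i", "Pi_i",
    "ATP_c", "ADP_c", "Pi_c",
    "H_x", "K_x", "Mg_x",
)

FLUX_NAMES: tuple[str, ...] = (
    "J_DH", "J_C1", "J_C3", "J_C4", "J_F1", "J_ANT",
    "J_Hle", "J_PiH", "J_KH", "J_AK", "J_ATPase_c",
)

#: activity constants, one per modelled flux
ACTIVITY_NAMES: tuple[str, ...] = (
    "X_DH", "X_C1", "X_C3", "X_C4", "X_F1", "X_ANT",
    "X_Hle", "X_PiH", "X_KH", "X_AK", "X_ATPase_c",
)

#: typical magnitudes used to scale solver tolerances and root-finder residuals
_STATE_SCALE = np.array([
    150.0,    # dpsi (mV)
    1e-3,     # NADH_x
    1e-3,     # QH2
    1e-3,     # Cred
    3e-3,     # ATP_x
    5e-3,     # ADP_x
    2e-3,     # Pi_x
    2e-3,     # ATP_i
    5e-4,     # ADP_i
    2e-3,     # Pi_i
    2e-3,     # ATP_c
    5e-4,     # ADP_c
    2e-3,     # Pi_c
    3e-8,     # H_x
    1e-1,     # K_x
    4e-4,     # Mg_x
])

_R_KJ = 8.314462618e-3      # kJ mol^-1 K^-1
_F_KJ_MV = 0.096484         # kJ mol^-1 mV^-1


class ModelError(ValueError):
    """Raised for invalid states, parameters or failed solver contracts."""


# ---------------------------------------------------------------------------
# parameter and state containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of the respiratory-chain model.

    Activity constants (``X_*``) carry the units that make each flux come out
    in mol s^-1 (l mito)^-1 given concentrations in M; pool totals and
    dissociation constants are in M; standard free energies in kJ/mol.
    """

    # --- flux activity constants ------------------------------------------
    X_DH: float = 0.002          # NADH delivery (substrate dehydrogenation)
    X_C1: float = 4.0          # complex I
    X_C3: float = 0.6         # complex III
    X_C4: float = 0.0003        # complex IV
    X_F1: float = 1.0           # F1Fo ATP synthase
    X_ANT: float = 0.03       # adenine nucleotide translocase
    X_Hle: float = 19.0           # proton leak
    X_PiH: float = 3.3914e5        # phosphate/H+ symport
    X_KH: float = 2.9802e7         # K+/H+ antiport
    X_AK: float = 0.0              # adenylate kinase (IMS); off by default
    X_ATPase_c: float = 0.00012    # cytosolic ATP consumption (saturable, max rate)

    # --- pool totals -------------------------------------------------------
    NADtot: float = 2.97e-3        # matrix NAD+ + NADH
    Qtot: float = 1.35e-3          # ubiquinone pool
    Ctot: float = 2.7e-3           # cytochrome c pool (IMS)

    # --- kinetic constants of the flux laws --------------------------------
    r_DH: float = 4.559            # NADH/NAD poise of the lumped dehydrogenase
    k_Pi1: float = 1.553e-4        # DH phosphate activation
    k_Pi2: float = 8.222e-4
    # membrane-potential coupling of the lumped NADH delivery: the flux
    # includes the electrogenic aspartate/glutamate carrier of the
    # malate-aspartate shuttle, so delivery capacity falls when the membrane
    # depolarises.  Sigmoid in dpsi: half-activation at dpsi_ref_DH, width
    # delta_psi_DH; essentially saturated (insensitive) at polarised basal
    # potentials.
    dpsi_ref_DH: float = 40.0
    delta_psi_DH: float = 30.0
    k_Pi3: float = 1.928e-4        # CIII phosphate activation
    k_Pi4: float = 2.531e-2
    # forward-saturation constants of the respiratory complexes (reversible
    # Michaelis-type denominators 1 + forward/k_sat): the complexes have a
    # finite turnover capacity, which bounds their flux under the large
    # thermodynamic driving forces reached at depolarised potentials
    k_sat_C1: float = 4.4e-05
    k_sat_C3: float = 9e-06
    k_sat_C4: float = 2.5
    K_AtC: float = 1.5e-4          # cytosolic ATPase Michaelis constant (M)
    k_O2: float = 1.2e-6           # CIV oxygen affinity
    k_mADP: float = 3.5e-6         # ANT external free-ADP affinity
    theta_ANT: float = 0.60        # ANT electrical partition
    k_PiH: float = 4.5082e-4       # Pi/H symport affinity
    Keq_AK: float = 0.4331         # adenylate kinase equilibrium

    # --- thermodynamic block ----------------------------------------------
    T: float = 310.15              # K
    dG_C1o: float = -69.37         # kJ/mol, per 2 e-
    dG_C3o: float = -32.53
    dG_C4o: float = -122.94
    dG_F1o: float = 36.03          # ATP synthesis
    n_A: float = 3.0               # H+ translocated per ATP by F1Fo
    K_DT: float = 24e-6            # Mg-ATP dissociation
    K_DD: float = 347e-6           # Mg-ADP dissociation
    pKa_ATP: float = 6.48
    pKa_ADP: float = 6.38
    pKa_Pi: float = 6.75

    # --- membrane / compartment geometry -----------------------------------
    CIM: float = 6.7568e-6         # inner-membrane capacitance, mol mV^-1 (l mito)^-1
    W_x: float = 0.6               # matrix water volume per l mito
    W_i: float = 0.066             # IMS water volume per l mito
    W_c: float = 15.0              # cytosolic water volume per l mito
    x_buff: float = 100.0          # matrix proton buffering (Beard form)
    x_AM: float = 100.0            # OMM permeation, ATP/ADP
    x_PM: float = 300.0            # OMM permeation, Pi

    # --- fixed boundary conditions -----------------------------------------
    O2: float = 2.6e-5             # dissolved oxygen, M (saturating, constant)
    pH_c: float = 7.2              # cytosolic / IMS pH (fixed)
    K_c: float = 0.14              # cytosolic K+
    Mg_c: float = 4.0e-4           # free cytosolic Mg2+
    AMP_c: float = 1.0e-5          # AMP seen by adenylate kinase (fixed)

    # ------------------------------------------------------------------
    @property
    def RT(self) -> float:
        return _R_KJ * self.T

    @property
    def F(self) -> float:
        return _F_KJ_MV

    @property
    def H_c(self) -> float:
        """Fixed cytosolic/IMS free proton concentration (M)."""
        return 10.0 ** (-self.pH_c)

    def activities(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in ACTIVITY_NAMES}

    def replace(self, **changes: float) -> "ModelParameters":
        return replace(self, **changes)

    def validate(self) -> None:
        for name in ACTIVITY_NAMES:
            if getattr(self, name) < 0:
                raise ModelError(f"activity constant {name} must be >= 0")
        for name in ("NADtot", "Qtot", "Ctot", "W_x", "W_i", "W_c", "CIM",
                     "T", "O2", "K_c", "Mg_c"):
            if getattr(self, name) <= 0:
                raise ModelError(f"parameter {name} must be > 0")

    # --- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ModelError(f"unknown parameter keys: {sorted(unknown)}")
        p = cls(**{k: float(v) for k, v in d.items()})
        p.validate()
        return p


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state (free concentrations, M; dpsi in mV)."""

    dpsi: float
    NADH_x: float
    QH2: float
    Cred: float
    ATP_x: float
    ADP_x: float
    Pi_x: float
    ATP_i: float
    ADP_i: float
    Pi_i: float
    ATP_c: float
    ADP_c: float
    Pi_c: float
    H_x: float
    K_x: float
    Mg_x: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: Sequence[float]) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(STATE_NAMES),):
            raise ModelError(f"state vector must have length {len(STATE_NAMES)}")
        return cls(**{n: float(v) for n, v in zip(STATE_NAMES, y)})

    @property
    def pH_x(self) -> float:
        return -math.log10(self.H_x)

    def redox_status(self, params: ModelParameters) -> float:
        """Matrix NADH/NAD+ ratio (pool size constant)."""
        nad = params.NADtot - self.NADH_x
        if nad <= 0:
            raise ModelError("NADH_x exceeds the NAD pool total")
        return self.NADH_x / nad

    def validate(self, params: ModelParameters) -> None:
        y = self.to_array()
        if not np.all(np.isfinite(y)):
            raise ModelError("non-finite state values")
        conc = y[1:]
        if np.any(conc < 0):
            bad = [STATE_NAMES[i + 1] for i in np.nonzero(conc < 0)[0]]
            raise ModelError(f"negative concentrations: {bad}")
        if self.NADH_x > params.NADtot * (1 + 1e-9):
            raise ModelError("NADH_x exceeds NADtot")
        if self.QH2 > params.Qtot * (1 + 1e-9):
            raise ModelError("QH2 exceeds Qtot")
        if self.Cred > params.Ctot * (1 + 1e-9):
            raise ModelError("Cred exceeds Ctot")


@dataclass(frozen=True)
class FluxVector:
    """Signed reaction/transport rates, mol s^-1 (l mito)^-1."""

    J_DH: float
    J_C1: float
    J_C3: float
    J_C4: float
    J_F1: float
    J_ANT: float
    J_Hle: float
    J_PiH: float
    J_KH: float
    J_AK: float
    J_ATPase_c: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FLUX_NAMES], dtype=float)

    @classmethod
    def from_array(cls, j: Sequence[float]) -> "FluxVector":
        return cls(**{n: float(v) for n, v in zip(FLUX_NAMES, j)})


# ---------------------------------------------------------------------------
# core numerics (plain floats for speed inside the stiff solver)
# ---------------------------------------------------------------------------

def _exp(x: float) -> float:
    """exp with the argument capped; trial states explored by the stiff solver
    and the root finder can otherwise overflow the thermodynamic factors."""
    return math.exp(min(x, 500.0))


def _fluxes_raw(y: np.ndarray, p: ModelParameters) -> tuple[float, ...]:
    """All fluxes at state ``y``; returns the 11 named fluxes plus the three
    outer-membrane permeation fluxes (ATP, ADP, Pi; positive cytosol->IMS)."""
    (dpsi, NADH, QH2, Cred, ATP_x, ADP_x, Pi_x,
     ATP_i, ADP_i, Pi_i, ATP_c, ADP_c, Pi_c, H_x, K_x, Mg_x) = y

    RT = p.RT
    F = p.F
    H_i = p.H_c
    # pool complements; clipped at 0 so solver trial steps slightly outside
    # the pool bounds stay evaluable (public entry points validate first)
    NAD = max(p.NADtot - NADH, 0.0)
    Q = max(p.Qtot - QH2, 0.0)
    Cox = max(p.Ctot - Cred, 0.0)
    NADH = max(NADH, 0.0)
    QH2 = max(QH2, 0.0)
    Cred = max(Cred, 0.0)

    # proton-motive force, kJ/mol, cost of pumping H+ matrix -> IMS
    dG_H = F * dpsi + RT * math.log(H_i / H_x)
    h7 = H_x / 1e-7  # chemical-proton correction relative to the pH-7 reference

    # -- NADH delivery (lumped dehydrogenase + malate-aspartate shuttle) ----
    # phosphate-activated, with a gentle electrogenic dependence on dpsi
    # (the shuttle's aspartate/glutamate carrier is driven by the proton
    # motive force, so supply capacity falls when the membrane depolarises)
    phi_DH = (1 + Pi_x / p.k_Pi1) / (1 + Pi_x / p.k_Pi2)
    m_psi = 1.0 / (1.0 + _exp(-(dpsi - p.dpsi_ref_DH) / p.delta_psi_DH))
    J_DH = p.X_DH * phi_DH * m_psi * (p.r_DH * NAD - NADH)

    # -- complex I: NADH + Q + 5H+x -> NAD + QH2 + 4H+i ---------------------
    Keq_C1 = _exp(-(p.dG_C1o + 4 * dG_H) / RT) * h7
    fwd_C1 = Keq_C1 * NADH * Q
    J_C1 = p.X_C1 * (fwd_C1 - NAD * QH2) / (1 + fwd_C1 / p.k_sat_C1)

    # -- complex III: QH2 + 2c3+ -> Q + 2c2+, 4 H+ to IMS, 2 charges --------
    phi_C3 = (1 + Pi_x / p.k_Pi3) / (1 + Pi_x / p.k_Pi4)
    Keq_C3 = _exp(-(p.dG_C3o + 4 * dG_H - 2 * F * dpsi) / RT) * h7 * h7
    fwd_C3 = math.sqrt(Keq_C3 * QH2) * Cox
    J_C3 = p.X_C3 * phi_C3 * (fwd_C3 - math.sqrt(Q) * Cred) \
        / (1 + fwd_C3 / p.k_sat_C3)

    # -- complex IV: 2c2+ + 0.5 O2 + 4H+x -> 2c3+ + H2O, 4 charges ----------
    Keq_C4 = _exp(-(p.dG_C4o + 2 * dG_H + 2 * F * dpsi) / RT) * h7 * h7
    sat_O2 = p.O2 / (p.O2 + p.k_O2)
    fwd_C4 = math.sqrt(Keq_C4) * Cred * p.O2 ** 0.25
    J_C4 = p.X_C4 * sat_O2 * (Cred / p.Ctot) * (fwd_C4 - Cox) \
        / (1 + fwd_C4 / p.k_sat_C4)

    # -- F1Fo ATP synthase: ADP + Pi + H+x + nA H+i -> ATP + nA H+x ---------
    P_ATPx = 1 + H_x / 10 ** (-p.pKa_ATP) + Mg_x / p.K_DT
    P_ADPx = 1 + H_x / 10 ** (-p.pKa_ADP) + Mg_x / p.K_DD
    P_Pix = 1 + H_x / 10 ** (-p.pKa_Pi)
    Keq_F1 = _exp(-(p.dG_F1o - p.n_A * dG_H) / RT) * h7
    J_F1 = p.X_F1 * (Keq_F1 * (ADP_x / P_ADPx) * (Pi_x / P_Pix) - ATP_x / P_ATPx)

    # -- adenine nucleotide translocase (free, Mg-unbound species) ----------
    P_ATPi = 1 + H_i / 10 ** (-p.pKa_ATP) + p.Mg_c / p.K_DT
    P_ADPi = 1 + H_i / 10 ** (-p.pKa_ADP) + p.Mg_c / p.K_DD
    ATP_fi = ATP_i / P_ATPi
    ADP_fi = ADP_i / P_ADPi
    ATP_fx = ATP_x / P_ATPx
    ADP_fx = ADP_x / P_ADPx
    if p.X_ANT > 0 and (ADP_fi + ATP_fi) > 0 and (ADP_fx + ATP_fx) > 0:
        th = p.theta_ANT
        e_i = _exp(-th * F * dpsi / RT)
        e_x = _exp((1 - th) * F * dpsi / RT)
        J_ANT = p.X_ANT * (
            ADP_fi / (ADP_fi + ATP_fi * e_i)
            - ADP_fx / (ADP_fx + ATP_fx * e_x)
        ) * (ADP_fi / (ADP_fi + p.k_mADP))
    else:
        J_ANT = 0.0

    # -- proton leak (Goldman-Hodgkin-Katz; positive into the matrix) -------
    zfv = F * dpsi / RT
    if abs(zfv) > 1e-9:
        J_Hle = p.X_Hle * dpsi * (H_i * _exp(zfv) - H_x) / (_exp(zfv) - 1)
    else:
        J_Hle = p.X_Hle * RT / F * (H_i - H_x)

    # -- phosphate/H+ symport (electroneutral, H2PO4- species) --------------
    Ka_Pi = 10 ** (-p.pKa_Pi)
    h2p_i = Pi_i * H_i / (H_i + Ka_Pi)
    h2p_x = Pi_x * H_x / (H_x + Ka_Pi)
    J_PiH = p.X_PiH * (H_i * h2p_i - H_x * h2p_x) / (h2p_i + p.k_PiH)

    # -- K+/H+ antiport ------------------------------------------------------
    J_KH = p.X_KH * (p.K_c * H_x - K_x * H_i)

    # -- adenylate kinase (IMS; AMP held fixed, off by default) -------------
    J_AK = p.X_AK * (p.Keq_AK * ADP_i * ADP_i - p.AMP_c * ATP_i)

    # -- cytosolic ATP consumption (saturable demand) -----------------------
    J_AtC = p.X_ATPase_c * ATP_c / (ATP_c + p.K_AtC)

    # -- outer-membrane permeation ------------------------------------------
    J_ATP_o = p.x_AM * (ATP_c - ATP_i)
    J_ADP_o = p.x_AM * (ADP_c - ADP_i)
    J_Pi_o = p.x_PM * (Pi_c - Pi_i)

    return (J_DH, J_C1, J_C3, J_C4, J_F1, J_ANT, J_Hle, J_PiH, J_KH, J_AK,
            J_AtC, J_ATP_o, J_ADP_o, J_Pi_o)


def _rhs(t: float, y: np.ndarray, p: ModelParameters) -> np.ndarray:
    (J_DH, J_C1, J_C3, J_C4, J_F1, J_ANT, J_Hle, J_PiH, J_KH, J_AK,
     J_AtC, J_ATP_o, J_ADP_o, J_Pi_o) = _fluxes_raw(y, p)

    W_x, W_i, W_c = p.W_x, p.W_i, p.W_c
    dy = np.empty(16)
    # membrane potential: charge pumped out minus charge returning
    dy[0] = (4 * J_C1 + 2 * J_C3 + 4 * J_C4
             - p.n_A * J_F1 - J_ANT - J_Hle) / p.CIM
    # redox carriers
    dy[1] = (J_DH - J_C1) / W_x                    # NADH_x
    dy[2] = (J_C1 - J_C3) / W_x                    # QH2
    dy[3] = (2 * J_C3 - 2 * J_C4) / W_i            # Cred
    # matrix nucleotides and phosphate
    dy[4] = (J_F1 - J_ANT) / W_x                   # ATP_x
    dy[5] = (-J_F1 + J_ANT) / W_x                  # ADP_x
    dy[6] = (-J_F1 + J_PiH) / W_x                  # Pi_x
    # intermembrane space
    dy[7] = (J_ANT + J_ATP_o + J_AK) / W_i         # ATP_i
    dy[8] = (-J_ANT + J_ADP_o - 2 * J_AK) / W_i    # ADP_i
    dy[9] = (-J_PiH + J_Pi_o) / W_i                # Pi_i
    # cytosol
    dy[10] = (-J_ATP_o - J_AtC) / W_c              # ATP_c
    dy[11] = (-J_ADP_o + J_AtC) / W_c              # ADP_c
    dy[12] = (-J_Pi_o + J_AtC) / W_c               # Pi_c
    # matrix ions; protons with Beard's effective buffering x_buff*H_x
    H_src = (J_DH - 5 * J_C1 - 2 * J_C3 - 4 * J_C4
             + (p.n_A - 1) * J_F1 + 2 * J_PiH + J_Hle - J_KH)
    dy[13] = p.x_buff * y[13] * H_src / W_x        # H_x
    dy[14] = J_KH / W_x                            # K_x
    dy[15] = 0.0                                   # Mg_x (fixed free Mg2+)
    return dy


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def compute_fluxes(state: ModelState, params: ModelParameters) -> FluxVector:
    """Evaluate every model flux at the given state (no mutation)."""
    state.validate(params)
    j = _fluxes_raw(state.to_array(), params)
    return FluxVector.from_array(j[:11])


def time_derivatives(state: ModelState, params: ModelParameters) -> np.ndarray:
    """Time derivative of every state variable (same order as STATE_NAMES)."""
    state.validate(params)
    return _rhs(0.0, state.to_array(), params)


@dataclass
class TimeCourse:
    """Simulated trajectory: dense output on a uniform grid plus events."""

    time: np.ndarray                       # s, strictly increasing
    states: np.ndarray                     # (n, 16)
    fluxes: np.ndarray                     # (n, 11)
    events: list[tuple[float, str, str, float]] = field(default_factory=list)
    params: ModelParameters | None = None

    def state_at(self, t: float) -> ModelState:
        y = np.array([np.interp(t, self.time, self.states[:, k])
                      for k in range(self.states.shape[1])])
        return ModelState.from_array(y)

    def flux_at(self, t: float, name: str) -> float:
        k = FLUX_NAMES.index(name)
        return float(np.interp(t, self.time, self.fluxes[:, k]))

    def variable(self, name: str) -> np.ndarray:
        if name in STATE_NAMES:
            return self.states[:, STATE_NAMES.index(name)]
        if name in FLUX_NAMES:
            return self.fluxes[:, FLUX_NAMES.index(name)]
        raise KeyError(name)

    def event_times(self) -> dict[str, float]:
        return {name: t for t, name, _target, _scale in self.events}

    def to_frame(self):
        """Tidy (time, variable, value) table."""
        import pandas as pd

        recs = []
        for k, n in enumerate(STATE_NAMES):
            recs.append(pd.DataFrame(
                {"time_s": self.time, "variable": n, "value": self.states[:, k]}))
        for k, n in enumerate(FLUX_NAMES):
            recs.append(pd.DataFrame(
                {"time_s": self.time, "variable": n, "value": self.fluxes[:, k]}))
        return pd.concat(recs, ignore_index=True)

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("time_s", data=self.time)
            h5.create_dataset("states", data=self.states)
            h5.create_dataset("fluxes", data=self.fluxes)
            h5["states"].attrs["columns"] = list(STATE_NAMES)
            h5["fluxes"].attrs["columns"] = list(FLUX_NAMES)
            ev = h5.create_group("events")
            for i, (t, name, target, scale) in enumerate(self.events):
                g = ev.create_group(str(i))
                g.attrs.update({"time_s": t, "name": name,
                                "target": target, "scale": scale})


def _solver_tols(rtol: float) -> tuple[float, np.ndarray]:
    return rtol, _STATE_SCALE * rtol * 1e-2


def simulate(
    params: ModelParameters,
    initial: ModelState,
    protocol=None,
    horizon: float = 6000.0,
    rtol: float = 1e-8,
    grid_dt: float = 10.0,
    max_step: float = math.inf,
) -> TimeCourse:
    """Integrate the model under a drug protocol.

    The system is stiff; integration uses BDF and restarts at every scheduled
    event, where the targeted activity constant jumps to ``baseline * scale``
    (scales always refer to the pre-protocol baseline, so repeated events on
    different targets never compound).
    """
    params.validate()
    initial.validate(params)

    events: list = []
    if protocol is not None:
        events = sorted(protocol.events, key=lambda e: e.time)
        times = [e.time for e in events]
        if len(set(times)) != len(times):
            seen: dict[float, set] = {}
            for e in events:
                seen.setdefault(e.time, set())
                if e.target in seen[e.time]:
                    raise ModelError(
                        f"event time collision at t={e.time} for target {e.target}")
                seen[e.time].add(e.target)
        if events and (events[0].time < 0 or events[-1].time > horizon):
            raise ModelError("protocol events must lie within [0, horizon]")

    # segment boundaries
    bounds = [0.0] + sorted({e.time for e in events if 0 < e.time < horizon}) + [horizon]
    atol_rtol, atol = _solver_tols(rtol)

    seg_times: list[np.ndarray] = []
    seg_states: list[np.ndarray] = []
    current = params
    from .protocols import scaled_activity  # late import to avoid cycle

    y0 = initial.to_array()
    applied: list[tuple[float, str, str, float]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        for e in events:
            if abs(e.time - a) < 1e-12 and e.time > 0 or (a == 0.0 and e.time == 0.0):
                current = current.replace(
                    **{scaled_activity(e.target): getattr(params, scaled_activity(e.target)) * e.scale})
                applied.append((e.time, e.name or e.target, e.target, e.scale))
        n_pts = max(int(round((b - a) / grid_dt)), 2) + 1
        t_eval = np.linspace(a, b, n_pts)
        sol = solve_ivp(
            _rhs, (a, b), y0, method="BDF", t_eval=t_eval,
            rtol=atol_rtol, atol=atol, max_step=max_step, args=(current,))
        if not sol.success:
            raise ModelError(
                f"integrator failed on [{a:.1f}, {b:.1f}] s: {sol.message}; "
                f"last state = {sol.y[:, -1] if sol.y.size else y0}")
        seg_times.append(sol.t)
        seg_states.append(sol.y.T)
        y0 = sol.y[:, -1]

    time = np.concatenate([s if i == 0 else s[1:] for i, s in enumerate(seg_times)])
    states = np.vstack([s if i == 0 else s[1:] for i, s in enumerate(seg_states)])

    # evaluate fluxes along the trajectory with the parameters active there
    fluxes = np.empty((len(time), 11))
    current = params
    ei = 0
    sorted_events = sorted(applied)
    for k, (t, y) in enumerate(zip(time, states)):
        while ei < len(sorted_events) and sorted_events[ei][0] <= t:
            _, _, target, scale = sorted_events[ei]
            nm = scaled_activity(target)
            current = current.replace(**{nm: getattr(params, nm) * scale})
            ei += 1
        fluxes[k] = _fluxes_raw(y, current)[:11]

    return TimeCourse(time=time, states=states, fluxes=fluxes,
                      events=applied, params=params)


def find_steady_state(
    params: ModelParameters,
    initial: ModelState | None = None,
    tol: float = 1e-10,
    max_fallbacks: int = 3,
) -> ModelState:
    """Steady state of the model (damped Newton with a long-integration fallback).

    The residual is the scaled derivative vector; convergence requires the
    max-norm of ``dy/dt / state_scale`` below ``tol`` (s^-1) and a state that
    satisfies all invariants.  Agrees with the long-time limit of ``simulate``
    with an empty protocol.
    """
    params.validate()
    if initial is None:
        initial = wtsim_initial_state()

    scale = _STATE_SCALE.copy()

    # The dynamics conserve a proton/charge inventory
    #   Phi = (W_x/x_buff) ln H_x + CIM dpsi - W_x (NADH + 2 Pi_x + ATP_x - K_x)
    # (matrix electroneutrality bookkeeping), which makes the steady state a
    # one-parameter family: the proton-balance row of the Jacobian is linearly
    # dependent on the charge balance.  Newton therefore replaces the H_x row
    # with conservation of Phi relative to the supplied initial state, pinning
    # the same steady state the long integration converges to.
    def _phi(y: np.ndarray) -> float:
        return (params.W_x / params.x_buff * math.log(y[13])
                + params.CIM * y[0]
                - params.W_x * (y[1] + 2 * y[6] + y[4] - y[14]))

    phi0 = _phi(initial.to_array())
    phi_scale = params.W_x * scale[14]

    # upper clip bounds keeping trial states inside the pool totals
    hi = np.full(16, np.inf)
    hi[1] = params.NADtot * (1 - 1e-12)
    hi[2] = params.Qtot * (1 - 1e-12)
    hi[3] = params.Ctot * (1 - 1e-12)

    def residual(z: np.ndarray) -> np.ndarray:
        y = z * scale
        y[15] = initial.Mg_x  # free Mg fixed; keep residual trivially zero
        yc = y.copy()
        yc[1:] = np.clip(y[1:], 1e-15, hi[1:])
        r = _rhs(0.0, yc, params) / scale
        # push the solver back toward the admissible region
        r += (y - yc) / scale
        r[13] = (_phi(yc) - phi0) / phi_scale
        r[15] = z[15] - initial.Mg_x / scale[15]
        return r

    y0 = initial.to_array()
    last_res = np.inf
    for attempt in range(max_fallbacks + 1):
        sol = root(residual, y0 / scale, method="hybr", tol=1e-14)
        y = sol.x * scale
        y[15] = initial.Mg_x
        inside = np.all(y[1:] >= 0) and np.all(y[1:] <= hi[1:] * (1 + 1e-12))
        if inside:
            res = float(np.max(np.abs(_rhs(0.0, y, params) / scale)))
            ok = res < tol
        else:
            res, ok = np.inf, False
        if ok:
            st = ModelState.from_array(y)
            try:
                st.validate(params)
            except ModelError:
                ok = False
            if ok:
                return st
        last_res = min(last_res, res)
        # fallback: relax toward the attractor, then retry Newton.  BDF first;
        # LSODA handles fully collapsed (depolarised, drained) regimes better.
        start = np.clip(y0, 1e-15, None) if np.all(np.isfinite(y0)) \
            else initial.to_array()
        start[0] = y0[0] if np.isfinite(y0[0]) else initial.dpsi
        horizon = 10 ** (4 + attempt)
        relaxed = None
        for method, rt in (("BDF", 1e-8), ("LSODA", 1e-7)):
            sol_ivp = solve_ivp(_rhs, (0.0, horizon), start, method=method,
                                rtol=rt, atol=_STATE_SCALE * rt * 1e-2,
                                args=(params,))
            if sol_ivp.success:
                relaxed = sol_ivp.y[:, -1]
                break
        if relaxed is None:
            continue
        y0 = relaxed
    raise ModelError(
        f"steady-state search did not converge: last residual {last_res:.3e}")


# ---------------------------------------------------------------------------
# bundled parameter profile
# ---------------------------------------------------------------------------

def load_profile(source) -> tuple[ModelParameters, ModelState]:
    """Load a parameter profile + initial state from YAML (path or name).

    ``source`` may be a bundled profile name (e.g. ``"WTsim"``) or a filesystem
    path to a YAML file with ``parameters:`` and ``initial_state:`` blocks.
    """
    import os

    if isinstance(source, str) and not os.path.exists(source):
        ref = resources.files("mitoflux") / "profiles" / f"{source.lower()}.yaml"
        if not ref.is_file():
            raise ModelError(f"unknown profile {source!r}")
        text = ref.read_text()
    else:
        with open(source) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    params = ModelParameters.from_dict(doc["parameters"])
    st = doc["initial_state"]
    unknown = set(st) - set(STATE_NAMES)
    if unknown:
        raise ModelError(f"unknown state keys: {sorted(unknown)}")
    state = ModelState(**{k: float(st[k]) for k in STATE_NAMES})
    return params, state


def wtsim_parameters() -> ModelParameters:
    """The bundled calibrated wild-type ('WTsim') parameter profile."""
    return load_profile("WTsim")[0]


def wtsim_initial_state() -> ModelState:
    return load_profile("WTsim")[1]
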