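"""Human ventricular myocyte electrophysiology with graded hypoxia.

The base model is the ten Tusscher–Panfilov (2006) human left-ventricular
myocyte, epicardial parameter set: 12 Hodgkin–Huxley gates, a CICR release
variable, and five intracellular concentrations.  Hypoxia is imposed through
the intracellular ATP concentration ``[ATP]_i`` (mM) in two places:

* an ATP-sensitive potassium current

  .. math:: I_{K(ATP)} = g_{K(ATP)}\\,f_{ATP}\\,(K_o/5.4)^{0.24}\\,(V - E_K),
            \\qquad f_{ATP} = \\frac{1}{1 + ([ATP]_i/K_{1/2})^{h}}

  whose open fraction ``f_ATP`` rises steeply as ATP falls, collapsing the
  plateau and abbreviating the action potential, and

* a metabolic depression of the L-type calcium conductance,
  ``P_CaL -> f_CaL([ATP]_i) P_CaL`` with a Hill-type activation factor that
  approaches 1 at normal ATP.

``[ATP]_i = 6`` mM is normoxia; ``2`` mM models acute hypoxia.  The three
K(ATP) parameters (``g_katp_max``, ``katp_atp_half``, ``katp_hill``) are
calibrated so the APD90 / conduction-velocity table of the hypoxic tissue
matches the published characterisation of this remodeling; every parameter is
exposed in :class:`CellParams` / the ``[cell]`` config section.

Gates are integrated with the Rush–Larsen exponential scheme; the membrane
potential and concentrations with forward Euler at a fixed ``dt`` (default
0.02 ms).  :func:`step_cell` is the readable reference integrator used by the
tests; production time-stepping goes through the table-driven numba kernels in
:mod:`cardiomaze.kernels`, which implement the identical update order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .errors import (
    ConfigurationError,
    DomainError,
    MeasurementError,
    NumericalInstabilityError,
    NumericalStateError,
)

__all__ = [
    "CellParams",
    "CellState",
    "APTrace",
    "GATE_NAMES",
    "CONC_NAMES",
    "STATE_NAMES",
    "resting_state",
    "gate_rates",
    "ionic_currents",
    "total_ionic_current",
    "ikatp_current",
    "ical_atp_factor",
    "step_cell",
    "run_paced_cell",
    "diastolic_threshold",
    "measure_apd",
]

# Physical constants
R_GAS = 8314.472  # mJ / (mol K)
TEMP = 310.0  # K
FARADAY = 96485.3415  # C / mol
RTONF = R_GAS * TEMP / FARADAY  # mV

ATP_MIN, ATP_MAX = 2.0, 6.0  # supported hypoxia range, mM

#: divergence guard for the explicit scheme
V_DIVERGENCE_LIMIT = 500.0  # mV

GATE_NAMES = (
    "m", "h", "j", "xr1", "xr2", "xs", "r", "s", "d", "f", "f2",
    "fcass", "rbar",
)
CONC_NAMES = ("Cai", "CaSR", "CaSS", "Nai", "Ki")
STATE_NAMES = ("V",) + GATE_NAMES + CONC_NAMES

# column indices into the flat state vector used everywhere
IV = 0
IGATE0 = 1
N_GATES = len(GATE_NAMES)
ICONC0 = IGATE0 + N_GATES
N_STATE = len(STATE_NAMES)
I_CAI, I_CASR, I_CASS, I_NAI, I_KI = range(ICONC0, ICONC0 + 5)


@dataclass
class CellParams:
    """All membrane-model parameters (epicardial defaults).

    Conductances are in nS/pF, concentrations in mM, permeability-like
    constants follow the original model's unit conventions so that every
    current comes out in pA/pF.
    """

    variant: str = "epicardial"
    # extracellular milieu
    Ko: float = 5.4
    Nao: float = 140.0
    Cao: float = 2.0
    # maximal conductances
    g_Na: float = 14.838
    g_K1: float = 5.405
    g_to: float = 0.294  # epicardial
    g_Kr: float = 0.153
    g_Ks: float = 0.392  # epicardial
    g_CaL: float = 3.980e-5
    g_bNa: float = 2.9e-4
    g_bCa: float = 5.92e-4
    g_pCa: float = 0.1238
    k_pCa: float = 5e-4
    g_pK: float = 1.46e-2
    p_KNa: float = 0.03
    # Na/Ca exchanger
    k_NaCa: float = 1000.0
    gamma_ncx: float = 0.35
    Km_Nai: float = 87.5
    Km_Ca: float = 1.38
    k_sat: float = 0.1
    alpha_ncx: float = 2.5
    # Na/K pump
    P_NaK: float = 2.724
    Km_K: float = 1.0
    Km_Na: float = 40.0
    # calcium handling
    V_maxup: float = 6.375e-3
    K_up: float = 2.5e-4
    V_rel: float = 0.102
    k1_prime: float = 0.15
    k2_prime: float = 0.045
    k3: float = 0.060
    k4: float = 0.005
    EC_sr: float = 1.5
    max_sr: float = 2.5
    min_sr: float = 1.0
    V_leak: float = 3.6e-4
    V_xfer: float = 3.8e-3
    Buf_c: float = 0.2
    K_bufc: float = 1e-3
    Buf_sr: float = 10.0
    K_bufsr: float = 0.3
    Buf_ss: float = 0.4
    K_bufss: float = 2.5e-4
    # cell geometry / capacitance
    V_c: float = 0.016404
    V_sr: float = 1.094e-3
    V_ss: float = 5.468e-5
    capacitance: float = 0.185
    # hypoxia remodeling: K(ATP) channel and L-type Ca depression
    g_katp_max: float = 0.06286     # nS/pF, fully un-blocked conductance (calibrated)
    katp_atp_half: float = 3.7726   # mM, half-inhibition constant (calibrated)
    katp_hill: float = 10.774       # Hill coefficient of ATP inhibition (calibrated)
    katp_ko_exp: float = 0.24       # [K+]_o dependence exponent
    katp_ko_ref: float = 5.4        # mM, reference [K+]_o
    ical_atp_half: float = 2.3519   # mM, half-activation of P_CaL (calibrated)
    ical_atp_hill: float = 7.771
    # default stimulus (single cell)
    stim_duration: float = 2.0      # ms
    stim_amplitude: float | None = None  # pA/pF; None -> 2x diastolic threshold
    atp_normal: float = 6.0         # mM

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class CellState:
    """Full electrophysiological state of one myocyte.

    ``gates`` holds the Hodgkin–Huxley gating variables plus the ryanodine
    release variable (all dimensionless, in [0, 1]); ``concentrations`` the
    intracellular/SR ionic concentrations (mM); ``atp`` the intracellular ATP
    level (mM) that sets the degree of hypoxia.
    """

    V: float
    gates: np.ndarray  # shape (13,), order GATE_NAMES
    concentrations: np.ndarray  # shape (5,), order CONC_NAMES
    atp: float = 6.0

    def __post_init__(self):
        self.gates = np.asarray(self.gates, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (np.isfinite(self.V) and np.all(np.isfinite(self.gates))
                and np.all(np.isfinite(self.concentrations))):
            raise NumericalStateError("non-finite values in cell state")
        if self.gates.shape != (N_GATES,):
            raise ConfigurationError(f"expected {N_GATES} gating variables")
        if self.concentrations.shape != (len(CONC_NAMES),):
            raise ConfigurationError(f"expected {len(CONC_NAMES)} concentrations")
        if np.any(self.gates < -1e-12) or np.any(self.gates > 1 + 1e-12):
            raise ConfigurationError("gating variables must lie in [0, 1]")
        if np.any(self.concentrations <= 0):
            raise ConfigurationError("concentrations must be positive")
        if not (ATP_MIN <= self.atp <= ATP_MAX):
            raise ConfigurationError(
                f"[ATP]_i = {self.atp} mM outside supported hypoxia range "
                f"[{ATP_MIN}, {ATP_MAX}] mM")

    def as_vector(self) -> np.ndarray:
        return np.concatenate(([self.V], self.gates, self.concentrations))

    @classmethod
    def from_vector(cls, y: np.ndarray, atp: float) -> "CellState":
        y = np.asarray(y, dtype=float)
        return cls(V=float(y[IV]), gates=y[IGATE0:ICONC0].copy(),
                   concentrations=y[ICONC0:].copy(), atp=atp)

    def gate(self, name: str) -> float:
        return float(self.gates[GATE_NAMES.index(name)])

    def conc(self, name: str) -> float:
        return float(self.concentrations[CONC_NAMES.index(name)])


# published initial (resting) values of the base model
_REST_VECTOR = np.array(
    [-86.2,
     # m h j xr1 xr2 xs r s d f f2 fcass rbar
     0.0, 0.75, 0.75, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 1.0, 1.0, 1.0,
     # Cai CaSR CaSS Nai Ki
     7e-5, 1.3, 7e-5, 7.67, 138.3])


def resting_state(atp: float = 6.0, params: CellParams | None = None,
                  equilibrate_ms: float = 0.0, dt: float = 0.02) -> CellState:
    """Resting state at the given ``[ATP]_i``.

    With ``equilibrate_ms > 0`` the published resting point is first relaxed
    (unstimulated) for that long, which settles the small transient introduced
    by switching on the hypoxic currents.
    """
    state = CellState.from_vector(_REST_VECTOR.copy(), atp=atp)
    if equilibrate_ms > 0:
        from . import kernels
        p = params or CellParams()
        key = (atp, equilibrate_ms, kernels._params_key(p, dt))
        hit = _rest_cache.get(key)
        if hit is None:
            hit = kernels.integrate_cell(state.as_vector(), atp, p, dt,
                                         int(round(equilibrate_ms / dt)))
            _rest_cache[key] = hit
        state = CellState.from_vector(hit.copy(), atp=atp)
    return state


_rest_cache: dict = {}


# ---------------------------------------------------------------------------
# hypoxia factors


def _check_atp(atp: float) -> None:
    if atp <= 0:
        raise DomainError(f"[ATP]_i must be positive, got {atp}")


def katp_open_fraction(atp: float, params: CellParams | None = None) -> float:
    """Hill-type fraction of un-blocked K(ATP) channels; falls with ATP."""
    p = params or CellParams()
    _check_atp(atp)
    return 1.0 / (1.0 + (atp / p.katp_atp_half) ** p.katp_hill)


def ikatp_current(V: float, atp: float, Ko: float | None = None,
                  params: CellParams | None = None, EK: float | None = None) -> float:
    """ATP-sensitive K+ current (pA/pF); outward for V > E_K.

    ``EK`` may be supplied directly (e.g., from a full cell state); otherwise
    the Nernst potential is computed at the base model's resting [K+]_i.
    """
    p = params or CellParams()
    _check_atp(atp)
    Ko = p.Ko if Ko is None else Ko
    if EK is None:
        EK = RTONF * math.log(Ko / _REST_VECTOR[I_KI])
    f_atp = katp_open_fraction(atp, p)
    return p.g_katp_max * f_atp * (Ko / p.katp_ko_ref) ** p.katp_ko_exp * (V - EK)


def ical_atp_factor(atp: float, params: CellParams | None = None) -> float:
    """Dimensionless metabolic scale on the L-type Ca conductance, in (0, 1]."""
    p = params or CellParams()
    _check_atp(atp)
    return 1.0 / (1.0 + (p.ical_atp_half / atp) ** p.ical_atp_hill)


# ---------------------------------------------------------------------------
# gate kinetics


def gate_rates(V: float, cass: float, casr: float,
               params: CellParams | None = None):
    """Steady states and time constants for all 13 gating variables.

    Returns ``(inf, tau)`` arrays ordered as :data:`GATE_NAMES`.  The fast
    Na+ inactivation rates switch formulation at V = -40 mV as in the source
    model; ``fcass`` and ``rbar`` depend on subspace/SR calcium rather than V
    but obey the same linear-relaxation form, so Rush–Larsen applies to every
    entry.
    """
    p = params or CellParams()
    inf = np.empty(N_GATES)
    tau = np.empty(N_GATES)

    # m
    inf[0] = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    a = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    b = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau[0] = a * b
    # h
    inf[1] = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah, bh = 0.0, 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau[1] = 1.0 / (ah + bh)
    # j
    inf[2] = inf[1]
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (aj + bj)
    # xr1
    inf[3] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    a = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    b = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau[3] = a * b
    # xr2
    inf[4] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    a = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    b = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau[4] = a * b
    # xs
    inf[5] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    a = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    b = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau[5] = a * b + 80.0
    # r
    inf[6] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau[6] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    # s (epicardial formulation)
    inf[7] = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau[7] = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
              + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)
    # d
    inf[8] = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    a = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    b = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    g = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau[8] = a * b + g
    # f
    inf[9] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau[9] = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
              + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
              + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)
    # f2
    inf[10] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tau[10] = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
               + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
               + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))
    # fcass (subspace-Ca dependent)
    r2 = 1.0 / (1.0 + (cass / 0.05) ** 2)
    inf[11] = 0.6 * r2 + 0.4
    tau[11] = 80.0 * r2 + 2.0
    # rbar: dR/dt = k4 (1-R) - k2 CaSS R  ->  linear relaxation
    kcasr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.EC_sr / casr) ** 2)
    k2 = p.k2_prime * kcasr
    tau[12] = 1.0 / (p.k4 + k2 * cass)
    inf[12] = p.k4 * tau[12]
    return inf, tau


# ---------------------------------------------------------------------------
# currents


def ionic_currents(state: CellState, params: CellParams | None = None,
                   istim: float = 0.0) -> dict:
    """All thirteen membrane currents (pA/pF) plus reversal potentials.

    The returned dict also carries the Ca-handling fluxes used by the
    concentration updates, so :func:`step_cell` and the tests can inspect
    every component of the right-hand side.
    """
    p = params or CellParams()
    state.validate()
    V = state.V
    m, h, j, xr1, xr2, xs, r, s, d, f, f2, fcass, rbar = state.gates
    cai, casr, cass, nai, ki = state.concentrations

    EK = RTONF * math.log(p.Ko / ki)
    ENa = RTONF * math.log(p.Nao / nai)
    EKs = RTONF * math.log((p.Ko + p.p_KNa * p.Nao) / (ki + p.p_KNa * nai))
    ECa = 0.5 * RTONF * math.log(p.Cao / cai)

    INa = p.g_Na * m ** 3 * h * j * (V - ENa)

    u = V - EK
    aK1 = 0.1 / (1.0 + math.exp(0.06 * (u - 200.0)))
    bK1 = ((3.0 * math.exp(2e-4 * (u + 100.0)) + math.exp(0.1 * (u - 10.0)))
           / (1.0 + math.exp(-0.5 * u)))
    IK1 = p.g_K1 * math.sqrt(p.Ko / 5.4) * aK1 / (aK1 + bK1) * u

    Ito = p.g_to * r * s * u
    IKr = p.g_Kr * math.sqrt(p.Ko / 5.4) * xr1 * xr2 * u
    IKs = p.g_Ks * xs ** 2 * (V - EKs)

    x = 2.0 * (V - 15.0) / RTONF
    if abs(x) < 1e-7:
        # removable singularity at V = 15 mV
        frac = 1.0 / (1.0 + 0.5 * x)
        e2x = 1.0 + x
    else:
        e2x = math.exp(x)
        frac = x / (e2x - 1.0)
    pref = p.g_CaL * ical_atp_factor(state.atp, p) * d * f * f2 * fcass * 2.0 * FARADAY
    ICaL = pref * frac * (0.25 * cass * e2x - p.Cao)

    eg = math.exp(p.gamma_ncx * V / RTONF)
    eg1 = math.exp((p.gamma_ncx - 1.0) * V / RTONF)
    INaCa = (p.k_NaCa * (eg * nai ** 3 * p.Cao - eg1 * p.Nao ** 3 * cai * p.alpha_ncx)
             / ((p.Km_Nai ** 3 + p.Nao ** 3) * (p.Km_Ca + p.Cao)
                * (1.0 + p.k_sat * eg1)))

    INaK = (p.P_NaK * p.Ko / (p.Ko + p.Km_K) * nai / (nai + p.Km_Na)
            / (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
               + 0.0353 * math.exp(-V / RTONF)))

    IpCa = p.g_pCa * cai / (cai + p.k_pCa)
    IpK = p.g_pK * u / (1.0 + math.exp((25.0 - V) / 5.98))
    IbNa = p.g_bNa * (V - ENa)
    IbCa = p.g_bCa * (V - ECa)

    IKatp = ikatp_current(V, state.atp, Ko=p.Ko, params=p, EK=EK)

    # calcium-handling fluxes (mM/ms)
    kcasr = p.max_sr - (p.max_sr - p.min_sr) / (1.0 + (p.EC_sr / casr) ** 2)
    k1 = p.k1_prime / kcasr
    O = k1 * cass ** 2 * rbar / (p.k3 + k1 * cass ** 2)
    Irel = p.V_rel * O * (casr - cass)
    Ileak = p.V_leak * (casr - cai)
    Iup = p.V_maxup / (1.0 + (p.K_up / cai) ** 2)
    Ixfer = p.V_xfer * (cass - cai)

    total = (INa + IK1 + Ito + IKr + IKs + ICaL + INaCa + INaK
             + IpCa + IpK + IbCa + IbNa + IKatp)
    return {
        "INa": INa, "IK1": IK1, "Ito": Ito, "IKr": IKr, "IKs": IKs,
        "ICaL": ICaL, "INaCa": INaCa, "INaK": INaK, "IpCa": IpCa,
        "IpK": IpK, "IbCa": IbCa, "IbNa": IbNa, "IKatp": IKatp,
        "Itot": total, "Istim": istim,
        "EK": EK, "ENa": ENa, "EKs": EKs, "ECa": ECa,
        "Irel": Irel, "Ileak": Ileak, "Iup": Iup, "Ixfer": Ixfer,
    }


def total_ionic_current(state: CellState, params: CellParams | None = None) -> float:
    """Signed sum of all thirteen membrane currents (pA/pF)."""
    return ionic_currents(state, params)["Itot"]


# ---------------------------------------------------------------------------
# reference integrator


def step_cell(state: CellState, dt: float = 0.02, istim: float = 0.0,
              params: CellParams | None = None) -> CellState:
    """One operator step: forward Euler on V and concentrations, Rush–Larsen
    on every gate.  ``istim`` is in pA/pF, *depolarizing positive*.

    Deterministic: identical inputs give bit-identical outputs.  This is the
    slow readable path; the numba kernels replicate the same update order.
    """
    if dt <= 0:
        raise DomainError(f"dt must be positive, got {dt}")
    p = params or CellParams()
    cur = ionic_currents(state, p, istim=istim)
    cai, casr, cass, nai, ki = state.concentrations
    capf = p.capacitance / FARADAY

    dV = -(cur["Itot"] - istim)

    # concentration updates (buffered rapid-equilibrium form)
    b_c = 1.0 / (1.0 + p.Buf_c * p.K_bufc / (cai + p.K_bufc) ** 2)
    b_sr = 1.0 / (1.0 + p.Buf_sr * p.K_bufsr / (casr + p.K_bufsr) ** 2)
    b_ss = 1.0 / (1.0 + p.Buf_ss * p.K_bufss / (cass + p.K_bufss) ** 2)
    dcai = b_c * ((cur["Ileak"] - cur["Iup"]) * p.V_sr / p.V_c + cur["Ixfer"]
                  - (cur["IbCa"] + cur["IpCa"] - 2.0 * cur["INaCa"])
                  * capf / (2.0 * p.V_c))
    dcasr = b_sr * (cur["Iup"] - cur["Irel"] - cur["Ileak"])
    dcass = b_ss * (-cur["ICaL"] * capf / (2.0 * p.V_ss)
                    + cur["Irel"] * p.V_sr / p.V_ss - cur["Ixfer"] * p.V_c / p.V_ss)
    dnai = -(cur["INa"] + cur["IbNa"] + 3.0 * cur["INaK"] + 3.0 * cur["INaCa"]) \
        * capf / p.V_c
    dki = -(cur["IK1"] + cur["Ito"] + cur["IKr"] + cur["IKs"] - 2.0 * cur["INaK"]
            + cur["IpK"] + cur["IKatp"] - istim) * capf / p.V_c

    inf, tau = gate_rates(state.V, cass, casr, p)
    gates = inf + (state.gates - inf) * np.exp(-dt / tau)

    conc = state.concentrations + dt * np.array([dcai, dcasr, dcass, dnai, dki])
    V = state.V + dt * dV
    if abs(V) > V_DIVERGENCE_LIMIT:
        raise NumericalInstabilityError(
            f"membrane potential diverged: V = {V:.1f} mV")
    return CellState(V=V, gates=gates, concentrations=conc, atp=state.atp)


# ---------------------------------------------------------------------------
# pacing protocols and AP metrics


@dataclass
class APTrace:
    """Sampled membrane-potential trace of one (final) paced beat."""

    times: np.ndarray  # ms
    voltages: np.ndarray  # mV
    cycle_length: float = float("nan")
    n_beats: int = 0
    atp: float = float("nan")
    stim_amplitude: float = float("nan")
    stim_duration: float = float("nan")
    captured: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.times.shape != self.voltages.shape:
            raise ConfigurationError("times and voltages must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ConfigurationError("sample times must be strictly increasing")

    def to_csv(self, path) -> None:
        header = (f"# cycle_length_ms={self.cycle_length} n_beats={self.n_beats} "
                  f"atp_mM={self.atp} stim_amplitude_pA_pF={self.stim_amplitude} "
                  f"stim_duration_ms={self.stim_duration} captured={self.captured}\n"
                  "time_ms,V_mV")
        np.savetxt(path, np.column_stack([self.times, self.voltages]),
                   delimiter=",", header=header, comments="")


def diastolic_threshold(atp: float, params: CellParams | None = None,
                        dt: float = 0.02, duration: float | None = None,
                        tol: float = 0.25) -> float:
    """Diastolic stimulus threshold (pA/pF) found by bisection.

    A stimulus "captures" when the peak V within 50 ms exceeds 0 mV.
    """
    from . import kernels
    p = params or CellParams()
    dur = p.stim_duration if duration is None else duration
    rest = resting_state(atp, p, equilibrate_ms=1000.0, dt=dt).as_vector()
    lo, hi = 0.0, 8.0
    while not kernels.peak_after_stimulus(rest, atp, p, dt, hi, dur) > 0.0:
        hi *= 2.0
        if hi > 2048.0:
            raise MeasurementError("no capturing stimulus amplitude found")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if kernels.peak_after_stimulus(rest, atp, p, dt, mid, dur) > 0.0:
            hi = mid
        else:
            lo = mid
    return hi


def run_paced_cell(atp: float, cycle_length: float = 1000.0, n_beats: int = 5,
                   stim_amplitude: float | None = None,
                   stim_duration: float | None = None,
                   params: CellParams | None = None, dt: float = 0.02,
                   sample_every_ms: float = 0.1) -> APTrace:
    """Pace a single cell and return the trace of the final beat.

    The first ``n_beats - 1`` beats condition the state; the trace covers the
    last cycle.  With ``stim_amplitude=None`` the amplitude is set to twice
    the diastolic threshold at this ATP level (bisection).  A stimulus that
    fails to elicit an AP (peak V < 0 mV) sets ``captured=False`` on the
    returned trace instead of raising.
    """
    from . import kernels
    if n_beats < 1:
        raise DomainError("n_beats must be >= 1")
    p = params or CellParams()
    if not (ATP_MIN <= atp <= ATP_MAX):
        raise ConfigurationError(
            f"[ATP]_i = {atp} mM outside supported range [{ATP_MIN}, {ATP_MAX}]")
    dur = p.stim_duration if stim_duration is None else stim_duration
    amp = stim_amplitude
    if amp is None:
        amp = p.stim_amplitude
    if amp is None:
        amp = 2.0 * diastolic_threshold(atp, p, dt=dt, duration=dur)

    y = resting_state(atp, p, equilibrate_ms=1000.0, dt=dt).as_vector()
    steps_cl = int(round(cycle_length / dt))
    sample_every = max(1, int(round(sample_every_ms / dt)))
    for _ in range(n_beats - 1):
        y = kernels.integrate_cell(y, atp, p, dt, steps_cl,
                                   stim_amplitude=amp, stim_duration=dur)
    t, v = kernels.integrate_cell_trace(y, atp, p, dt, steps_cl,
                                        stim_amplitude=amp, stim_duration=dur,
                                        sample_every=sample_every)
    captured = bool(np.max(v) > 0.0)
    return APTrace(times=t, voltages=v, cycle_length=cycle_length,
                   n_beats=n_beats, atp=atp, stim_amplitude=amp,
                   stim_duration=dur, captured=captured)


def measure_apd(trace: APTrace, repolarization_fraction: float = 0.9) -> float:
    """Action-potential duration (ms) at the given repolarization fraction.

    Measured from the instant of maximum upstroke velocity to the downward
    crossing of ``V_rest + (1 - fraction) (V_peak - V_rest)``, with linear
    interpolation between samples.
    """
    if not (0.0 < repolarization_fraction < 1.0):
        raise DomainError("repolarization fraction must lie in (0, 1)")
    t, v = trace.times, trace.voltages
    if t.size < 3:
        raise MeasurementError("trace too short to contain an action potential")
    if not trace.captured or np.max(v) <= 0.0:
        raise MeasurementError("no action potential in trace (capture failure)")
    dvdt = np.diff(v) / np.diff(t)
    iup = int(np.argmax(dvdt))
    t_up = t[iup]
    v_rest = float(np.min(v[: iup + 1])) if iup > 0 else float(v[0])
    v_peak = float(np.max(v[iup:]))
    v_target = v_rest + (1.0 - repolarization_fraction) * (v_peak - v_rest)
    ipk = iup + int(np.argmax(v[iup:]))
    below = np.nonzero(v[ipk:] <= v_target)[0]
    if below.size == 0:
        raise MeasurementError("AP does not repolarize to target level in trace")
    k = ipk + below[0]
    if k == 0:
        return 0.0
    # linear interpolation between samples k-1 and k
    t_cross = t[k - 1] + (v[k - 1] - v_target) / (v[k - 1] - v[k]) * (t[k] - t[k - 1])
    return float(t_cross - t_up)
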