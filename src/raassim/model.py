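"""Deterministic structural model of benazeprilat-RAAS dynamics in one dog.

The model tracks 24 molar amounts: three oral absorption depots and three
benazeprilat pools (free circulation, tissue, non-specifically bound), six
ACE species (free enzyme E, enzyme-substrate complex ES and enzyme-inhibitor
complex EI, in the free-circulation and tissue compartments), two pools each
for angiotensin I (the ACE substrate S), angiotensin II (the product P) and
angiotensin (1-7), and renal/plasma/tissue pools for angiotensins III and IV.

ACE inhibition is a competitive Michaelis-Menten scheme: benazeprilat (I)
and angiotensin I (S) compete for free ACE; catalysis of the ES complex
produces angiotensin II one-to-one.  Angiotensin I production is modulated
by a 24-h cosine (chronobiology) with peak clock time ``PRA`` and relative
amplitude ``delta24hr``.  Angiotensin II is converted to angiotensin III in
the renal sub-volume (where aminopeptidase A resides) and onward to
angiotensin IV.

Internally all amounts are in pmol, volumes in L and times in h.  The
published enzyme amounts, the angiotensin I production rate and the
bimolecular association constants live on the micromolar amount scale the
model was estimated on; :func:`derive_rates` converts them once.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from .parameters import ConfigurationError, FixedEffects, ModelConstants

__all__ = [
    "StateIndex",
    "N_STATES",
    "ANALYTES",
    "DerivedRates",
    "InitMode",
    "ProductionMode",
    "chronobiology",
    "derive_rates",
    "rhs",
    "initial_state",
    "effective_production",
    "observe",
    "integrate_segment",
    "IntegrationError",
]


class IntegrationError(RuntimeError):
    """ODE solver failure, annotated with time and individual context."""


class StateIndex(enum.IntEnum):
    """Index of each state amount (pmol) in the state vector."""

    I_1abs_fr = 0  # depot absorbed directly at ka1
    I_1abs_pr = 1  # depot routed through the pre-circulatory chain at ka
    I_pr = 2  # pre-circulatory benazeprilat
    I_fr = 3  # free-circulation benazeprilat
    I_ts = 4  # tissue benazeprilat
    I_ns = 5  # non-specifically bound benazeprilat
    E_fr = 6  # free ACE, free circulation
    ES_fr = 7  # ACE-angiotensin I complex, free circulation
    EI_fr = 8  # ACE-benazeprilat complex, free circulation
    E_ts = 9
    ES_ts = 10
    EI_ts = 11
    S_fr = 12  # angiotensin I
    S_ts = 13
    P_fr = 14  # angiotensin II
    P_ts = 15
    A17_fr = 16  # angiotensin (1-7)
    A17_ts = 17
    AIII_rn = 18  # angiotensin III, renal / plasma / tissue
    AIII_pl = 19
    AIII_ts = 20
    AIV_rn = 21
    AIV_pl = 22
    AIV_ts = 23


N_STATES = 24

#: integration kernel state count: the 24 model states plus two audit
#: accumulators that track drug mass leaving the system (cumulative cleared
#: benazeprilat, and depot mass lost to incomplete bioavailability).  They
#: receive flux but feed nothing back, so they do not alter the dynamics.
N_STATES_AUG = 26
IDX_CLEARED = 24
IDX_UNABSORBED = 25

#: observed analytes, in reporting order
ANALYTES = ("benazeprilat", "AngI", "AngII", "Ang17", "AngIII", "AngIV")


class InitMode(str, enum.Enum):
    BASELINE_ANCHORED = "baseline-anchored"
    BURN_IN = "burn-in"


class ProductionMode(str, enum.Enum):
    TABLE_VALUE = "table-value"
    STEADY_STATE = "steady-state-constrained"


@dataclasses.dataclass(frozen=True)
class DerivedRates:
    """First-order micro-rates and scaled amounts in pmol/L/h units.

    Flows are converted to transfer rates by dividing by the source
    compartment volume (standard mammillary convention); clearances to
    elimination rates by the volume of the compartment they act on.  The
    enzyme rate constants are converted from the published per-second scale
    to per-hour, and the bimolecular association constants from per-umol to
    per-pmol.
    """

    k_fr_ns: float
    k_ns_fr: float
    k_fr_ts: float
    k_ts_fr: float
    k_pl_rn: float
    k_rn_pl: float
    k_rn_ts: float
    k_ts_rn: float
    k_pl_ts: float
    k_ts_pl: float
    kCl_I: float
    kCl_S: float
    kCl_P: float
    kCl_A17: float
    kCl_AIII: float
    kCl_AIV: float
    k1: float
    k2: float
    k3: float
    k_m1: float  # ACE-AngI association, per pmol per h (kd * k2, amount-based)
    k_m3: float  # ACE-benazeprilat association, per pmol per h (k3 / Ki-amount)
    Vfr: float
    E_fr_total: float  # pmol
    E_ts_total: float  # pmol
    rS_table: float  # table-value AngI production, pmol/h
    frac_rn: float  # Vrn / Vfr

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"derived rate {f.name!r}={v} not finite/non-negative")


def derive_rates(
    fe: FixedEffects,
    rate_scale: float = 3600.0,
    amount_scale: float = 1e6,
    association_mode: str = "baseline-referenced",
) -> DerivedRates:
    """Derive micro-rate constants from the population parameter vector.

    Parameters
    ----------
    fe:
        Fixed effects (typical or individual values, as printed).
    rate_scale:
        Conversion of the published per-second enzyme rate constants to the
        model time unit (3600 -> 1/h).
    amount_scale:
        pmol per internal published amount unit (1e6: the published enzyme
        total and production rate are micromolar amounts).
    association_mode:
        How the (unpublished) bimolecular association constant is fixed.
        ``"baseline-referenced"`` (default) derives it by requiring the
        printed angiotensin II baseline to be a drug-free fixed point of
        the free-circulation cascade: the catalytic flux ``k2 * ES0`` must
        balance the baseline angiotensin II losses, which pins the baseline
        ES occupancy and hence ``k_m1``.  ``"kd-ratio"`` uses the published
        association/catalysis ratio directly, ``k_m1 = kd * k2`` on the
        micromolar amount scale.  The enzyme-inhibitor association
        ``k_m3`` equals ``k_m1`` in both modes.
    """
    if rate_scale <= 0 or amount_scale <= 0:
        raise ConfigurationError("rate_scale and amount_scale must be > 0")
    fe.validate()
    Vfr = fe.Vpl + fe.Vrn
    k1 = fe.k1s * rate_scale
    k2 = fe.k2s * rate_scale
    k3 = fe.k3s * rate_scale
    E_fr_total = fe.FACEfr * fe.ACEtotal * amount_scale
    if association_mode == "kd-ratio":
        k_m1 = fe.kd * k2 / amount_scale
    elif association_mode == "baseline-referenced":
        # AngII baseline stationarity: tissue transfers cancel at equal
        # concentrations, so k2*ES0 must equal the free-pool loss flux
        es0 = fe.P0 * Vfr * (fe.ClP / Vfr + fe.kII17 + fe.kII_III * fe.Vrn / Vfr) / k2
        if not 0.0 < es0 < E_fr_total:
            raise ConfigurationError(
                "baseline-referenced association needs 0 < ES0 < E_fr_total; "
                f"got ES0={es0:.3g}, E_fr_total={E_fr_total:.3g}"
            )
        k_m1 = (k1 + k2) * es0 / ((E_fr_total - es0) * fe.S0 * Vfr)
    else:
        raise ConfigurationError(f"unknown association_mode {association_mode!r}")
    return DerivedRates(
        k_fr_ns=fe.Qfr_ns / Vfr,
        k_ns_fr=fe.Qfr_ns / fe.Vns,
        k_fr_ts=fe.Qfr_ts / Vfr,
        k_ts_fr=fe.Qfr_ts / fe.Vts,
        k_pl_rn=fe.Qrn / fe.Vpl,
        k_rn_pl=fe.Qrn / fe.Vrn,
        # no dedicated kidney/plasma <-> tissue flow is estimated; the
        # free<->tissue flow is reused with source-compartment volumes
        k_rn_ts=fe.Qfr_ts / fe.Vrn,
        k_ts_rn=fe.Qfr_ts / fe.Vts,
        k_pl_ts=fe.Qfr_ts / fe.Vpl,
        k_ts_pl=fe.Qfr_ts / fe.Vts,
        kCl_I=fe.ClI / Vfr,
        kCl_S=fe.ClS / Vfr,
        kCl_P=fe.ClP / Vfr,
        kCl_A17=fe.ClAng17 / Vfr,
        # angiotensins III/IV are cleared from the plasma sub-volume
        kCl_AIII=fe.ClAngIII / fe.Vpl,
        kCl_AIV=fe.ClAngIV / fe.Vpl,
        k1=k1,
        k2=k2,
        k3=k3,
        k_m1=k_m1,
        k_m3=k_m1,
        Vfr=Vfr,
        E_fr_total=E_fr_total,
        E_ts_total=(1.0 - fe.FACEfr) * fe.ACEtotal * amount_scale,
        rS_table=fe.rS * amount_scale,
        frac_rn=fe.Vrn / Vfr,
    )


def chronobiology(t: float | np.ndarray, delta24hr: float, PRA: float):
    """24-h cosine modulation of angiotensin I production.

    ``f(t) = delta24hr * cos((t - PRA) * 2*pi / 24)`` with ``t`` in hours on
    the simulation clock (t mod 24 = clock time); the peak is at clock time
    ``PRA`` and the range is ``[-delta24hr, +delta24hr]``.
    """
    return delta24hr * np.cos((t - PRA) * (2.0 * np.pi / 24.0))


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernels

_N_THETA = 32


def pack_theta(dr: DerivedRates, fe: FixedEffects, rS_eff: float) -> np.ndarray:
    """Flatten the rates needed by the compiled RHS into one vector."""
    return np.array(
        [
            fe.ka1, fe.ka, fe.Fbio,
            dr.k_fr_ns, dr.k_ns_fr, dr.k_fr_ts, dr.k_ts_fr,
            dr.k_pl_rn, dr.k_rn_pl, dr.k_rn_ts, dr.k_ts_rn, dr.k_pl_ts, dr.k_ts_pl,
            dr.kCl_I, dr.kCl_S, dr.kCl_P, dr.kCl_A17, dr.kCl_AIII, dr.kCl_AIV,
            dr.k1, dr.k2, dr.k3, dr.k_m1, dr.k_m3,
            fe.kI17, fe.kII17, fe.kII_III, fe.kIII_IV,
            dr.frac_rn, rS_eff, fe.delta24hr, fe.PRA,
        ]
    )


@njit(cache=True)
def _rhs_nb(t, y, th):  # pragma: no cover - exercised via wrappers
    ka1 = th[0]; ka = th[1]; Fbio = th[2]
    kfn = th[3]; knf = th[4]; kft = th[5]; ktf = th[6]
    kpr = th[7]; krp = th[8]; krt = th[9]; ktr = th[10]; kpt = th[11]; ktp = th[12]
    kClI = th[13]; kClS = th[14]; kClP = th[15]; kClA7 = th[16]; kCl3 = th[17]; kCl4 = th[18]
    k1 = th[19]; k2 = th[20]; k3 = th[21]; km1 = th[22]; km3 = th[23]
    kI17 = th[24]; kII17 = th[25]; kII_III = th[26]; kIII_IV = th[27]
    frn = th[28]; rS = th[29]; delta = th[30]; PRA = th[31]

    d = np.empty(26)
    fct = delta * np.cos((t - PRA) * (2.0 * np.pi / 24.0))
    # absorption depots
    d[0] = -ka1 * y[0]
    d[1] = -ka * y[1]
    d[2] = Fbio * ka * y[1] - ka * y[2]
    # enzyme-inhibitor and enzyme-substrate net association fluxes
    bindF = km3 * y[6] * y[3] - k3 * y[8]
    bindT = km3 * y[9] * y[4] - k3 * y[11]
    catF = km1 * y[6] * y[12] - k1 * y[7]
    catT = km1 * y[9] * y[13] - k1 * y[10]
    # benazeprilat
    d[3] = (Fbio * ka1 * y[0] + ka * y[2]
            - kfn * y[3] + knf * y[5]
            - kft * y[3] + ktf * y[4]
            - kClI * y[3] - bindF)
    d[4] = kft * y[3] - ktf * y[4] - bindT
    d[5] = kfn * y[3] - knf * y[5]
    # ACE species
    d[6] = -catF + k2 * y[7] - bindF
    d[7] = catF - k2 * y[7]
    d[8] = bindF
    d[9] = -catT + k2 * y[10] - bindT
    d[10] = catT - k2 * y[10]
    d[11] = bindT
    # angiotensin I (substrate)
    d[12] = (rS * (1.0 + fct)
             - kft * y[12] + ktf * y[13]
             - catF - kI17 * y[12] - kClS * y[12])
    d[13] = kft * y[12] - ktf * y[13] - catT - kI17 * y[13]
    # angiotensin II (product; produced one-to-one with AngI catalysis)
    d[14] = (k2 * y[7]
             - kft * y[14] + ktf * y[15]
             - kClP * y[14] - kII17 * y[14] - kII_III * y[14] * frn)
    d[15] = k2 * y[10] + kft * y[14] - ktf * y[15] - kII17 * y[15]
    # angiotensin (1-7)
    d[16] = (kII17 * y[14] + kI17 * y[12]
             - kft * y[16] + ktf * y[17] - kClA7 * y[16])
    d[17] = kII17 * y[15] + kI17 * y[13] + kft * y[16] - ktf * y[17]
    # angiotensin III (renal production from plasma AngII)
    d[18] = (kII_III * y[14] * frn
             + y[19] * kpr - y[18] * krp
             - y[18] * krt + y[20] * ktr
             - kIII_IV * y[18])
    d[19] = (-y[19] * kpr + y[18] * krp
             - y[19] * kpt + y[20] * ktp
             - kCl3 * y[19])
    d[20] = y[18] * krt - y[20] * ktr + y[19] * kpt - y[20] * ktp
    # angiotensin IV
    d[21] = (kIII_IV * y[18]
             + y[22] * kpr - y[21] * krp
             - y[21] * krt + y[23] * ktr)
    d[22] = (-y[22] * kpr + y[21] * krp
             - y[22] * kpt + y[23] * ktp
             - kCl4 * y[22])
    d[23] = y[21] * krt - y[23] * ktr + y[22] * kpt - y[23] * ktp
    # audit accumulators: cleared drug and non-bioavailable depot loss
    d[24] = kClI * y[3]
    d[25] = (1.0 - Fbio) * (ka1 * y[0] + ka * y[1])
    return d


@njit(cache=True)
def _jac_nb(t, y, th):  # pragma: no cover - exercised via wrappers
    ka1 = th[0]; ka = th[1]; Fbio = th[2]
    kfn = th[3]; knf = th[4]; kft = th[5]; ktf = th[6]
    kpr = th[7]; krp = th[8]; krt = th[9]; ktr = th[10]; kpt = th[11]; ktp = th[12]
    kClI = th[13]; kClS = th[14]; kClP = th[15]; kClA7 = th[16]; kCl3 = th[17]; kCl4 = th[18]
    k1 = th[19]; k2 = th[20]; k3 = th[21]; km1 = th[22]; km3 = th[23]
    kI17 = th[24]; kII17 = th[25]; kII_III = th[26]; kIII_IV = th[27]
    frn = th[28]

    J = np.zeros((26, 26))
    J[0, 0] = -ka1
    J[1, 1] = -ka
    J[2, 1] = Fbio * ka; J[2, 2] = -ka
    bF_E = km3 * y[3]; bF_I = km3 * y[6]
    bT_E = km3 * y[4]; bT_I = km3 * y[9]
    cF_E = km1 * y[12]; cF_S = km1 * y[6]
    cT_E = km1 * y[13]; cT_S = km1 * y[9]
    J[3, 0] = Fbio * ka1; J[3, 2] = ka
    J[3, 3] = -kfn - kft - kClI - bF_I
    J[3, 4] = ktf; J[3, 5] = knf
    J[3, 6] = -bF_E; J[3, 8] = k3
    J[4, 3] = kft; J[4, 4] = -ktf - bT_I; J[4, 9] = -bT_E; J[4, 11] = k3
    J[5, 3] = kfn; J[5, 5] = -knf
    J[6, 3] = -bF_I; J[6, 6] = -cF_E - bF_E; J[6, 7] = k1 + k2
    J[6, 8] = k3; J[6, 12] = -cF_S
    J[7, 6] = cF_E; J[7, 7] = -k1 - k2; J[7, 12] = cF_S
    J[8, 3] = bF_I; J[8, 6] = bF_E; J[8, 8] = -k3
    J[9, 4] = -bT_I; J[9, 9] = -cT_E - bT_E; J[9, 10] = k1 + k2
    J[9, 11] = k3; J[9, 13] = -cT_S
    J[10, 9] = cT_E; J[10, 10] = -k1 - k2; J[10, 13] = cT_S
    J[11, 4] = bT_I; J[11, 9] = bT_E; J[11, 11] = -k3
    J[12, 6] = -cF_E; J[12, 7] = k1
    J[12, 12] = -kft - cF_S - kI17 - kClS; J[12, 13] = ktf
    J[13, 9] = -cT_E; J[13, 10] = k1
    J[13, 12] = kft; J[13, 13] = -ktf - cT_S - kI17
    J[14, 7] = k2; J[14, 14] = -kft - kClP - kII17 - kII_III * frn; J[14, 15] = ktf
    J[15, 10] = k2; J[15, 14] = kft; J[15, 15] = -ktf - kII17
    J[16, 12] = kI17; J[16, 14] = kII17; J[16, 16] = -kft - kClA7; J[16, 17] = ktf
    J[17, 13] = kI17; J[17, 15] = kII17; J[17, 16] = kft; J[17, 17] = -ktf
    J[18, 14] = kII_III * frn; J[18, 18] = -krp - krt - kIII_IV
    J[18, 19] = kpr; J[18, 20] = ktr
    J[19, 18] = krp; J[19, 19] = -kpr - kpt - kCl3; J[19, 20] = ktp
    J[20, 18] = krt; J[20, 19] = kpt; J[20, 20] = -ktr - ktp
    J[21, 18] = kIII_IV; J[21, 21] = -krp - krt; J[21, 22] = kpr; J[21, 23] = ktr
    J[22, 21] = krp; J[22, 22] = -kpr - kpt - kCl4; J[22, 23] = ktp
    J[23, 21] = krt; J[23, 22] = kpt; J[23, 23] = -ktr - ktp
    J[24, 3] = kClI
    J[25, 0] = (1.0 - Fbio) * ka1; J[25, 1] = (1.0 - Fbio) * ka
    return J


def rhs(
    t: float,
    y: np.ndarray,
    dr: DerivedRates,
    fe: FixedEffects,
    rS_eff: float | None = None,
) -> np.ndarray:
    """Time derivative of the 24 state amounts (pmol/h).

    ``rS_eff`` is the effective angiotensin I production rate in pmol/h;
    ``None`` uses the steady-state-constrained default
    (:func:`effective_production`).
    """
    y = np.asarray(y, dtype=float)
    if y.shape not in ((N_STATES,), (N_STATES_AUG,)):
        raise ValueError(f"state vector must have {N_STATES} (or {N_STATES_AUG}) entries")
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t}")
    if rS_eff is None:
        rS_eff = effective_production(fe, dr)
    n = y.shape[0]
    if n == N_STATES:
        y = np.concatenate([y, np.zeros(2)])
    d = _rhs_nb(float(t), y, pack_theta(dr, fe, float(rS_eff)))
    return d[:n]


def initial_state(
    fe: FixedEffects,
    dr: DerivedRates,
    mode: InitMode | str = InitMode.BASELINE_ANCHORED,
    burn_in_days: float = 10.0,
    rS_eff: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> np.ndarray:
    """Drug-free initial state (pmol).

    ``baseline-anchored`` puts every angiotensin pool at its printed baseline
    concentration times its compartment volume (angiotensins III/IV are split
    across renal and plasma sub-volumes at equal concentration) and puts the
    ACE species at the algebraic substrate-binding equilibrium
    ``k_m1 * E * S = (k1 + k2) * ES`` with ``E + ES`` fixed to the
    compartment's ACE total and no inhibitor bound.  ``burn-in`` additionally
    integrates the system drug-free for ``burn_in_days`` so it relaxes onto
    its own 24-h limit cycle; the returned state is at simulation time 0
    (midnight).

    The returned vector has :data:`N_STATES_AUG` entries: the 24 model
    states followed by the two (zero) drug-mass audit accumulators.
    """
    mode = InitMode(mode)
    idx = StateIndex
    y = np.zeros(N_STATES_AUG)
    Vfr, Vts = dr.Vfr, fe.Vts
    y[idx.S_fr] = fe.S0 * Vfr
    y[idx.S_ts] = fe.S0 * Vts
    y[idx.P_fr] = fe.P0 * Vfr
    y[idx.P_ts] = fe.P0 * Vts
    y[idx.A17_fr] = fe.Ang17_0 * Vfr
    y[idx.A17_ts] = fe.Ang17_0 * Vts
    y[idx.AIII_rn] = fe.AngIII0 * fe.Vrn
    y[idx.AIII_pl] = fe.AngIII0 * fe.Vpl
    y[idx.AIII_ts] = fe.AngIII0 * Vts
    y[idx.AIV_rn] = fe.AngIV0 * fe.Vrn
    y[idx.AIV_pl] = fe.AngIV0 * fe.Vpl
    y[idx.AIV_ts] = fe.AngIV0 * Vts
    # ES equilibrium with the substrate pool anchored: the conservation
    # constraint E + ES = E_total makes the equilibrium condition linear in ES
    for e_tot, s_ix, e_ix, es_ix in (
        (dr.E_fr_total, idx.S_fr, idx.E_fr, idx.ES_fr),
        (dr.E_ts_total, idx.S_ts, idx.E_ts, idx.ES_ts),
    ):
        s = y[s_ix]
        es = e_tot * dr.k_m1 * s / (dr.k1 + dr.k2 + dr.k_m1 * s)
        if not 0.0 <= es <= e_tot:
            raise ConfigurationError("no admissible enzyme-substrate equilibrium root")
        y[es_ix] = es
        y[e_ix] = e_tot - es

    if mode is InitMode.BASELINE_ANCHORED:
        return y

    if rS_eff is None:
        rS_eff = effective_production(fe, dr)
    th = pack_theta(dr, fe, rS_eff)
    t0 = -float(burn_in_days) * 24.0
    sol = solve_ivp(
        _rhs_nb, (t0, 0.0), y, method="LSODA", jac=_jac_nb,
        args=(th,), rtol=rtol, atol=atol, dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"burn-in integration failed: {sol.message}")
    return sol.y[:, -1]


def effective_production(
    fe: FixedEffects,
    dr: DerivedRates,
    mode: ProductionMode | str = ProductionMode.STEADY_STATE,
) -> float:
    """Effective angiotensin I production rate (pmol/h).

    ``steady-state-constrained`` (default) chooses the rate that makes the
    free-circulation angiotensin I pool stationary at the baseline-anchored
    drug-free state with the chronobiology modulation at its zero crossing:
    production then balances clearance, conversion to angiotensin (1-7),
    net tissue transfer and net enzymatic consumption.  ``table-value``
    returns the published relative production rate converted to pmol/h.
    """
    mode = ProductionMode(mode)
    if mode is ProductionMode.TABLE_VALUE:
        return dr.rS_table
    y0 = initial_state(fe, dr, InitMode.BASELINE_ANCHORED)
    th = pack_theta(dr, fe, 0.0)
    th[30] = 0.0  # delta24hr = 0: evaluate at the cosine zero level
    d0 = _rhs_nb(0.0, y0, th)
    rs = -float(d0[StateIndex.S_fr])
    if rs < 0:
        raise ConfigurationError(
            "steady-state-constrained production is negative; "
            "parameter overrides are inconsistent"
        )
    return rs


def observe(
    y: np.ndarray,
    dr: DerivedRates,
    noise: dict[str, float] | None = None,
) -> dict[str, float]:
    """Map a state vector to plasma concentrations (pmol/L).

    The benazeprilat observation sums free, non-specifically bound and
    ACE-bound drug; angiotensins III/IV sum their plasma and renal pools.
    All are divided by the free-circulation volume.  ``noise`` optionally
    supplies per-analyte proportional-error draws ``eps`` so that the
    observation is ``C * (1 + eps)``.
    """
    y = np.maximum(np.asarray(y, dtype=float), 0.0)  # solver tolerance band
    idx = StateIndex
    conc = {
        "benazeprilat": (y[idx.I_fr] + y[idx.I_ns] + y[idx.EI_fr]) / dr.Vfr,
        "AngI": y[idx.S_fr] / dr.Vfr,
        "AngII": y[idx.P_fr] / dr.Vfr,
        "Ang17": y[idx.A17_fr] / dr.Vfr,
        "AngIII": (y[idx.AIII_pl] + y[idx.AIII_rn]) / dr.Vfr,
        "AngIV": (y[idx.AIV_pl] + y[idx.AIV_rn]) / dr.Vfr,
    }
    if noise:
        for k, eps in noise.items():
            if k not in conc:
                raise ValueError(f"unknown analyte {k!r}")
            conc[k] = conc[k] * (1.0 + eps)
    return conc


#: observation matrix mapping states to the 6 analyte concentrations
def observation_matrix(dr: DerivedRates) -> np.ndarray:
    """6 x 24 linear map from state amounts to analyte concentrations."""
    M = np.zeros((len(ANALYTES), N_STATES))
    idx = StateIndex
    v = 1.0 / dr.Vfr
    M[0, [idx.I_fr, idx.I_ns, idx.EI_fr]] = v
    M[1, idx.S_fr] = v
    M[2, idx.P_fr] = v
    M[3, idx.A17_fr] = v
    M[4, [idx.AIII_pl, idx.AIII_rn]] = v
    M[5, [idx.AIV_pl, idx.AIV_rn]] = v
    return M


def integrate_segment(
    y0: np.ndarray,
    t_span: tuple[float, float],
    theta: np.ndarray,
    t_eval: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    context: str = "",
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the stiff system over one dose-free segment.

    Returns ``(states_at_t_eval, state_at_t_end)``.  Uses LSODA with the
    analytic Jacobian; failures raise :class:`IntegrationError` carrying the
    segment and caller context.
    """
    te = list(t_eval) if t_eval is not None else []
    if te and te[-1] >= t_span[1]:
        eval_pts = np.asarray(te, dtype=float)
        drop_last = False
    else:
        eval_pts = np.asarray(te + [t_span[1]], dtype=float)
        drop_last = True
    sol = solve_ivp(
        _rhs_nb, t_span, np.asarray(y0, dtype=float), method="LSODA",
        jac=_jac_nb, args=(theta,), rtol=rtol, atol=atol, t_eval=eval_pts,
    )
    if not sol.success:
        raise IntegrationError(
            f"integration failed on segment {t_span} ({context}): {sol.message}"
        )
    if drop_last:
        return sol.y[:, :-1], sol.y[:, -1]
    return sol.y, sol.y[:, -1].copy()
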