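"""Minimal multiscale model of T-cell-dependent anti-drug-antibody induction.

The model chains three scales, mirroring how a therapeutic protein product
(TPP) elicits ADA through cognate T-cell help:

whole body
    Subcutaneous depot -> central (plasma) <-> peripheral two-compartment
    pharmacokinetics with first-order elimination plus an ADA-mediated
    clearance term proportional to total ADA x drug.
subcellular (antigen-presenting cell)
    Plasma drug is internalized into the APC endosome at rate IR
    (default IR0 = 14.4 day^-1) and degraded at rate DR (default
    DR0 = 17.28 day^-1) into epitope peptides, one pool per epitope.
    Peptides load onto a finite surface pool of MHC class II molecules
    through competitive, saturable loading; surface complexes of epitope j
    are lost at a rate proportional to the epitope's MHC dissociation
    constant Kd_j, so high-affinity (low-Kd) epitopes accumulate more
    complexes.  Two structural consequences hold by construction: the
    steady-state endosomal level scales as IR/DR, and the steady-state
    peptide supply is independent of DR, so faster degradation empties the
    endosome without producing more peptide.
cellular
    A danger signal (LPS-equivalent, ng) matures dendritic cells through a
    Hill dose-response; T-cell help is the product of mature-DC level and
    a Hill function of the best-presented epitope (max over j of surface
    complexes M_j).  B cells sit on a 17-point geometric ladder of
    antigen-binding Kd; subgroup i precursors activate at a rate
    proportional to T help x drug occupancy at their ladder Kd, drift one
    rung toward higher affinity (affinity maturation), and differentiate
    into plasma cells secreting subgroup-specific ADA.  Total ADA is the
    sum over the 17 subgroups and feeds back on drug clearance.

All parameters printed for the adalimumab case (rates, epitope Kd sets,
danger-signal amounts, dose ladder) enter verbatim; the remaining rate
constants are a single frozen calibration shipped as the defaults below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "Regimen",
    "Epitope",
    "PkParams",
    "SubcellularParams",
    "CellularParams",
    "AdaScenario",
    "AdaTrajectory",
    "AdaResult",
    "SubcellularSteadyState",
    "AdaModelError",
    "simulate_pk",
    "simulate_subcellular",
    "subcellular_steady_state",
    "simulate_cellular",
    "run_scenario",
    "N_SUBGROUPS",
    "default_kd_ladder",
]

N_SUBGROUPS = 17

IR0 = 14.4  # day^-1, baseline endosomal internalization rate
DR0 = 17.28  # day^-1, baseline endosomal degradation rate


class AdaModelError(ValueError):
    """Invalid parameter or scenario configuration."""


@dataclass(frozen=True)
class Regimen:
    """Dosing schedule: repeated equal doses at a fixed interval."""

    dose_mg: float
    interval_days: float = 14.0  # biweekly
    n_doses: int = 6
    mw_g_per_mol: float = 150_000.0  # IgG-class monoclonal antibody

    def __post_init__(self) -> None:
        if self.dose_mg < 0:
            raise AdaModelError(f"dose must be >= 0 mg, got {self.dose_mg}")
        if self.interval_days <= 0:
            raise AdaModelError(f"dose interval must be > 0, got {self.interval_days}")
        if self.n_doses < 1:
            raise AdaModelError("need at least one dose")
        if self.mw_g_per_mol <= 0:
            raise AdaModelError("molecular weight must be > 0")

    @property
    def dose_pmol(self) -> float:
        return self.dose_mg / self.mw_g_per_mol * 1e9

    @property
    def dose_times(self) -> np.ndarray:
        return self.interval_days * np.arange(self.n_doses)


@dataclass(frozen=True)
class Epitope:
    """MHC class II epitope with dissociation constant in nM."""

    kd_mhc_nM: float
    copies_per_molecule: int = 1

    def __post_init__(self) -> None:
        if self.kd_mhc_nM <= 0:
            raise AdaModelError(f"epitope Kd must be > 0 nM, got {self.kd_mhc_nM}")
        if self.copies_per_molecule < 1:
            raise AdaModelError("epitope copy number must be >= 1")


@dataclass(frozen=True)
class PkParams:
    """Two-compartment PK with depot absorption and ADA-mediated clearance."""

    ka: float = 0.25  # day^-1, depot absorption
    k_el: float = 0.0462  # day^-1, linear elimination (t1/2 ~ 15 days)
    k_cp: float = 0.3  # day^-1, central -> peripheral
    k_pc: float = 0.15  # day^-1, peripheral -> central
    v_central_L: float = 3.0
    k_ada_clear: float = 1e-5  # pM^-1 day^-1, ADA-complex-mediated elimination

    def __post_init__(self) -> None:
        for name in ("ka", "k_el", "k_cp", "k_pc", "k_ada_clear"):
            if getattr(self, name) < 0:
                raise AdaModelError(f"PK rate {name} must be >= 0")
        if self.v_central_L <= 0:
            raise AdaModelError("central volume must be > 0 L")


def _default_epitopes() -> tuple[Epitope, ...]:
    # Two predicted adalimumab epitopes with high affinity for DRB1*04:01.
    return (Epitope(123.0), Epitope(85.0))


@dataclass(frozen=True)
class SubcellularParams:
    """Endosomal processing and MHC class II loading parameters."""

    internalization_rate: float = IR0  # day^-1
    degradation_rate: float = DR0  # day^-1
    epitopes: tuple[Epitope, ...] = field(default_factory=_default_epitopes)
    peptide_decay: float = 10.0  # day^-1, loss of free peptide pools
    mhc_total: float = 1e5  # MHC II molecules per APC
    k_load: float = 1.0  # day^-1, maximal per-MHC loading rate
    km_load: float = 1e-4  # peptide units, loading half-saturation
    k_surf: float = 0.1  # day^-1 nM^-1, surface loss coefficient x Kd

    def __post_init__(self) -> None:
        object.__setattr__(self, "epitopes", tuple(self.epitopes))
        if self.internalization_rate <= 0 or self.degradation_rate <= 0:
            raise AdaModelError("internalization and degradation rates must be > 0")
        if not self.epitopes:
            raise AdaModelError("at least one epitope is required")
        for bad in ("peptide_decay", "mhc_total", "k_load", "km_load", "k_surf"):
            if getattr(self, bad) <= 0:
                raise AdaModelError(f"{bad} must be > 0")


def default_kd_ladder(
    n: int = N_SUBGROUPS, kd_low_pM: float = 1e6, kd_high_pM: float = 1e2
) -> np.ndarray:
    """Geometric antigen-binding Kd ladder, subgroup 1 (weak) -> n (strong).

    Spans 1 uM down to 0.1 nM, the affinity window of a maturing antibody
    response; strictly decreasing in Kd as required of the subgroups.
    """
    return np.geomspace(kd_low_pM, kd_high_pM, n)


@dataclass(frozen=True)
class CellularParams:
    """Danger-signal, T-help and affinity-structured B-cell parameters."""

    danger_signal_ng: float = 350.0  # LPS-equivalent
    ds_ec50_ng: float = 5000.0
    ds_hill: float = 2.0
    t_help_gain: float = 1.0
    m50_complexes: float = 2000.0  # T-activation half-saturation (per APC)
    m_hill: float = 2.0
    kd_ladder_pM: tuple[float, ...] = field(
        default_factory=lambda: tuple(default_kd_ladder())
    )
    precursor_ratio: float = 0.5  # subgroup i precursor pool = ratio**(i-1)
    k_act: float = 1.0  # day^-1, naive activation scale
    k_mat: float = 0.4  # day^-1, one-rung affinity-maturation drift
    k_plasma: float = 0.1  # day^-1, plasma-cell differentiation
    d_bcell: float = 0.05  # day^-1
    d_plasma: float = 0.05  # day^-1
    k_secrete: float = 100.0  # pM day^-1 per plasma-cell unit
    d_ada: float = 0.033  # day^-1, IgG catabolism (t1/2 ~ 21 days)

    def __post_init__(self) -> None:
        ladder = np.asarray(self.kd_ladder_pM, dtype=float)
        object.__setattr__(self, "kd_ladder_pM",
                           tuple(float(x) for x in ladder))
        if ladder.size != N_SUBGROUPS:
            raise AdaModelError(
                f"the B-cell ladder must have exactly {N_SUBGROUPS} subgroups, "
                f"got {ladder.size}"
            )
        if not np.all(np.diff(ladder) < 0):
            raise AdaModelError("the Kd ladder must be strictly decreasing")
        if self.danger_signal_ng < 0:
            raise AdaModelError("danger signal must be >= 0 ng")
        if not 0 < self.precursor_ratio <= 1:
            raise AdaModelError("precursor_ratio must lie in (0, 1]")
        for name in ("ds_ec50_ng", "ds_hill", "m50_complexes", "m_hill"):
            if getattr(self, name) <= 0:
                raise AdaModelError(f"{name} must be > 0")
        for name in ("t_help_gain", "k_act", "k_mat", "k_plasma",
                     "d_bcell", "d_plasma", "k_secrete", "d_ada"):
            if getattr(self, name) < 0:
                raise AdaModelError(f"{name} must be >= 0")

    def mature_dc(self, danger_signal_ng: float | None = None) -> float:
        """Mature dendritic-cell level: Hill response to the danger signal."""
        ds = self.danger_signal_ng if danger_signal_ng is None else danger_signal_ng
        if ds <= 0:
            return 0.0
        x = (ds / self.ds_ec50_ng) ** self.ds_hill
        return x / (1.0 + x)


@dataclass(frozen=True)
class AdaScenario:
    """A complete runnable configuration of the multiscale model."""

    name: str
    regimen: Regimen
    subcellular: SubcellularParams = field(default_factory=SubcellularParams)
    cellular: CellularParams = field(default_factory=CellularParams)
    pk: PkParams = field(default_factory=PkParams)
    t_end: float | None = None  # default: dosing span + 28-day washout
    reference: "str | None" = None  # name of the fold-change reference

    @property
    def horizon(self) -> float:
        if self.t_end is not None:
            return self.t_end
        return self.regimen.interval_days * self.regimen.n_doses + 28.0


@dataclass
class AdaTrajectory:
    """Time courses of every model compartment on a uniform output grid."""

    t: np.ndarray
    plasma_drug_pM: np.ndarray
    endosomal_antigen: np.ndarray
    peptides: np.ndarray  # shape (nt, n_epitopes)
    surface_complexes: np.ndarray  # shape (nt, n_epitopes), per APC
    ada_subgroups: np.ndarray  # shape (nt, 17), pM

    @property
    def ada_total(self) -> np.ndarray:
        return self.ada_subgroups.sum(axis=1)

    def cumulative_ada(self) -> float:
        """Time integral of total ADA over the simulated course (pM * day)."""
        return float(np.trapezoid(self.ada_total, self.t))

    def mean_log10_affinity(self, ladder_pM: Sequence[float]) -> np.ndarray:
        """Abundance-weighted mean log10 association constant of ADA (per M).

        NaN where total ADA is zero (no antibody yet).
        """
        log_ka = -np.log10(np.asarray(ladder_pM) * 1e-12)
        total = self.ada_total
        with np.errstate(invalid="ignore", divide="ignore"):
            return (self.ada_subgroups @ log_ka) / np.where(total > 0, total, np.nan)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t_day": self.t, "plasma_drug_pM": self.plasma_drug_pM,
                           "endosomal_antigen": self.endosomal_antigen})
        for j in range(self.peptides.shape[1]):
            df[f"peptide_{j + 1}"] = self.peptides[:, j]
            df[f"mhc_complex_{j + 1}"] = self.surface_complexes[:, j]
        for i in range(N_SUBGROUPS):
            df[f"ada_sub_{i + 1}_pM"] = self.ada_subgroups[:, i]
        df["ada_total_pM"] = self.ada_total
        return df


@dataclass
class AdaResult:
    """Trajectory plus scalar summaries for one scenario run."""

    scenario: AdaScenario
    trajectory: AdaTrajectory
    cumulative_ada: float
    fold_change: float | None = None  # vs the reference scenario, if given

    def summary(self) -> dict:
        out = {
            "scenario": self.scenario.name,
            "cumulative_ada_pM_day": self.cumulative_ada,
            "final_ada_pM": float(self.trajectory.ada_total[-1]),
            "peak_plasma_drug_pM": float(self.trajectory.plasma_drug_pM.max()),
        }
        if self.fold_change is not None:
            out["ada_fold_change_vs_reference"] = self.fold_change
        return out


# ---------------------------------------------------------------------------
# Whole-body PK


def simulate_pk(
    regimen: Regimen,
    pk: PkParams = PkParams(),
    ada_total: float | Callable[[float], float] = 0.0,
    t_end: float | None = None,
    dt_out: float = 0.1,
) -> pd.DataFrame:
    """Plasma drug time course under repeated dosing.

    ``ada_total`` may be a constant (pM) or a callable of time, modelling
    ADA-complex-mediated elimination on top of linear clearance.  Returns a
    frame with depot/central/peripheral amounts (pmol) and the plasma
    concentration in pM.
    """
    ada_fn = ada_total if callable(ada_total) else (lambda t: float(ada_total))
    horizon = t_end if t_end is not None else (
        regimen.interval_days * regimen.n_doses + 28.0
    )

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        depot, central, periph = y
        conc = central / pk.v_central_L  # pmol/L == pM
        return np.array([
            -pk.ka * depot,
            pk.ka * depot - (pk.k_el + pk.k_cp) * central
            + pk.k_pc * periph - pk.k_ada_clear * ada_fn(t) * conc * pk.v_central_L,
            pk.k_cp * central - pk.k_pc * periph,
        ])

    t_grid = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    y = np.zeros(3)
    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    # integrate piecewise between dose times, bolus into depot at each dose
    segments = list(regimen.dose_times[regimen.dose_times < horizon]) + [horizon]
    y[0] += regimen.dose_pmol  # first dose at t = 0
    start = 0.0
    for end in segments[1:]:
        mask = (t_grid >= start) & (t_grid <= end)
        te = np.unique(np.concatenate([[start], t_grid[mask], [end]]))
        sol = solve_ivp(rhs, (start, end), y, method="LSODA",
                        rtol=1e-9, atol=1e-12, t_eval=te)
        if not sol.success:
            raise AdaModelError(f"PK integration failed: {sol.message}")
        rows_t.append(sol.t[:-1] if end != segments[-1] else sol.t)
        rows_y.append(sol.y[:, :-1].T if end != segments[-1] else sol.y.T)
        y = sol.y[:, -1].copy()
        if end != segments[-1]:
            y[0] += regimen.dose_pmol
        start = end
    t = np.concatenate(rows_t)
    ys = np.vstack(rows_y)
    return pd.DataFrame({
        "t_day": t,
        "depot_pmol": ys[:, 0],
        "central_pmol": ys[:, 1],
        "peripheral_pmol": ys[:, 2],
        "plasma_pM": ys[:, 1] / pk.v_central_L,
    })


# ---------------------------------------------------------------------------
# Subcellular antigen processing and presentation


def _subcellular_rhs(
    sub: SubcellularParams,
) -> tuple[Callable[[float, np.ndarray, float], np.ndarray], int]:
    n_ep = len(sub.epitopes)
    copies = np.array([e.copies_per_molecule for e in sub.epitopes], dtype=float)
    k_off_surf = sub.k_surf * np.array([e.kd_mhc_nM for e in sub.epitopes])

    def rhs(t: float, y: np.ndarray, drug_nM: float) -> np.ndarray:
        E = y[0]
        P = y[1:1 + n_ep]
        M = y[1 + n_ep:1 + 2 * n_ep]
        dE = sub.internalization_rate * drug_nM - sub.degradation_rate * E
        dP = copies * sub.degradation_rate * E - sub.peptide_decay * P
        mhc_free = max(sub.mhc_total - M.sum(), 0.0)
        denom = sub.km_load + P.sum()
        load = sub.k_load * mhc_free * P / denom
        dM = load - k_off_surf * M
        return np.concatenate(([dE], dP, dM))

    return rhs, n_ep


def simulate_subcellular(
    drug_nM: float | Callable[[float], float],
    sub: SubcellularParams = SubcellularParams(),
    t_end: float = 28.0,
    dt_out: float = 0.1,
) -> pd.DataFrame:
    """Endosomal antigen, peptide pools and surface MHC II complexes.

    ``drug_nM`` is the plasma drug concentration driving uptake, either a
    constant or a callable of time (days).  Returns a frame with one
    peptide and one surface-complex column per epitope.
    """
    drug_fn = drug_nM if callable(drug_nM) else (lambda t: float(drug_nM))
    rhs, n_ep = _subcellular_rhs(sub)
    y0 = np.zeros(1 + 2 * n_ep)
    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(lambda t, y: rhs(t, y, drug_fn(t)), (0.0, t_end), y0,
                    method="LSODA", rtol=1e-10, atol=1e-14, t_eval=t_eval)
    if not sol.success:
        raise AdaModelError(f"subcellular integration failed: {sol.message}")
    df = pd.DataFrame({"t_day": sol.t, "endosomal_antigen": sol.y[0]})
    for j in range(n_ep):
        df[f"peptide_{j + 1}"] = sol.y[1 + j]
        df[f"mhc_complex_{j + 1}"] = sol.y[1 + n_ep + j]
    return df


@dataclass(frozen=True)
class SubcellularSteadyState:
    """Closed-form fixed point of the processing cascade at constant input."""

    endosomal_antigen: float
    peptides: np.ndarray
    surface_complexes: np.ndarray


def subcellular_steady_state(
    drug_nM: float, sub: SubcellularParams = SubcellularParams()
) -> SubcellularSteadyState:
    """Analytic steady state at constant plasma drug.

    E* = IR * c / DR (linear in IR, inverse in DR); P_j* = copies_j * IR *
    c / d_P, independent of DR; M_j* solves the competitive loading balance
    on the finite MHC pool.
    """
    e_star = sub.internalization_rate * drug_nM / sub.degradation_rate
    copies = np.array([e.copies_per_molecule for e in sub.epitopes], dtype=float)
    p_star = copies * sub.internalization_rate * drug_nM / sub.peptide_decay
    k_off = sub.k_surf * np.array([e.kd_mhc_nM for e in sub.epitopes])
    denom = sub.km_load + p_star.sum()
    # M_j* = k_load * F * p_j / (denom * k_off_j) with F = mhc_total - sum M
    coef = sub.k_load * p_star / (denom * k_off)
    mhc_free = sub.mhc_total / (1.0 + coef.sum())
    return SubcellularSteadyState(
        endosomal_antigen=e_star,
        peptides=p_star,
        surface_complexes=coef * mhc_free,
    )


# ---------------------------------------------------------------------------
# Cellular activation and the full coupled model


def simulate_cellular(
    surface_complexes: Callable[[float], np.ndarray] | np.ndarray,
    plasma_drug_pM: Callable[[float], float] | float,
    cell: CellularParams = CellularParams(),
    t_end: float = 112.0,
    dt_out: float = 0.1,
) -> pd.DataFrame:
    """B-cell / plasma-cell / ADA dynamics for a prescribed presentation input.

    ``surface_complexes`` supplies the per-epitope MHC II complex counts
    (array, or callable of time); T help uses the best-presented epitope
    (max over epitopes).  Useful for dissecting the cellular module on its
    own; :func:`run_scenario` couples all scales.
    """
    m_fn = (surface_complexes if callable(surface_complexes)
            else (lambda t: np.asarray(surface_complexes, dtype=float)))
    c_fn = (plasma_drug_pM if callable(plasma_drug_pM)
            else (lambda t: float(plasma_drug_pM)))
    ladder = np.asarray(cell.kd_ladder_pM)
    precursors = cell.precursor_ratio ** np.arange(N_SUBGROUPS)
    dc = cell.mature_dc()

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        B = y[:N_SUBGROUPS]
        PC = y[N_SUBGROUPS:2 * N_SUBGROUPS]
        A = y[2 * N_SUBGROUPS:]
        m_max = float(np.max(m_fn(t)))
        hill_m = (m_max ** cell.m_hill) / (m_max ** cell.m_hill
                                           + cell.m50_complexes ** cell.m_hill)
        t_help = cell.t_help_gain * dc * hill_m
        conc = c_fn(t)
        occ = conc / (conc + ladder)
        act = cell.k_act * t_help * occ * precursors
        drift_in = np.concatenate(([0.0], cell.k_mat * B[:-1]))
        dB = act + drift_in - (cell.k_mat + cell.k_plasma + cell.d_bcell) * B
        dB[-1] += cell.k_mat * B[-1]  # top rung: no further drift out
        dPC = cell.k_plasma * B - cell.d_plasma * PC
        dA = cell.k_secrete * PC - cell.d_ada * A
        return np.concatenate([dB, dPC, dA])

    t_eval = np.arange(0.0, t_end + 0.5 * dt_out, dt_out)
    sol = solve_ivp(rhs, (0.0, t_end), np.zeros(3 * N_SUBGROUPS),
                    method="LSODA", rtol=1e-8, atol=1e-12, t_eval=t_eval)
    if not sol.success:
        raise AdaModelError(f"cellular integration failed: {sol.message}")
    df = pd.DataFrame({"t_day": sol.t})
    for i in range(N_SUBGROUPS):
        df[f"ada_sub_{i + 1}_pM"] = sol.y[2 * N_SUBGROUPS + i]
    df["ada_total_pM"] = sol.y[2 * N_SUBGROUPS:].sum(axis=0)
    return df


def _full_rhs(scn: AdaScenario) -> tuple[Callable[[float, np.ndarray], np.ndarray], int]:
    pk, sub, cell = scn.pk, scn.subcellular, scn.cellular
    n_ep = len(sub.epitopes)
    copies = np.array([e.copies_per_molecule for e in sub.epitopes], dtype=float)
    k_off_surf = sub.k_surf * np.array([e.kd_mhc_nM for e in sub.epitopes])
    ladder = np.asarray(cell.kd_ladder_pM)
    precursors = cell.precursor_ratio ** np.arange(N_SUBGROUPS)
    dc = cell.mature_dc()
    i_pep = 4
    i_mhc = i_pep + n_ep
    i_b = i_mhc + n_ep
    i_pc = i_b + N_SUBGROUPS
    i_ada = i_pc + N_SUBGROUPS

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        depot, central, periph, E = y[0], y[1], y[2], y[3]
        P = y[i_pep:i_mhc]
        M = y[i_mhc:i_b]
        B = y[i_b:i_pc]
        PC = y[i_pc:i_ada]
        A = y[i_ada:]
        ada_total = A.sum()
        conc_pM = central / pk.v_central_L
        conc_nM = conc_pM * 1e-3

        d_depot = -pk.ka * depot
        d_central = (pk.ka * depot - (pk.k_el + pk.k_cp) * central
                     + pk.k_pc * periph
                     - pk.k_ada_clear * ada_total * central)
        d_periph = pk.k_cp * central - pk.k_pc * periph

        dE = sub.internalization_rate * conc_nM - sub.degradation_rate * E
        dP = copies * sub.degradation_rate * E - sub.peptide_decay * P
        mhc_free = max(sub.mhc_total - M.sum(), 0.0)
        load = sub.k_load * mhc_free * P / (sub.km_load + P.sum())
        dM = load - k_off_surf * M

        m_max = float(M.max()) if n_ep else 0.0
        if m_max > 0.0:
            x = (m_max / cell.m50_complexes) ** cell.m_hill
            hill_m = x / (1.0 + x)
        else:
            hill_m = 0.0
        t_help = cell.t_help_gain * dc * hill_m
        occ = conc_pM / (conc_pM + ladder) if conc_pM > 0 else np.zeros_like(ladder)
        act = cell.k_act * t_help * occ * precursors
        drift_in = np.concatenate(([0.0], cell.k_mat * B[:-1]))
        dB = act + drift_in - (cell.k_mat + cell.k_plasma + cell.d_bcell) * B
        dB[-1] += cell.k_mat * B[-1]
        dPC = cell.k_plasma * B - cell.d_plasma * PC
        dA = cell.k_secrete * PC - cell.d_ada * A

        return np.concatenate(([d_depot, d_central, d_periph, dE], dP, dM,
                               dB, dPC, dA))

    return rhs, n_ep


def run_scenario(
    scenario: AdaScenario,
    reference: "AdaScenario | AdaResult | None" = None,
    dt_out: float = 0.1,
) -> AdaResult:
    """Simulate the fully coupled multiscale model for one scenario.

    If ``reference`` is given (a scenario, or a previously computed
    result), the summary carries the cumulative-ADA fold change
    scenario / reference.  A scenario that names a reference but is run
    without one raises a configuration error only when the fold change is
    requested through the scenario's ``reference`` field being set.
    """
    rhs, n_ep = _full_rhs(scenario)
    reg = scenario.regimen
    horizon = scenario.horizon
    nstate = 4 + 2 * n_ep + 3 * N_SUBGROUPS
    y = np.zeros(nstate)
    t_grid = np.arange(0.0, horizon + 0.5 * dt_out, dt_out)
    dose_times = reg.dose_times[reg.dose_times < horizon]
    segments = list(dose_times) + [horizon]
    y[0] += reg.dose_pmol
    rows_t: list[np.ndarray] = []
    rows_y: list[np.ndarray] = []
    start = 0.0
    for end in segments[1:]:
        mask = (t_grid >= start) & (t_grid < end)
        te = np.unique(np.concatenate([[start], t_grid[mask], [end]]))
        sol = solve_ivp(rhs, (start, end), y, method="LSODA",
                        rtol=1e-8, atol=1e-10, t_eval=te)
        if not sol.success:
            raise AdaModelError(
                f"multiscale integration failed on [{start}, {end}]: {sol.message}"
            )
        last = end == segments[-1]
        rows_t.append(sol.t if last else sol.t[:-1])
        rows_y.append(sol.y.T if last else sol.y[:, :-1].T)
        y = sol.y[:, -1].copy()
        if not last:
            y[0] += reg.dose_pmol
        start = end
    t = np.concatenate(rows_t)
    ys = np.vstack(rows_y)
    i_pep = 4
    i_mhc = i_pep + n_ep
    i_b = i_mhc + n_ep
    i_ada = i_b + 2 * N_SUBGROUPS
    traj = AdaTrajectory(
        t=t,
        plasma_drug_pM=ys[:, 1] / scenario.pk.v_central_L,
        endosomal_antigen=ys[:, 3],
        peptides=ys[:, i_pep:i_mhc],
        surface_complexes=ys[:, i_mhc:i_b],
        ada_subgroups=np.clip(ys[:, i_ada:], 0.0, None),
    )
    result = AdaResult(scenario=scenario, trajectory=traj,
                       cumulative_ada=traj.cumulative_ada())
    if reference is None and scenario.reference is not None:
        raise AdaModelError(
            f"scenario '{scenario.name}' declares reference "
            f"'{scenario.reference}' but none was supplied"
        )
    if reference is not None:
        ref_result = (reference if isinstance(reference, AdaResult)
                      else run_scenario(reference, dt_out=dt_out))
        if ref_result.cumulative_ada == 0.0:
            result.fold_change = math.inf if result.cumulative_ada > 0 else 1.0
        else:
            result.fold_change = result.cumulative_ada / ref_result.cumulative_ada
    return result
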