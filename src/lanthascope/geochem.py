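"""Seawater chemical equilibrium: C, P and La speciation and LaPO4 solubility.

Solves a small mass-action tableau for a seawater-like solution (components
Na, K, Cl, Mg, Ca, SO4, dissolved inorganic carbon, total phosphate, total
lanthanum): Newton iteration on log free concentrations of the non-proton
components at fixed pH, nested inside Brent root-finding on pH that closes
the carbonate-alkalinity proton condition.  Alkalinity -- not charge balance
-- closes the system: the canonical surface-seawater recipe used here is
electrically imbalanced by ~8.7e-4 eq/kg as printed, so net charge is
reported as a diagnostic only.  Activities follow the Davies equation (with
the 0.3 I term); formation constants are 25 degC reference values corrected
to the working temperature by van't Hoff where enthalpies are available.

The headline derived quantity is the total dissolved La concentration in
equilibrium with LaPO4(s) as CO2 is varied at constant alkalinity: rising pH
raises the PO4(3-) activity (lowering La solubility) but strips free La(3+)
into carbonate complexes (raising it), producing a shallow solubility minimum
near pH 8.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

COMPONENTS = ("H", "Na", "K", "Cl", "Mg", "Ca", "SO4", "CO3", "PO4", "La")

#: nominal charge of each component as supplied in a recipe (for the charge
#: imbalance diagnostic; DIC is supplied as bicarbonate, P as orthophosphate)
_RECIPE_CHARGES = {"Na": 1, "K": 1, "Cl": -1, "Mg": 2, "Ca": 2, "SO4": -2,
                   "CO3": -1, "PO4": -3, "La": 3}

# Alkalinity weights per species follow the proton condition w = 2*nu_CO3 -
# nu_H (CO2 / H2O reference levels), so ion-paired carbonate (MgCO3, CaCO3,
# LaCO3+, ...) counts as a proton acceptor exactly like free CO3--.  This
# reduces to the familiar [HCO3-] + 2[CO3--] + [OH-] - [H+] when no ion pairs
# are present and keeps alkalinity strictly monotone in pH.  Phosphate terms
# (w = 2*nu_PO4 - nu_H, H2PO4- reference) are excluded by default: at typical
# seawater phosphate (<= 1e-6 mol/kg) they are negligible.

_MANDATORY_SPECIES = {
    "OH-", "CO2(aq)", "HCO3-", "CO3-2",
    "H3PO4", "H2PO4-", "HPO4-2", "PO4-3",
    "LaOH+2", "LaCO3+", "La(CO3)2-", "LaHCO3+2", "LaSO4+",
    "MgCO3", "CaCO3", "MgSO4", "CaSO4", "NaSO4-",
    "LaPO4(s)",
}

R_GAS = 8.314462618  # J / (mol K)

# Debye-Hueckel A parameter (log10 basis) vs temperature in degC
_DH_A_TEMPS = np.array([0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0])
_DH_A_VALUES = np.array([0.4913, 0.4943, 0.4976, 0.5012, 0.5050, 0.5092,
                         0.5137, 0.5241])


class ConvergenceError(RuntimeError):
    """Raised when the Newton solver fails to close the mass balances."""


@dataclass(frozen=True)
class SpeciesDef:
    """One aqueous species or mineral: stoichiometry over the component basis
    plus a log10 formation constant at the 25 degC reference state."""

    name: str
    stoich: tuple[float, ...]          # aligned with COMPONENTS
    charge: int
    logk25: float
    delta_h_kj_mol: float | None
    kind: str                          # "basis" | "aqueous" | "mineral"
    source: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("basis", "aqueous", "mineral"):
            raise ValueError(f"{self.name}: unknown kind {self.kind!r}")
        if not any(self.stoich):
            raise ValueError(f"{self.name}: stoichiometry is all zero")
        if not math.isfinite(self.logk25):
            raise ValueError(f"{self.name}: non-finite log K")

    def logk_at(self, temperature_c: float) -> float:
        """Van't Hoff-corrected log10 K (no correction without an enthalpy)."""
        if self.delta_h_kj_mol is None:
            return self.logk25
        t = temperature_c + 273.15
        return self.logk25 - (self.delta_h_kj_mol * 1000.0 / (R_GAS * math.log(10))
                              ) * (1.0 / t - 1.0 / 298.15)


def load_constants(path: str | Path | None = None) -> list[SpeciesDef]:
    """Load the thermodynamic constants table (package data by default).

    Validates that the mandatory species set is present, that names are
    unique, that exactly one mineral (LaPO4) is defined, and that its Ksp
    falls in the accepted literature range (10^-26 .. 10^-25).
    """
    if path is None:
        with resources.as_file(
            resources.files("lanthascope.data") / "constants.csv"
        ) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    required_cols = {"name", "kind", "charge", "logk25"} | set(COMPONENTS)
    missing_cols = required_cols - set(df.columns)
    if missing_cols:
        raise ValueError(f"constants table missing columns {sorted(missing_cols)}")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate species names: {dups}")
    species = [
        SpeciesDef(
            name=row["name"],
            stoich=tuple(float(row[c]) for c in COMPONENTS),
            charge=int(row["charge"]),
            logk25=float(row["logk25"]),
            delta_h_kj_mol=None if pd.isna(row.get("delta_h_kj_mol"))
            else float(row["delta_h_kj_mol"]),
            kind=row["kind"],
            source=str(row.get("source", "")),
        )
        for _, row in df.iterrows()
    ]
    names = {s.name for s in species}
    absent = _MANDATORY_SPECIES - names
    if absent:
        raise ValueError(f"constants table lacks mandatory species {sorted(absent)}")
    minerals = [s for s in species if s.kind == "mineral"]
    if len(minerals) != 1:
        raise ValueError(f"expected exactly 1 mineral, found {len(minerals)}")
    ksp = minerals[0].logk25
    if not (-26.0 <= ksp <= -25.0):
        raise ValueError(
            f"Ksp(LaPO4) = 10^{ksp} outside the accepted range 10^-26..10^-25"
        )
    return species


@dataclass(frozen=True)
class ComponentTotals:
    """Total molalities per component (mol/kg) plus T, P and alkalinity.

    ``totals['CO3']`` is total dissolved inorganic carbon, ``totals['PO4']``
    total phosphate and ``totals['La']`` total lanthanum.  ``alkalinity`` is
    carbonate alkalinity in eq/kg and closes the proton condition.
    """

    totals: dict[str, float] = field(default_factory=dict)
    temperature_c: float = 15.0
    pressure_bar: float = 1.0
    alkalinity: float = 0.0

    def __post_init__(self) -> None:
        for name, value in self.totals.items():
            if name not in COMPONENTS or name == "H":
                raise ValueError(f"unknown component {name!r}")
            if value < 0 or not math.isfinite(value):
                raise ValueError(f"total for {name} must be finite and >= 0")
        if not (math.isfinite(self.temperature_c) and math.isfinite(self.pressure_bar)):
            raise ValueError("temperature and pressure must be finite")

    def with_dic(self, dic: float) -> "ComponentTotals":
        totals = dict(self.totals)
        totals["CO3"] = dic
        return replace(self, totals=totals)


def seawater_recipe(temperature_c: float = 15.0,
                    phosphate: float = 1e-6,
                    la_total: float = 20e-12) -> ComponentTotals:
    """The canonical surface-seawater composition used throughout: Na 0.468,
    Cl 0.546, Mg 0.0533, SO4 0.0281, HCO3 0.0023 (taken as the DIC total and
    as the carbonate alkalinity), Ca 0.0104, K 0.00997 mol/kg, at 15 degC and
    1 bar, with trace phosphate and lanthanum."""
    return ComponentTotals(
        totals={
            "Na": 0.468, "Cl": 0.546, "Mg": 0.0533, "SO4": 0.0281,
            "CO3": 0.0023, "Ca": 0.0104, "K": 0.00997,
            "PO4": phosphate, "La": la_total,
        },
        temperature_c=temperature_c,
        pressure_bar=1.0,
        alkalinity=0.0023,
    )


def charge_imbalance(totals: ComponentTotals) -> float:
    """Net charge (eq/kg) of the recipe as supplied -- diagnostic only."""
    return sum(_RECIPE_CHARGES[c] * v for c, v in totals.totals.items())


def davies_log_gamma(charge: int, ionic_strength: float,
                     temperature_c: float) -> float:
    """Davies equation with the 0.3 I linear term (log10 activity coefficient)."""
    if ionic_strength <= 0 or charge == 0:
        return 0.0
    a = float(np.interp(temperature_c, _DH_A_TEMPS, _DH_A_VALUES))
    sqrt_i = math.sqrt(ionic_strength)
    return -a * charge ** 2 * (sqrt_i / (1.0 + sqrt_i) - 0.3 * ionic_strength)


@dataclass
class EquilibriumState:
    """A solved speciation state: molalities, activities, pH and derived
    saturation quantities for one seawater condition."""

    molalities: dict[str, float]
    activities: dict[str, float]
    log_gamma: dict[str, float]
    ph: float
    ionic_strength: float
    temperature_c: float
    alkalinity: float
    residuals: dict[str, float]          # relative mass-balance residuals
    fraction_co3_of_dic: float
    fraction_po4_of_p: float
    fraction_la_free: float
    si_lapo4: float | None
    charge_imbalance: float
    converged: bool
    _log_m_basis: dict[str, float] = field(default_factory=dict, repr=False)


def _active_setup(totals: ComponentTotals, species: list[SpeciesDef]):
    """Select active components and the aqueous species they support."""
    active = [c for c in COMPONENTS if c != "H" and totals.totals.get(c, 0.0) > 0]
    comp_index = {c: i for i, c in enumerate(COMPONENTS)}

    def supported(sp: SpeciesDef) -> bool:
        for c, nu in zip(COMPONENTS, sp.stoich):
            if nu != 0 and c != "H" and c not in active:
                return False
        return True

    aqueous = [sp for sp in species if sp.kind != "mineral" and supported(sp)]
    return active, aqueous, comp_index


def _alk_weights(nu: np.ndarray, comp_index: dict[str, int],
                 include_phosphate: bool) -> np.ndarray:
    """Proton-condition alkalinity weight per species: w = 2*nu_CO3 - nu_H
    (CO2 and H2O reference levels), so ion-paired carbonate counts; phosphate
    species use w = 2*nu_PO4 - nu_H (H2PO4- reference) only on request."""
    h, co3, po4 = comp_index["H"], comp_index["CO3"], comp_index["PO4"]
    w = np.empty(nu.shape[0])
    for i, row in enumerate(nu):
        if row[po4] != 0:
            w[i] = (2.0 * row[po4] - row[h]) if include_phosphate else 0.0
        else:
            w[i] = 2.0 * row[co3] - row[h]
    return w


_BASIS_CHARGE = {"H": 1, "Na": 1, "K": 1, "Cl": -1, "Mg": 2, "Ca": 2,
                 "SO4": -2, "CO3": -2, "PO4": -3, "La": 3}


def solve_equilibrium(totals: ComponentTotals, species: list[SpeciesDef],
                      fixed_ph: float | None = None,
                      activity_model: str = "davies",
                      include_phosphate_alkalinity: bool = False,
                      max_iter: int = 100,
                      tol: float = 1e-13,
                      warm_start: dict | None = None) -> EquilibriumState:
    """Speciate one solution.

    Nested solve: Newton iteration on log free concentrations of the non-H
    components at fixed proton activity (the mass-balance map is monotone
    there, so this converges in a handful of steps), with Brent root-finding
    on pH to close the alkalinity proton condition -- or at the given pH when
    ``fixed_ph`` is set.  Activity coefficients (Davies, or unity under
    ``activity_model='ideal'``) are relaxed in an outer loop on ionic
    strength.  Raises :class:`ConvergenceError` with a residual report when
    the tableau cannot be closed.
    """
    from scipy.optimize import brentq

    if activity_model not in ("davies", "ideal"):
        raise ValueError("activity_model must be 'davies' or 'ideal'")
    if totals.alkalinity < 0 and totals.totals.get("CO3", 0.0) == 0:
        raise ValueError("negative alkalinity with zero DIC is infeasible")

    t_c = totals.temperature_c
    ln10 = math.log(10.0)
    active, aqueous, comp_index = _active_setup(totals, species)
    names = [sp.name for sp in aqueous]
    nu = np.array([sp.stoich for sp in aqueous])               # species x comps
    charges = np.array([sp.charge for sp in aqueous], dtype=float)
    logk_t = np.array([sp.logk_at(t_c) for sp in aqueous])
    h_col = comp_index["H"]
    nu_h = nu[:, h_col]
    act_idx = [comp_index[c] for c in active]
    nu_act = nu[:, act_idx]
    n_act = len(active)
    T = np.array([totals.totals[c] for c in active])
    alk_w = _alk_weights(nu, comp_index, include_phosphate_alkalinity)

    # starting point (warm start carries x, pH and ionic strength across
    # neighbouring solves, e.g. along a DIC sweep)
    if warm_start:
        x = np.array([warm_start["x"].get(c, math.log(max(t * 0.5, 1e-30)))
                      for c, t in zip(active, T)])
        ph_guess = warm_start.get("ph", 8.0)
        ionic_strength = warm_start.get("ionic_strength", 0.0)
    else:
        x = np.empty(n_act)
        for j, c in enumerate(active):
            frac = {"CO3": 1e-2, "PO4": 1e-3, "La": 0.05}.get(c, 0.7)
            x[j] = math.log(max(T[j] * frac, 1e-300))
        ph_guess = fixed_ph if fixed_ph is not None else 8.0
        ionic_strength = 0.0

    def gammas(i_str: float):
        if activity_model == "ideal" or i_str <= 0:
            return np.zeros(len(aqueous)), np.zeros(len(COMPONENTS))
        lg_sp = np.array([davies_log_gamma(sp.charge, i_str, t_c)
                          for sp in aqueous])
        lg_basis = np.array([davies_log_gamma(_BASIS_CHARGE[c], i_str, t_c)
                             for c in COMPONENTS])
        return lg_sp, lg_basis

    def inner_solve(logk_eff: np.ndarray, ph_val: float, x0: np.ndarray):
        """Mass balances at fixed proton activity a_H = 10^-pH."""
        const = ln10 * logk_eff + nu_h * (-ln10 * ph_val)
        if n_act == 0:
            return x0, np.exp(np.minimum(const, 700.0))
        xx = x0.copy()
        res = None
        for _ in range(max_iter):
            m = np.exp(np.minimum(const + nu_act @ xx, 700.0))
            s = nu_act.T @ m
            res = np.log(s / T)
            if float(np.max(np.abs(res))) < tol:
                return xx, m
            jac = (nu_act.T * m) @ nu_act / s[:, None]
            try:
                step = np.linalg.solve(jac, -res)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular Jacobian at pH {ph_val:.3f}"
                                       ) from exc
            n0 = float(np.linalg.norm(res))
            t = 1.0
            while True:
                xt = xx + t * step
                mt = np.exp(np.minimum(const + nu_act @ xt, 700.0))
                rt = np.log((nu_act.T @ mt) / T)
                if float(np.linalg.norm(rt)) < n0 or t <= 1e-8:
                    xx = xt
                    break
                t /= 2.0
        report = dict(zip(active, np.asarray(res)))
        raise ConvergenceError(f"component solve stalled at pH {ph_val:.3f}; "
                               f"log residuals {report}")

    ph = ph_guess
    m_sp = np.zeros(len(aqueous))
    lg_sp, lg_basis = gammas(ionic_strength)
    for _outer in range(60):
        lg_b = lg_basis.copy()
        lg_b[h_col] = 0.0  # proton handled as activity directly
        logk_eff = logk_t + nu @ lg_b - lg_sp
        if fixed_ph is not None:
            ph = float(fixed_ph)
            x, m_sp = inner_solve(logk_eff, ph, x)
        else:
            state_x = {"x": x}

            def alk_residual(ph_val: float) -> float:
                xs, ms = inner_solve(logk_eff, ph_val, state_x["x"])
                state_x["x"] = xs
                return float(alk_w @ ms) - totals.alkalinity

            lo, hi = max(0.0, ph_guess - 1.0), min(14.0, ph_guess + 1.0)
            f_lo, f_hi = alk_residual(lo), alk_residual(hi)
            if f_lo * f_hi > 0:  # widen to the full feasible window
                lo, hi = 0.0, 14.0
                f_lo, f_hi = alk_residual(lo), alk_residual(hi)
                if f_lo * f_hi > 0:
                    raise ConvergenceError(
                        "alkalinity condition has no root in pH [0, 14]"
                    )
            ph = float(brentq(alk_residual, lo, hi, xtol=1e-13))
            x, m_sp = inner_solve(logk_eff, ph, state_x["x"])
            ph_guess = ph
        if activity_model == "ideal":
            break
        i_new = 0.5 * float((charges ** 2) @ m_sp)
        if abs(i_new - ionic_strength) < 1e-12 * max(i_new, 1e-3):
            break
        ionic_strength = i_new
        lg_sp, lg_basis = gammas(ionic_strength)
    else:  # pragma: no cover
        raise ConvergenceError("ionic-strength relaxation did not settle")

    molal = {n: float(m) for n, m in zip(names, m_sp)}
    lg = {n: float(g) for n, g in zip(names, lg_sp)}
    act = {n: molal[n] * 10 ** lg[n] for n in names}

    def component_sum(c: str) -> float:
        return float(nu[:, comp_index[c]] @ m_sp)

    residual_report = {
        c: (component_sum(c) - totals.totals[c]) / totals.totals[c]
        for c in active
    }
    if fixed_ph is None:
        scale = max(abs(totals.alkalinity), float(np.abs(alk_w) @ m_sp), 1e-30)
        residual_report["alkalinity"] = (
            float(alk_w @ m_sp) - totals.alkalinity
        ) / scale
    worst = max((abs(v) for v in residual_report.values()), default=0.0)
    if worst > 1e-8:
        raise ConvergenceError(f"residuals too large: {residual_report}")

    dic = component_sum("CO3") if "CO3" in active else 0.0
    p_tot = component_sum("PO4") if "PO4" in active else 0.0
    la_tot = component_sum("La") if "La" in active else 0.0
    frac_co3 = molal.get("CO3-2", 0.0) / dic if dic > 0 else math.nan
    frac_po4 = molal.get("PO4-3", 0.0) / p_tot if p_tot > 0 else math.nan
    frac_la = molal.get("La+3", 0.0) / la_tot if la_tot > 0 else math.nan

    si = None
    mineral = next((sp for sp in species if sp.kind == "mineral"), None)
    if mineral is not None and "La+3" in act and "PO4-3" in act:
        iap = act["La+3"] * act["PO4-3"]
        if iap > 0:
            si = math.log10(iap) - mineral.logk_at(t_c)

    return EquilibriumState(
        molalities=molal,
        activities=act,
        log_gamma=lg,
        ph=ph,
        ionic_strength=ionic_strength,
        temperature_c=t_c,
        alkalinity=totals.alkalinity,
        residuals=residual_report,
        fraction_co3_of_dic=frac_co3,
        fraction_po4_of_p=frac_po4,
        fraction_la_free=frac_la,
        si_lapo4=si,
        charge_imbalance=float(charges @ m_sp),
        converged=True,
        _log_m_basis={
            "x": {c: float(v) for c, v in zip(active, x)},
            "ph": float(ph),
            "ionic_strength": float(ionic_strength),
        },
    )


def la_saturation_total(state: EquilibriumState, species: list[SpeciesDef] | None = None,
                        log_ksp: float | None = None) -> float:
    """Total dissolved La (mol/kg) in equilibrium with LaPO4(s) at this state.

    a(La3+)_sat = Ksp / a(PO4 3-); the total follows by dividing the free
    molality by the free-La fraction at the state's pH and ligand activities.
    """
    if log_ksp is None:
        if species is None:
            raise ValueError("provide species or log_ksp")
        mineral = next(sp for sp in species if sp.kind == "mineral")
        log_ksp = mineral.logk_at(state.temperature_c)
    a_po4 = state.activities.get("PO4-3", 0.0)
    if a_po4 <= 0:
        raise ValueError("PO4 3- activity must be positive")
    f_free = state.fraction_la_free
    if not (f_free > 0):
        raise ValueError("free-La fraction is zero: complex-only speciation")
    gamma_la = 10 ** state.log_gamma.get("La+3", 0.0)
    m_la_sat = (10 ** log_ksp / a_po4) / gamma_la
    return m_la_sat / f_free


@dataclass
class SaturationCurve:
    """La solubility and speciation fractions along a DIC sweep at fixed
    alkalinity."""

    table: pd.DataFrame   # columns: dic, ph, f_co3, f_po4, f_la_free,
    #                       la_total_sat, si_lapo4, converged
    alkalinity: float
    log_ksp: float

    @property
    def converged(self) -> pd.DataFrame:
        return self.table[self.table["converged"]]


def sweep_co2_constant_alkalinity(totals: ComponentTotals,
                                  species: list[SpeciesDef],
                                  dic_grid: np.ndarray) -> SaturationCurve:
    """Solve the system over a DIC grid at the recipe's fixed alkalinity.

    Raising CO2 (DIC) at constant alkalinity acidifies the solution, so pH
    decreases strictly along the grid.  Grid points that fail to converge are
    masked rather than aborting the sweep.
    """
    dic_grid = np.asarray(dic_grid, dtype=float)
    if dic_grid.size == 0 or (np.diff(dic_grid) <= 0).any() or (dic_grid <= 0).any():
        raise ValueError("dic_grid must be positive and strictly increasing")
    mineral = next(sp for sp in species if sp.kind == "mineral")
    log_ksp = mineral.logk_at(totals.temperature_c)
    rows = []
    warm: dict[str, float] | None = None
    for dic in dic_grid:
        point = totals.with_dic(float(dic))
        try:
            state = solve_equilibrium(point, species, warm_start=warm)
            warm = state._log_m_basis
            rows.append(
                {
                    "dic": dic,
                    "ph": state.ph,
                    "f_co3": state.fraction_co3_of_dic,
                    "f_po4": state.fraction_po4_of_p,
                    "f_la_free": state.fraction_la_free,
                    "la_total_sat": la_saturation_total(state, log_ksp=log_ksp),
                    "si_lapo4": state.si_lapo4,
                    "converged": True,
                }
            )
        except (ConvergenceError, ValueError):
            rows.append({"dic": dic, "ph": math.nan, "f_co3": math.nan,
                         "f_po4": math.nan, "f_la_free": math.nan,
                         "la_total_sat": math.nan, "si_lapo4": math.nan,
                         "converged": False})
    return SaturationCurve(table=pd.DataFrame(rows),
                           alkalinity=totals.alkalinity, log_ksp=log_ksp)


@dataclass(frozen=True)
class SaturationMinimum:
    ph: float
    bracketed: bool
    grid_ph: float          # pH of the discrete argmin
    la_total_sat: float


def find_saturation_minimum(curve: SaturationCurve) -> SaturationMinimum:
    """pH minimising total La at LaPO4 saturation, refined by quadratic
    interpolation through the three grid points bracketing the discrete
    minimum.  A boundary minimum is flagged unbracketed and returned raw."""
    ok = curve.converged.sort_values("ph").reset_index(drop=True)
    if len(ok) < 5:
        raise ValueError("need >= 5 converged points spanning the minimum")
    y = ok["la_total_sat"].to_numpy()
    x = ok["ph"].to_numpy()
    i = int(np.argmin(y))
    if i == 0 or i == len(ok) - 1:
        return SaturationMinimum(ph=float(x[i]), bracketed=False,
                                 grid_ph=float(x[i]), la_total_sat=float(y[i]))
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2 ** 2 * (y0 - y1) + x1 ** 2 * (y2 - y0) + x0 ** 2 * (y1 - y2)) / denom
    ph_min = float(x1 if a <= 0 else -b / (2 * a))
    return SaturationMinimum(ph=ph_min, bracketed=True, grid_ph=float(x1),
                             la_total_sat=float(y1))


def dic_grid_for_ph_span(totals: ComponentTotals, species: list[SpeciesDef],
                         ph_low: float = 7.4, ph_high: float = 8.6,
                         n: int = 200) -> np.ndarray:
    """DIC grid (increasing) whose solved pH spans [ph_low, ph_high]."""
    from scipy.optimize import brentq

    def ph_of(dic: float) -> float:
        return solve_equilibrium(totals.with_dic(dic), species).ph

    alk = totals.alkalinity
    lo_bracket, hi_bracket = 0.2 * alk, 2.5 * alk
    dic_at_high = brentq(lambda d: ph_of(d) - ph_high, lo_bracket, hi_bracket,
                         xtol=1e-9)
    dic_at_low = brentq(lambda d: ph_of(d) - ph_low, lo_bracket, hi_bracket,
                        xtol=1e-9)
    return np.linspace(dic_at_high, dic_at_low, n)
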