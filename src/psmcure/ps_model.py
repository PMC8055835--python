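"""Three-state partitioned survival model.

State membership is read directly off the OS and PFS curves each 21-day
cycle: progression-free PF = min(S_pfs, S_os), postprogression
PP = S_os − PF, dead = 1 − S_os.  Expected costs (drugs, administration,
supportive care, second-line, adverse-event management, death) and
QALYs/life-years are accumulated per cycle with annual discounting.

Dosing follows the trial regimens: carboplatin by the Calvert formula
(AUC·(CrCl+25)), etoposide 100 mg/m² per dosing day, atezolizumab 1,200 mg
flat per cycle while progression-free, topotecan 1.5 mg/m² on days 1–5 and
CAV (cyclophosphamide 1,000 mg/m², doxorubicin 45 mg/m², vincristine 2 mg)
as second-line options.  Prices are linear in dose (no vial wastage).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

INTERVENTION = "intervention"
CONTROL = "control"


@dataclass
class CycleGrid:
    """Model time axis: 21-day cycles over a 2.5-year horizon."""

    cycle_length_days: float = 21.0
    horizon_years: float = 2.5
    discount_rate_annual: float = 0.03
    half_cycle: bool = False  # evaluate membership at cycle midpoints

    def __post_init__(self):
        if not (0.0 <= self.discount_rate_annual <= 0.05):
            raise ValueError("discount rate outside the supported [0, 0.05] range")
        if self.cycle_length_days <= 0 or self.horizon_years <= 0:
            raise ValueError("grid durations must be positive")

    @property
    def n_cycles(self) -> int:
        return int(math.ceil(self.horizon_years * DAYS_PER_YEAR / self.cycle_length_days))

    @property
    def times_days(self) -> np.ndarray:
        """Cycle start times in days (k·21, k = 0…n_cycles−1)."""
        return np.arange(self.n_cycles) * self.cycle_length_days

    @property
    def eval_times_days(self) -> np.ndarray:
        t = self.times_days
        return t + 0.5 * self.cycle_length_days if self.half_cycle else t

    @property
    def times_months(self) -> np.ndarray:
        from .synthetic_trial import DAYS_PER_MONTH

        return self.eval_times_days / DAYS_PER_MONTH

    def discount_factors(self, rate: Optional[float] = None) -> np.ndarray:
        r = self.discount_rate_annual if rate is None else rate
        return (1.0 + r) ** (-(self.times_days / DAYS_PER_YEAR))

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR


@dataclass
class StateOccupancy:
    """Per-cycle proportions in progression-free / postprogression / dead."""

    pf: np.ndarray
    pp: np.ndarray
    dead: np.ndarray

    def __post_init__(self):
        total = self.pf + self.pp + self.dead
        if np.max(np.abs(total - 1.0)) > 1e-9:
            raise ValueError("state proportions must sum to 1 each cycle")
        if np.any(self.pp < -1e-12):
            raise ValueError("negative postprogression occupancy")

    def __len__(self):
        return len(self.pf)

    @property
    def alive(self) -> np.ndarray:
        return self.pf + self.pp

    def incident_progressions(self) -> np.ndarray:
        """Per-cycle drop in PF occupancy (first cycle: 1 − pf_0)."""
        inc = -np.diff(np.concatenate([[1.0], self.pf]))
        if np.any(inc < -1e-9):
            raise ValueError("negative incident progression flow; PF curve is non-monotone")
        return np.clip(inc, 0.0, None)

    def incident_deaths(self) -> np.ndarray:
        inc = np.diff(np.concatenate([[0.0], self.dead]))
        if np.any(inc < -1e-9):
            raise ValueError("negative incident death flow; OS curve is non-monotone")
        return np.clip(inc, 0.0, None)


def compute_membership(s_os: np.ndarray, s_pfs: np.ndarray, grid: CycleGrid) -> StateOccupancy:
    """State occupancy from survival curves evaluated on the cycle grid.

    PF is clamped to S_os where the fitted PFS curve crosses above the OS
    curve (a well-known artifact of independently fitted curves).
    """
    s_os = np.asarray(s_os, dtype=float)
    s_pfs = np.asarray(s_pfs, dtype=float)
    if s_os.shape != s_pfs.shape or len(s_os) != grid.n_cycles:
        raise ValueError("survival curves must both be tabulated on the cycle grid")
    for name, s in (("OS", s_os), ("PFS", s_pfs)):
        if np.any((s < 0) | (s > 1)):
            raise ValueError(f"{name} survival outside [0, 1]")
    n_clamped = int(np.sum(s_pfs > s_os + 1e-12))
    if n_clamped:
        logger.info("PFS > OS at %d cycles; PF clamped to OS", n_clamped)
    pf = np.minimum(s_pfs, s_os)
    pp = s_os - pf
    dead = 1.0 - s_os
    return StateOccupancy(pf=pf, pp=pp, dead=dead)


# ---------------------------------------------------------------------------
# economic inputs


class EconomicInputs:
    """The model's cost/utility/adverse-event ledger.

    Wraps the structured config (see ``data/econ_inputs.yaml``); every
    uncertain input is a mapping with keys value/dist/low/high and is
    addressable by a dotted flat name (e.g. ``utilities.pf``,
    ``adverse_events.anemia.cost``) for sensitivity analyses.
    """

    def __init__(self, raw: Dict, check_bounds: bool = True):
        self.raw = raw
        self._validate(check_bounds)

    # -- construction -------------------------------------------------
    @classmethod
    def default(cls) -> "EconomicInputs":
        with resources.files("psmcure.data").joinpath("econ_inputs.yaml").open() as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path) -> "EconomicInputs":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.raw, fh, sort_keys=False)

    def _validate(self, check_bounds: bool = True):
        for name, spec in self.uncertain_params().items():
            lo, v, hi = spec["low"], spec["value"], spec["high"]
            # bound bracketing is a property of the base ledger; overridden
            # copies (PSA draws may fall outside the 95% bounds) skip it
            if check_bounds and not (lo <= v <= hi):
                raise ValueError(f"{name}: bounds must bracket the deterministic value")
            if "utilities." in name and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}: utilities must lie in [0, 1]")
            if ".risk_" in name and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}: risks must lie in [0, 1]")
            if (".cost" in name or "costs" in name) and v < 0:
                raise ValueError(f"{name}: costs must be non-negative")

    # -- flat access --------------------------------------------------
    def _walk(self, node, prefix, out):
        if isinstance(node, dict):
            if {"value", "dist"} <= set(node):
                out[prefix] = node
            else:
                for k, v in node.items():
                    self._walk(v, f"{prefix}.{k}" if prefix else k, out)

    def uncertain_params(self) -> Dict[str, Dict]:
        out: Dict[str, Dict] = {}
        self._walk(self.raw, "", out)
        return out

    def value(self, flat_name: str) -> float:
        node = self.raw
        for part in flat_name.split("."):
            node = node[part]
        return float(node["value"]) if isinstance(node, dict) else float(node)

    def with_overrides(self, overrides: Dict[str, float]) -> "EconomicInputs":
        """Copy with the named inputs' deterministic values replaced."""
        raw = copy.deepcopy(self.raw)
        for name, val in overrides.items():
            node = raw
            parts = name.split(".")
            for part in parts[:-1]:
                if part not in node:
                    raise KeyError(f"unknown input {name!r}")
                node = node[part]
            leaf = parts[-1]
            if leaf not in node:
                raise KeyError(f"unknown input {name!r}")
            if isinstance(node[leaf], dict):
                node[leaf]["value"] = float(val)
            else:
                node[leaf] = float(val)
        return EconomicInputs(raw, check_bounds=False)

    # -- convenience values -------------------------------------------
    @property
    def discount_rate(self) -> float:
        return self.value("discount_rate")

    def utility(self, state: str) -> float:
        return self.value(f"utilities.{state}")

    def unit_cost_per_mg(self, drug: str) -> float:
        spec = self.raw["unit_costs"][drug]
        return float(spec["value"]) / float(spec["unit_size"])

    def ae_names(self):
        return list(self.raw["adverse_events"])

    def ae(self, name: str, fld: str) -> float:
        return float(self.raw["adverse_events"][name][fld]["value"])


# ---------------------------------------------------------------------------
# regimen costing


def regimen_cycle_cost(regimen: str, inputs: EconomicInputs) -> Dict[str, float]:
    """Drug acquisition cost per 21-day cycle, by component (US$).

    Regimens: 'carboplatin_etoposide', 'atezolizumab', 'topotecan', 'cav'.
    """
    pat = inputs.raw["patient"]
    rs = inputs.raw["regimen_settings"]
    bsa = float(pat["bsa_m2"])
    crcl = float(pat["crcl_ml_min"])
    c = inputs.unit_cost_per_mg

    if regimen == "carboplatin_etoposide":
        carbo_mg = rs["carboplatin_auc"] * (crcl + 25.0)  # Calvert formula
        etop_mg = rs["etoposide_mg_per_m2"] * bsa * rs["etoposide_days_per_cycle"]
        return {
            "carboplatin": carbo_mg * c("carboplatin"),
            "etoposide": etop_mg * c("etoposide"),
        }
    if regimen == "atezolizumab":
        return {"atezolizumab": rs["atezolizumab_mg_flat"] * c("atezolizumab")}
    if regimen == "topotecan":
        mg = rs["topotecan_mg_per_m2"] * bsa * rs["topotecan_days_per_cycle"]
        return {"topotecan": mg * c("topotecan")}
    if regimen == "cav":
        return {
            "cyclophosphamide": rs["cyclophosphamide_mg_per_m2"] * bsa * c("cyclophosphamide"),
            "doxorubicin": rs["doxorubicin_mg_per_m2"] * bsa * c("doxorubicin"),
            "vincristine": rs["vincristine_mg_flat"] * c("vincristine"),
        }
    raise ValueError(f"unknown regimen {regimen!r}")


def second_line_lump_cost(inputs: EconomicInputs, role: str) -> float:
    """Expected second-line cost per incident progression (4-cycle course
    of topotecan or CAV, weighted by uptake)."""
    sl = inputs.raw["second_line"]
    uptake = sl["uptake_intervention" if role == INTERVENTION else "uptake_control"]
    n_cyc = float(sl["n_cycles"])
    topo = sum(regimen_cycle_cost("topotecan", inputs).values())
    cav = sum(regimen_cycle_cost("cav", inputs).values())
    return n_cyc * (
        float(uptake["topotecan"]["value"]) * topo + float(uptake["cav"]["value"]) * cav
    )


# ---------------------------------------------------------------------------
# expected costs and outcomes


def expected_costs(
    occ: StateOccupancy,
    inputs: EconomicInputs,
    grid: CycleGrid,
    role: str,
) -> Dict[str, float]:
    """Discounted expected cost per patient, by category.

    Intervention: induction chemotherapy (4 cycles) + atezolizumab every
    cycle while progression-free; control: induction chemotherapy only.
    Administration is costed per treatment cycle (first infusion rate at
    cycle 1, additional rate thereafter).  Supportive care accrues for all
    alive patients; second-line and death costs attach to incident flows;
    adverse-event management is a one-time expected cost at cycle 1.
    """
    if role not in (INTERVENTION, CONTROL):
        raise ValueError("role must be 'intervention' or 'control'")
    d = grid.discount_factors(inputs.discount_rate)
    n = grid.n_cycles
    pf, alive = occ.pf, occ.alive
    chemo_cycles = int(inputs.raw["regimen_settings"]["chemo_cycles"])

    chemo_per_cycle = sum(regimen_cycle_cost("carboplatin_etoposide", inputs).values())
    chemo_mask = np.zeros(n)
    chemo_mask[:chemo_cycles] = 1.0
    cost_chemo = float(np.sum(d * chemo_mask * pf * chemo_per_cycle))

    cost_atezo = 0.0
    if role == INTERVENTION:
        atezo = sum(regimen_cycle_cost("atezolizumab", inputs).values())
        cost_atezo = float(np.sum(d * pf * atezo))

    admin_first = inputs.value("other_costs.admin_first")
    admin_add = inputs.value("other_costs.admin_additional")
    treat_mask = np.ones(n) if role == INTERVENTION else chemo_mask
    admin_rates = np.where(np.arange(n) == 0, admin_first, admin_add)
    cost_admin = float(np.sum(d * treat_mask * pf * admin_rates))

    supportive = inputs.value("other_costs.supportive_care_per_cycle")
    cost_supportive = float(np.sum(d * alive * supportive))

    lump = second_line_lump_cost(inputs, role)
    cost_second_line = float(np.sum(d * occ.incident_progressions() * lump))

    death_cost = inputs.value("other_costs.death")
    cost_death = float(np.sum(d * occ.incident_deaths() * death_cost))

    risk_fld = "risk_intervention" if role == INTERVENTION else "risk_control"
    cost_ae = float(
        d[0] * sum(inputs.ae(a, risk_fld) * inputs.ae(a, "cost") for a in inputs.ae_names())
    )

    out = {
        "chemotherapy": cost_chemo,
        "atezolizumab": cost_atezo,
        "administration": cost_admin,
        "supportive_care": cost_supportive,
        "second_line": cost_second_line,
        "death": cost_death,
        "adverse_events": cost_ae,
    }
    out["total"] = float(sum(out.values()))
    return out


def expected_qalys_lys(
    occ: StateOccupancy,
    inputs: EconomicInputs,
    grid: CycleGrid,
    role: str,
) -> Tuple[float, float]:
    """Discounted (QALYs, life-years) per patient.

    QALY = Σ_k d_k·(u_PF·pf_k + u_PP·pp_k)·(cycle/365.25) minus a one-time
    expected adverse-event decrement Σ risk·|disutility|·duration/365.25.
    """
    u_pf, u_pp = inputs.utility("pf"), inputs.utility("pp")
    for u in (u_pf, u_pp):
        if not (0.0 <= u <= 1.0):
            raise ValueError("utilities must lie in [0, 1]")
    d = grid.discount_factors(inputs.discount_rate)
    cyc_years = grid.cycle_years
    lyg = float(np.sum(d * occ.alive * cyc_years))
    qaly = float(np.sum(d * (u_pf * occ.pf + u_pp * occ.pp) * cyc_years))
    risk_fld = "risk_intervention" if role == INTERVENTION else "risk_control"
    ae_dec = sum(
        inputs.ae(a, risk_fld) * abs(inputs.ae(a, "disutility")) * inputs.ae(a, "duration_days")
        / DAYS_PER_YEAR
        for a in inputs.ae_names()
    )
    qaly -= float(d[0] * ae_dec)
    return qaly, lyg


@dataclass
class ArmResult:
    """Evaluated arm: occupancy, discounted costs by category, QALYs, LYs."""

    role: str
    occupancy: StateOccupancy
    costs: Dict[str, float]
    qalys: float
    lygs: float

    @property
    def total_cost(self) -> float:
        return self.costs["total"]


def run_arm(
    s_os: np.ndarray,
    s_pfs: np.ndarray,
    inputs: EconomicInputs,
    grid: CycleGrid,
    role: str,
) -> ArmResult:
    """Evaluate the partitioned survival model for one arm."""
    occ = compute_membership(s_os, s_pfs, grid)
    costs = expected_costs(occ, inputs, grid, role)
    qalys, lygs = expected_qalys_lys(occ, inputs, grid, role)
    return ArmResult(role=role, occupancy=occ, costs=costs, qalys=qalys, lygs=lygs)


def trace_frame(arm: ArmResult, grid: CycleGrid) -> pd.DataFrame:
    """Per-cycle trace (state occupancy and discount factor) for export."""
    occ = arm.occupancy
    return pd.DataFrame(
        {
            "cycle": np.arange(grid.n_cycles),
            "time_days": grid.times_days,
            "pf": occ.pf,
            "pp": occ.pp,
            "dead": occ.dead,
            "discount": grid.discount_factors(),
        }
    )
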