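"""Costs, utilities and discounting.

Scalar reference implementations of the per-cycle cost and utility rules; the
simulation engine applies vectorised equivalents, and the test suite checks
the two against each other on recorded ledgers.  All costs are 2022 euros;
costs discount at 4.0%/y and effects at 1.5%/y (Dutch guidelines), anchored at
simulation start with per-cycle factors (1+r)^(-month/12).

Utility in a cycle is the age-band baseline multiplied by every applicable
condition multiplier (COPD GOLD grade, lung-cancer stage, an exacerbation
this month, CVD event recency); the multiplicative combination rule for
comorbidity is a documented modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass

from .params import ParameterSet, CostTable, UtilityTable


def discount_factor(annual_rate: float, month: int) -> float:
    """(1 + r)^(-month/12); 1 at month 0."""
    if month < 0:
        raise ValueError("month must be >= 0")
    return (1.0 + annual_rate) ** (-month / 12.0)


@dataclass
class CycleEvents:
    """What happened to one individual in one cycle (cost triggers)."""

    invited: bool = False
    scanned: bool = False
    workup: bool = False            # positive screen (TP or FP) or symptomatic dx
    new_lc_diagnosis: bool = False
    operable: bool = False          # surgery at diagnosis
    n_moderate_exacerbations: int = 0
    n_severe_exacerbations: int = 0
    mi: bool = False
    angina_or_arrest: bool = False


@dataclass
class HealthState:
    """Slow-moving state of one individual at one cycle."""

    age: float = 60.0
    alive: bool = True
    lc_stage_group: int | None = None       # 0..3 = I..IV, None undiagnosed
    months_since_lc_dx: int | None = None
    copd_diagnosed: bool = False
    emphysema_severity: int = 0             # 0..4, maps to GOLD 1..4 when >=1
    on_statin: bool = False
    on_ace: bool = False
    months_since_stroke: int | None = None  # 0 in the stroke cycle
    months_since_chd_event: int | None = None


def cycle_cost(state: HealthState, events: CycleEvents, costs: CostTable,
               params: ParameterSet | None = None) -> float:
    """Undiscounted cost (€) of one cycle for one individual."""
    p = params or _DEFAULTS
    total = 0.0
    if events.invited:
        total += costs.invitation
    if events.scanned:
        total += costs.ldct_scan
    if events.workup:
        total += costs.diagnosis
    if events.new_lc_diagnosis and events.operable:
        total += costs.lc_surgery_onceoff
    if state.lc_stage_group is not None and state.months_since_lc_dx is not None:
        dur = (costs.lc_treatment_months_iv if state.lc_stage_group == 3
               else costs.lc_treatment_months_i_iii)
        if state.months_since_lc_dx < dur:
            monthly = (costs.lc_monthly_stage_iv if state.lc_stage_group == 3
                       else costs.lc_monthly_stage_iii if state.lc_stage_group == 2
                       else costs.lc_monthly_stage_i_ii)
            total += monthly
    if state.copd_diagnosed and state.emphysema_severity >= 1:
        total += costs.copd_annual[state.emphysema_severity - 1] / 12.0
    n_ex = events.n_moderate_exacerbations + events.n_severe_exacerbations
    total += n_ex * costs.exacerbation
    if state.on_statin:
        total += costs.statin_annual / 12.0
    if state.on_ace:
        total += costs.ace_annual / 12.0
    if events.mi:
        total += costs.mi
    if events.angina_or_arrest:
        total += costs.cardiac_arrest_or_angina
    if state.months_since_stroke is not None:
        if state.months_since_stroke <= 5:
            total += costs.stroke_monthly_1_6
        elif state.months_since_stroke <= 12:
            total += costs.stroke_monthly_7_13
    return total


def cycle_utility(state: HealthState, events: CycleEvents,
                  utilities: UtilityTable) -> float:
    """Utility weight for one cycle: age baseline x condition multipliers; 0 if dead."""
    if not state.alive:
        return 0.0
    if state.age <= 60:
        w = utilities.baseline_le60
    elif state.age <= 70:
        w = utilities.baseline_60_70
    else:
        w = utilities.baseline_gt70
    # GOLD-grade disutility attaches to the underlying airflow limitation,
    # whether or not COPD has been formally diagnosed (costs do require dx)
    if state.emphysema_severity >= 1:
        w *= utilities.copd_gold[state.emphysema_severity - 1]
    if state.lc_stage_group is not None:
        w *= utilities.lc_stage[state.lc_stage_group]
    if events.n_severe_exacerbations > 0:
        w *= utilities.exacerbation_severe
    elif events.n_moderate_exacerbations > 0:
        w *= utilities.exacerbation_moderate
    if state.months_since_stroke is not None:
        w *= (utilities.stroke_first_month if state.months_since_stroke == 0
              else utilities.stroke_after)
    if state.months_since_chd_event is not None:
        w *= (utilities.chd_first_month if state.months_since_chd_event == 0
              else utilities.chd_after)
    return w


_DEFAULTS = ParameterSet()
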