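"""Assembly of per-vessel flows into the fetal-circulation model.

Flow-combination rules:

* PBF  = LPA + RPA              (pulmonary blood flow)
* RVCO = DA + PBF               (right ventricular output)
* LVCO = AAo                    (left ventricular output, coronaries excluded)
* CVO  = RVCO + LVCO            (combined ventricular output)

Two further quantities are not directly measurable and are derived under the
standard fetal-circulation topology; both carry a "derived" flag in outputs:

* foramen ovale flow  FO = LVCO - PBF   (left-heart inflow minus pulmonary
  venous return)
* lower-trunk flow    = DAo - UV        (descending aortic flow minus the
  placental return)

Distribution metrics express each flow as % of CVO.
"""

from __future__ import annotations

from typing import Dict

from .types import CirculationState, DerivedHaemodynamics, ValidationError

__all__ = ["derive_flows", "check_conservation", "delta_so2",
           "CVO_PARTITION"]

_REQUIRED = ("LPA", "RPA", "DA", "AAo", "DAo", "UV", "SVC",
             "CCA_left", "CCA_right")

#: Flows that partition CVO exactly under the derivation rules:
#: CVO = RVCO + LVCO = (DA + PBF) + (FO + PBF) = DA + PBF + FO + PBF.
CVO_PARTITION = ("DA", "PBF", "FO", "PBF_again")


def derive_flows(state: CirculationState) -> DerivedHaemodynamics:
    """Compute derived flows and the %CVO distribution for one state."""
    flows = state.flows
    missing = [v for v in _REQUIRED if v not in flows]
    if missing:
        raise ValidationError(f"missing vessel flows: {missing}")

    pbf = flows["LPA"] + flows["RPA"]
    rvco = flows["DA"] + pbf
    lvco = flows["AAo"]
    cvo = rvco + lvco
    cca = flows["CCA_left"] + flows["CCA_right"]
    fo = lvco - pbf
    lower_trunk = flows["DAo"] - flows["UV"]

    flags = ["fo_flow derived as LVCO - PBF (not directly measured)",
             "lower_trunk_flow derived as DAo - UV (not directly measured)"]
    if fo < 0:
        flags.append("fo_flow negative: pulmonary return exceeds LVCO")
    if lower_trunk < 0:
        flags.append("lower_trunk_flow negative: UV exceeds DAo")

    if cvo == 0:
        raise ValidationError("CVO is zero: distribution undefined")
    dist: Dict[str, float] = {
        name: q / cvo * 100.0
        for name, q in (("FO", fo), ("CCA", cca), ("DA", flows["DA"]),
                        ("PBF", pbf), ("DAo", flows["DAo"]), ("SVC", flows["SVC"]),
                        ("UV", flows["UV"]), ("lower_trunk", lower_trunk))
    }

    delta = None
    sats = state.saturations
    if "AAo" in sats and "MPA" in sats:
        delta = delta_so2(sats["AAo"], sats["MPA"])

    return DerivedHaemodynamics(
        pbf=pbf, rvco=rvco, lvco=lvco, cvo=cvo, fo_flow=fo,
        lower_trunk_flow=lower_trunk, cca_combined=cca,
        distribution_pct=dist, delta_so2_aao_mpa=delta, flags=flags)


def check_conservation(state: CirculationState,
                       derived: DerivedHaemodynamics,
                       tol_pct: float = 1.0) -> dict:
    """Consistency report for the measured circulation.

    Checks the anatomical identity MPA = DA + PBF (the main pulmonary artery
    feeds only the ductus arteriosus and the branch pulmonary arteries) and
    that the derived flows partition CVO: DA + PBF + FO + PBF = CVO.
    """
    for v in ("MPA", "DA", "LPA", "RPA"):
        if v not in state.flows:
            raise ValidationError(f"missing vessel flows: ['{v}']")
    mpa = state.flows["MPA"]
    expected = state.flows["DA"] + derived.pbf
    if mpa == 0:
        discrepancy = abs(mpa - expected)
        relative = False
    else:
        discrepancy = abs(mpa - expected) / mpa * 100.0
        relative = True

    partition_sum = (derived.distribution_pct["DA"]
                     + 2.0 * derived.distribution_pct["PBF"]
                     + derived.distribution_pct["FO"])
    return {
        "subject_id": state.subject_id,
        "state": state.state,
        "mpa_discrepancy": discrepancy,
        "mpa_discrepancy_is_relative_pct": relative,
        "mpa_pass": discrepancy <= tol_pct,
        "cvo_partition_pct_sum": partition_sum,
        "cvo_partition_pass": abs(partition_sum - 100.0) <= tol_pct,
    }


def delta_so2(y_aao: float, y_mpa: float) -> float:
    """AAo - MPA saturation difference in percentage points."""
    for y in (y_aao, y_mpa):
        if not 0.0 <= y <= 1.0:
            raise ValidationError("saturations must be in [0, 1]")
    return (y_aao - y_mpa) * 100.0
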