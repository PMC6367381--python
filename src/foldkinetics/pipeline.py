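"""Record-level temperature-correction policy.

Given a kinetics record measured at T_x, this module decides *which*
(T_H, beta) pair transports each of its rate constants to the standard
25 C, and stamps the result with a provenance label:

``measured_at_25C``
    T_x already equals the target; values pass through unchanged.
``panel_default``
    The panel-average (T_H, beta) for the record's folding class and the
    reaction direction (the database's roman-type values).
``protein_specific``
    The record carries its own (dH_act, dCp_act) pair, from which T_H
    follows directly (boldface values).
``tanford_beta``
    beta is taken from the record's Tanford beta — beta = -beta_T for
    folding of two-state proteins, beta = 1 - beta_T for unfolding —
    with the panel T_H (italic values).

Intermediate-formation rates (ln k_I of non-two-state proteins) are
carried through uncorrected: no correction is defined for them.
Thermophilic records are corrected but flagged with a warning, since the
calibration panels contain only mesophilic proteins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .calibration import CorrectionParams, Direction, FoldClass, PairedRateObservation
from .curation import ActivationData, KineticsRecord
from .thermo import (
    T_STANDARD,
    Temperature,
    correct_rate,
    delta_cp_from_length,
    t_h_from_enthalpy,
)

__all__ = [
    "CorrectionProvenance",
    "CorrectionPolicy",
    "default_policy",
    "load_policy",
    "correct_record",
    "correct_record_tanford",
    "validate_predictions",
    "ValidationResult",
]


class CorrectionProvenance(str, Enum):
    MEASURED_AT_25C = "measured_at_25C"
    PANEL_DEFAULT = "panel_default"
    PROTEIN_SPECIFIC = "protein_specific"
    TANFORD_BETA = "tanford_beta"


@dataclass(frozen=True)
class CorrectionPolicy:
    """The four panel-level (T_H, beta) pairs plus the dCp(L) model."""

    folding_2s: CorrectionParams
    folding_n2s: CorrectionParams
    unfolding_2s: CorrectionParams
    unfolding_n2s: CorrectionParams
    delta_cp_model: str = "with_intercept"

    def __post_init__(self) -> None:
        expect = {
            "folding_2s": (Direction.FOLDING, False),
            "folding_n2s": (Direction.FOLDING, True),
            "unfolding_2s": (Direction.UNFOLDING, False),
            "unfolding_n2s": (Direction.UNFOLDING, True),
        }
        for name, (direction, is_n2s) in expect.items():
            params: CorrectionParams = getattr(self, name)
            if params.direction is not direction:
                raise ValueError(f"{name} carries direction {params.direction}")
            if (params.fold_class is FoldClass.NON_TWO_STATE) != is_n2s:
                raise ValueError(f"{name} carries fold class {params.fold_class}")

    def params_for(self, direction: Direction, fold_class: FoldClass) -> CorrectionParams:
        two_state = fold_class.effective_two_state
        if direction is Direction.FOLDING:
            return self.folding_2s if two_state else self.folding_n2s
        return self.unfolding_2s if two_state else self.unfolding_n2s


#: Headline panel values: folding (315 K, -0.62) for 2S and (305 K, -0.75)
#: for N2S from Eyring-plot panels; unfolding (224 K, 0.38) and
#: (119 K, 0.21) from the RMSD placement of T_Hu with beta_u = 1 + beta_f
#: (2S) and 1 - mean(beta_T) (N2S).
_HEADLINE = {
    "folding_2s": (315.0, -0.62, 1.0, 0.03, 12),
    "folding_n2s": (305.0, -0.75, 4.0, 0.07, 3),
    "unfolding_2s": (224.0, 0.38, None, 0.03, 6),
    "unfolding_n2s": (119.0, 0.21, None, 0.02, 3),
}


def default_policy(precision: str = "headline") -> CorrectionPolicy:
    """The shipped correction policy.

    ``precision="headline"`` uses the rounded values quoted above.
    ``precision="panel"`` replaces the folding pairs with the unrounded
    panel means recomputed from the packaged calibration panels
    (e.g. T_Hf = 314.70 K for two-state proteins).
    """
    if precision not in ("headline", "panel"):
        raise ValueError("precision must be 'headline' or 'panel'")

    def build(name: str, direction: Direction, fold_class: FoldClass) -> CorrectionParams:
        t_h, beta, t_h_se, beta_se, n = _HEADLINE[name]
        return CorrectionParams(
            direction=direction,
            fold_class=fold_class,
            t_h=Temperature(t_h),
            beta=beta,
            t_h_se=t_h_se,
            beta_se=beta_se,
            n_proteins=n,
        )

    policy = CorrectionPolicy(
        folding_2s=build("folding_2s", Direction.FOLDING, FoldClass.TWO_STATE),
        folding_n2s=build("folding_n2s", Direction.FOLDING, FoldClass.NON_TWO_STATE),
        unfolding_2s=build("unfolding_2s", Direction.UNFOLDING, FoldClass.TWO_STATE),
        unfolding_n2s=build("unfolding_n2s", Direction.UNFOLDING, FoldClass.NON_TWO_STATE),
    )
    if precision == "panel":
        from . import fixtures  # deferred: fixtures imports this module's siblings

        policy = replace(
            policy,
            folding_2s=fixtures.recalibrated_folding_params(FoldClass.TWO_STATE),
            folding_n2s=fixtures.recalibrated_folding_params(FoldClass.NON_TWO_STATE),
        )
    return policy


def load_policy(path: Union[str, Path]) -> CorrectionPolicy:
    """Read a policy from a small key=value text file.

    Recognized keys: ``<slot>.t_h`` and ``<slot>.beta`` for slot in
    {folding_2s, folding_n2s, unfolding_2s, unfolding_n2s}, plus
    ``delta_cp_model``.  Unspecified slots keep their defaults; ``#``
    starts a comment.
    """
    base = default_policy()
    overrides: Dict[str, Dict[str, float]] = {}
    model = base.delta_cp_model
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key == "delta_cp_model":
            model = value
            continue
        slot, _, param = key.partition(".")
        if slot not in ("folding_2s", "folding_n2s", "unfolding_2s", "unfolding_n2s") or param not in ("t_h", "beta"):
            raise ValueError(f"{path}:{lineno}: unknown policy key {key!r}")
        overrides.setdefault(slot, {})[param] = float(value)

    def rebuild(slot: str) -> CorrectionParams:
        params: CorrectionParams = getattr(base, slot)
        over = overrides.get(slot, {})
        if not over:
            return params
        return CorrectionParams(
            direction=params.direction,
            fold_class=params.fold_class,
            t_h=Temperature(over.get("t_h", params.t_h.kelvin)),
            beta=over.get("beta", params.beta),
            t_h_se=None,
            beta_se=None,
            n_proteins=1,
        )

    return CorrectionPolicy(
        folding_2s=rebuild("folding_2s"),
        folding_n2s=rebuild("folding_n2s"),
        unfolding_2s=rebuild("unfolding_2s"),
        unfolding_n2s=rebuild("unfolding_n2s"),
        delta_cp_model=model,
    )


def _target_for(record: KineticsRecord, t_target: Optional[float]) -> float:
    if t_target is not None:
        return float(t_target)
    if record.t_target_override_k is not None:
        return record.t_target_override_k
    return T_STANDARD.kelvin


def _correct_one(
    record: KineticsRecord,
    ln_k: float,
    direction: Direction,
    policy: CorrectionPolicy,
    t_target: float,
) -> Tuple[float, CorrectionProvenance]:
    t_x = record.temperature.kelvin
    if t_x == t_target:
        return ln_k, CorrectionProvenance.MEASURED_AT_25C
    specific = (
        record.folding_activation
        if direction is Direction.FOLDING
        else record.unfolding_activation
    )
    if specific is not None:
        t_h = t_h_from_enthalpy(specific.t_ref_k, specific.delta_h_act, specific.delta_cp_act)
        value = correct_rate(ln_k, t_x, specific.delta_cp_act, t_h, t_target)
        return value, CorrectionProvenance.PROTEIN_SPECIFIC
    if record.l_pdb is None:
        raise ValueError(
            f"{record.key}: chain length (l_pdb) required for a panel-based correction"
        )
    params = policy.params_for(direction, record.folding_type)
    dcp_act = params.beta * delta_cp_from_length(record.l_pdb, policy.delta_cp_model)
    value = correct_rate(ln_k, t_x, dcp_act, params.t_h, t_target)
    return value, CorrectionProvenance.PANEL_DEFAULT


def correct_record(
    record: KineticsRecord,
    policy: Optional[CorrectionPolicy] = None,
    t_target: Optional[float] = None,
) -> KineticsRecord:
    """Standardize a record's rate constants to 25 C.

    Every present rate (ln k_f and/or ln k_u) is corrected and stamped
    with exactly one provenance.  Records already at the target
    temperature pass through numerically unchanged.  A record-level
    target-temperature override (``t_target_override_k``) is honoured
    unless ``t_target`` is given explicitly.

    Requires a measurement temperature and, unless protein-specific
    activation data are present, a chain length and folding type.
    """
    policy = policy or default_policy()
    if record.temperature is None:
        raise ValueError(f"{record.key}: measurement temperature is required")
    if record.ln_kf_reported is None and record.ln_ku_reported is None:
        raise ValueError(f"{record.key}: no rate constant to correct")
    if record.folding_type is None and (
        record.folding_activation is None or record.unfolding_activation is None
    ):
        raise ValueError(f"{record.key}: folding type is required for panel-based correction")
    if "thermophilic" in record.flags:
        warnings.warn(
            f"{record.key}: thermophilic origin; panel parameters were calibrated on "
            "mesophilic proteins",
            stacklevel=2,
        )
    target = _target_for(record, t_target)
    updates: Dict[str, object] = {}
    if record.ln_kf_reported is not None:
        value, prov = _correct_one(record, record.ln_kf_reported, Direction.FOLDING, policy, target)
        updates["ln_kf_corrected"] = value
        updates["ln_kf_provenance"] = prov.value
    if record.ln_ku_reported is not None:
        value, prov = _correct_one(record, record.ln_ku_reported, Direction.UNFOLDING, policy, target)
        updates["ln_ku_corrected"] = value
        updates["ln_ku_provenance"] = prov.value
    # ln_ki is deliberately not touched: no correction is defined for
    # intermediate-formation rates.
    return replace(record, **updates)


def correct_record_tanford(
    record: KineticsRecord,
    policy: Optional[CorrectionPolicy] = None,
    t_target: Optional[float] = None,
) -> KineticsRecord:
    """Standardize rates using the record's own Tanford beta.

    The denaturant m-value coordinate and the heat-capacity coordinate
    locate the transition state consistently, so beta_T substitutes for
    the panel beta: folding (two-state records only) uses beta = -beta_T;
    unfolding uses beta = 1 - beta_T.  The panel T_H for the record's
    class is retained.  Results are stamped ``tanford_beta``.
    """
    policy = policy or default_policy()
    if record.beta_t is None:
        raise ValueError(f"{record.key}: Tanford beta is required")
    if record.temperature is None:
        raise ValueError(f"{record.key}: measurement temperature is required")
    if record.l_pdb is None:
        raise ValueError(f"{record.key}: chain length (l_pdb) is required")
    if record.folding_type is None:
        raise ValueError(f"{record.key}: folding type is required")
    target = _target_for(record, t_target)
    t_x = record.temperature.kelvin
    dcp_eq = delta_cp_from_length(record.l_pdb, policy.delta_cp_model)
    updates: Dict[str, object] = {}
    if record.ln_kf_reported is not None:
        if not record.folding_type.effective_two_state:
            raise ValueError(
                f"{record.key}: the Tanford-beta folding correction applies only to "
                "two-state records"
            )
        if t_x == target:
            updates["ln_kf_corrected"] = record.ln_kf_reported
            updates["ln_kf_provenance"] = CorrectionProvenance.MEASURED_AT_25C.value
        else:
            params = policy.params_for(Direction.FOLDING, record.folding_type)
            updates["ln_kf_corrected"] = correct_rate(
                record.ln_kf_reported, t_x, -record.beta_t * dcp_eq, params.t_h, target
            )
            updates["ln_kf_provenance"] = CorrectionProvenance.TANFORD_BETA.value
    if record.ln_ku_reported is not None:
        if t_x == target:
            updates["ln_ku_corrected"] = record.ln_ku_reported
            updates["ln_ku_provenance"] = CorrectionProvenance.MEASURED_AT_25C.value
        else:
            params = policy.params_for(Direction.UNFOLDING, record.folding_type)
            updates["ln_ku_corrected"] = correct_rate(
                record.ln_ku_reported, t_x, (1.0 - record.beta_t) * dcp_eq, params.t_h, target
            )
            updates["ln_ku_provenance"] = CorrectionProvenance.TANFORD_BETA.value
    if not updates:
        raise ValueError(f"{record.key}: no rate constant to correct")
    return replace(record, **updates)


@dataclass(frozen=True)
class ValidationResult:
    """Observed-vs-predicted comparison over a validation panel."""

    table: pd.DataFrame  # protein_id, observed, predicted, residual
    rmsd: float
    max_abs_residual: float


def validate_predictions(
    pairs: Sequence[PairedRateObservation],
    t_h: Union[Temperature, float],
    beta: float,
) -> ValidationResult:
    """Predict each pair's standard-temperature rate and compare.

    For each paired observation the rate at T_x is corrected with
    dCp_act = beta * dCp_eq and the supplied T_H, and the residual
    predicted - observed is tabulated together with the panel RMSD and
    the largest absolute residual.
    """
    if not pairs:
        raise ValueError("at least one paired observation is required")
    rows = []
    for obs in pairs:
        predicted = correct_rate(
            obs.ln_k_x, obs.t_x_k, beta * obs.delta_cp_eq, t_h, obs.t_target_k
        )
        rows.append(
            {
                "protein_id": obs.protein_id,
                "observed": obs.ln_k_0_observed,
                "predicted": predicted,
                "residual": predicted - obs.ln_k_0_observed,
            }
        )
    table = pd.DataFrame(rows)
    rmsd = float(math.sqrt((table["residual"] ** 2).mean()))
    return ValidationResult(
        table=table,
        rmsd=rmsd,
        max_abs_residual=float(table["residual"].abs().max()),
    )
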