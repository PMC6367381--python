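"""Kinetics-database record schema and dataset construction rules.

A curated folding-kinetics database is built from heterogeneous literature
sources by (1) excluding records that cannot be compared on a common
footing — chains under 34 residues, proteins with disulfide bonds or
covalently bound prosthetic groups, entries whose reported rate is not the
actual folding rate, rates reported in the presence of denaturant, entries
without usable PDB coordinates or without an experimental reference —
(2) resolving duplicate entries of the same protein, and (3) merging
source datasets keyed on PDB identity.

Flags such as ``has_disulfide`` are input annotations supplied by the
curator; nothing here parses structures.  Exclusion reasons are
single-valued with a fixed precedence (length first), and every filter
classifies rather than fails, so curation reports account for every input
record.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple, Union

import pandas as pd

from .calibration import Direction, FoldClass
from .thermo import MIN_CHAIN_LENGTH, Temperature

__all__ = [
    "StructuralClass",
    "ExclusionReason",
    "ActivationData",
    "KineticsRecord",
    "CurationReport",
    "RECORD_FLAGS",
    "filter_dataset",
    "resolve_duplicates",
    "merge_datasets",
    "composition_table",
    "classify_folding_type",
    "read_records_csv",
    "write_records_csv",
]


class StructuralClass(str, Enum):
    ALPHA = "alpha"
    BETA = "beta"
    ALPHA_BETA = "alpha/beta"
    ALPHA_PLUS_BETA = "alpha+beta"


class ExclusionReason(str, Enum):
    TOO_SHORT = "too_short"
    DISULFIDE = "disulfide"
    PROSTHETIC_GROUP = "prosthetic_group"
    IRRELEVANT_RATE = "irrelevant_rate"
    DENATURANT_PRESENT = "denaturant_present"
    MISSING_COORDINATES = "missing_coordinates"
    MISSING_REFERENCE = "missing_reference"
    DUPLICATE = "duplicate"


#: Allowed members of ``KineticsRecord.flags``.
RECORD_FLAGS: FrozenSet[str] = frozenset(
    {
        "has_disulfide",
        "has_prosthetic_group",
        "rate_is_intermediate_only",
        "measured_in_denaturant",
        "no_pdb_coordinates",
        "no_reference",
        "off_pathway_intermediate",
        "denaturant_activity_extrapolation",
        "thermophilic",
    }
)

# exclusion precedence: first triggered reason wins
_FILTER_ORDER: Tuple[Tuple[ExclusionReason, str], ...] = (
    (ExclusionReason.DISULFIDE, "has_disulfide"),
    (ExclusionReason.PROSTHETIC_GROUP, "has_prosthetic_group"),
    (ExclusionReason.IRRELEVANT_RATE, "rate_is_intermediate_only"),
    (ExclusionReason.DENATURANT_PRESENT, "measured_in_denaturant"),
    (ExclusionReason.MISSING_COORDINATES, "no_pdb_coordinates"),
    (ExclusionReason.MISSING_REFERENCE, "no_reference"),
)


@dataclass(frozen=True)
class ActivationData:
    """Protein-specific activation parameters (dH_act at t_ref, dCp_act).

    When present on a record they take precedence over panel-average
    correction parameters.
    """

    delta_h_act: float  # kJ/mol at t_ref_k
    delta_cp_act: float  # kJ/mol/K
    t_ref_k: float


@dataclass(frozen=True)
class KineticsRecord:
    """One protein's row in the kinetics database.

    Rates are natural logs of rate constants (s^-1) extrapolated to zero
    denaturant.  ``ln_ki`` — the formation rate of a stable intermediate —
    exists only for non-two-state folders and is never temperature-
    corrected.  ``beta_t`` is the Tanford beta in [0, 1].
    """

    pdb_code: str
    protein_name: str = ""
    structural_class: Optional[StructuralClass] = None
    scop_fold: str = ""
    l_pdb: Optional[int] = None
    l_experimental: Optional[int] = None
    ph: Optional[float] = None
    temperature: Optional[Temperature] = None
    folding_type: Optional[FoldClass] = None
    ln_kf_reported: Optional[float] = None
    ln_kf_corrected: Optional[float] = None
    ln_kf_provenance: Optional[str] = None
    ln_ki: Optional[float] = None
    ln_ku_reported: Optional[float] = None
    ln_ku_corrected: Optional[float] = None
    ln_ku_provenance: Optional[str] = None
    beta_t: Optional[float] = None
    folding_activation: Optional[ActivationData] = None
    unfolding_activation: Optional[ActivationData] = None
    t_target_override_k: Optional[float] = None
    flags: FrozenSet[str] = frozenset()
    comment: str = ""

    def __post_init__(self) -> None:
        code = self.pdb_code.strip()
        if not code:
            raise ValueError("pdb_code is required")
        # uppercase the 4-char PDB id, preserve any range/chain suffix text
        head, _, tail = code.partition(" ")
        object.__setattr__(self, "pdb_code", (head.upper() + (" " + tail if tail else "")))
        bad = set(self.flags) - RECORD_FLAGS
        if bad:
            raise ValueError(f"unknown record flags: {sorted(bad)}")
        object.__setattr__(self, "flags", frozenset(self.flags))
        if self.structural_class is not None:
            object.__setattr__(self, "structural_class", StructuralClass(self.structural_class))
        if self.folding_type is not None:
            object.__setattr__(self, "folding_type", FoldClass(self.folding_type))
        if self.ln_ki is not None and self.folding_type is not FoldClass.NON_TWO_STATE:
            raise ValueError("ln_ki is defined only for non-two-state records")
        if self.beta_t is not None and not 0.0 <= self.beta_t <= 1.0:
            raise ValueError(f"beta_t must lie in [0, 1], got {self.beta_t}")

    @property
    def key(self) -> str:
        """Identity key: PDB code plus optional residue-range suffix."""
        return self.pdb_code


@dataclass
class CurationReport:
    """Accounting of one curation pass.

    Invariant: ``input_count == len(kept) + len(excluded) + len(merged_duplicates)``.
    """

    input_count: int
    kept: List[KineticsRecord] = field(default_factory=list)
    excluded: List[Tuple[KineticsRecord, ExclusionReason]] = field(default_factory=list)
    merged_duplicates: List[Tuple[str, str]] = field(default_factory=list)  # (kept, dropped)

    def check(self) -> None:
        total = len(self.kept) + len(self.excluded) + len(self.merged_duplicates)
        if total != self.input_count:
            raise AssertionError(
                f"curation accounting broken: {self.input_count} in, "
                f"{len(self.kept)} kept + {len(self.excluded)} excluded + "
                f"{len(self.merged_duplicates)} dropped duplicates"
            )


def _first_exclusion(record: KineticsRecord) -> Optional[ExclusionReason]:
    if record.l_pdb is not None and record.l_pdb < MIN_CHAIN_LENGTH:
        return ExclusionReason.TOO_SHORT
    for reason, flag in _FILTER_ORDER:
        if flag in record.flags:
            return reason
    return None


def filter_dataset(records: Sequence[KineticsRecord]) -> CurationReport:
    """Classify records as kept or excluded, preserving input order.

    Each excluded record carries exactly the first triggered reason in the
    fixed precedence (length, disulfide, prosthetic group, irrelevant
    rate, denaturant, missing coordinates, missing reference).  Applying
    the filter to its own ``kept`` output keeps everything (idempotence).
    """
    report = CurationReport(input_count=len(records))
    for rec in records:
        reason = _first_exclusion(rec)
        if reason is None:
            report.kept.append(rec)
        else:
            report.excluded.append((rec, reason))
    report.check()
    return report


def resolve_duplicates(
    records: Sequence[KineticsRecord],
    pairs: Sequence[Tuple[str, str]],
) -> Tuple[List[KineticsRecord], List[Tuple[str, str]]]:
    """Collapse known duplicate entries, keeping one record per pair.

    The record listed first in a pair survives unless its flags force
    exclusion, in which case the second survives.  Returns the surviving
    records (input order) and the (kept_id, dropped_id) merge list.
    """
    by_key: Dict[str, KineticsRecord] = {}
    for rec in records:
        by_key[rec.key] = rec
    for a, b in pairs:
        missing = [x for x in (a, b) if x not in by_key]
        if missing:
            raise ValueError(f"duplicate pair {(a, b)} references absent record(s) {missing}")
    drop: Set[str] = set()
    merged: List[Tuple[str, str]] = []
    for a, b in pairs:
        if a in drop or b in drop:
            continue
        first, second = by_key[a], by_key[b]
        keep, lose = (a, b) if _first_exclusion(first) is None else (b, a)
        drop.add(lose)
        merged.append((keep, lose))
    survivors = [rec for rec in records if rec.key not in drop]
    return survivors, merged


def merge_datasets(
    a: Sequence[KineticsRecord],
    b: Sequence[KineticsRecord],
) -> Tuple[List[KineticsRecord], List[str]]:
    """Union of two datasets keyed on PDB identity.

    On a key collision the record from ``a`` wins and the shadowed key
    from ``b`` is reported.  ``len(result) == len(a) + #unique-in-b``.
    """
    keys_a = {rec.key for rec in a}
    result = list(a)
    shadowed: List[str] = []
    for rec in b:
        if rec.key in keys_a:
            shadowed.append(rec.key)
        else:
            result.append(rec)
            keys_a.add(rec.key)
    return result, shadowed


def composition_table(records: Sequence[KineticsRecord]) -> pd.DataFrame:
    """Folding-type x structural-class count matrix with margins.

    Rows 2S (2S* folded in) and N2S; columns the four structural classes;
    a ``Total`` row and column.  Records missing either annotation raise,
    listing the offending ids.
    """
    missing = [r.key for r in records if r.structural_class is None or r.folding_type is None]
    if missing:
        raise ValueError(f"records missing structural class or folding type: {missing}")
    classes = [
        StructuralClass.ALPHA,
        StructuralClass.BETA,
        StructuralClass.ALPHA_PLUS_BETA,
        StructuralClass.ALPHA_BETA,
    ]
    table = pd.DataFrame(
        0,
        index=["2S", "N2S"],
        columns=[c.value for c in classes],
        dtype=int,
    )
    for rec in records:
        row = "2S" if rec.folding_type.effective_two_state else "N2S"
        table.loc[row, rec.structural_class.value] += 1
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    return table


def classify_folding_type(
    has_stable_intermediate: bool, has_chevron_curvature: bool
) -> FoldClass:
    """Assign the kinetic folding class from two curator observations.

    A stable kinetic intermediate makes a protein non-two-state.  Without
    one, chevron-limb curvature (evidence of a hidden high-energy
    intermediate) gives 2S*; otherwise plain 2S.
    """
    if has_stable_intermediate:
        return FoldClass.NON_TWO_STATE
    if has_chevron_curvature:
        return FoldClass.TWO_STATE_HIDDEN
    return FoldClass.TWO_STATE


# ---------------------------------------------------------------------------
# CSV round-trip

_CSV_COLUMNS = [
    "pdb_code",
    "protein_name",
    "structural_class",
    "scop_fold",
    "l_pdb",
    "l_experimental",
    "ph",
    "temperature_c",
    "folding_type",
    "ln_kf_reported",
    "ln_kf_corrected",
    "ln_kf_provenance",
    "ln_ki",
    "ln_ku_reported",
    "ln_ku_corrected",
    "ln_ku_provenance",
    "beta_t",
    "folding_dh_act",
    "folding_dcp_act",
    "folding_t_ref_k",
    "unfolding_dh_act",
    "unfolding_dcp_act",
    "unfolding_t_ref_k",
    "t_target_override_k",
    "flags",
    "comment",
]


def _fmt(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)  # shortest round-trippable representation
    return str(value)


def _opt_float(cell: str) -> Optional[float]:
    return float(cell) if cell != "" else None


def _opt_int(cell: str) -> Optional[int]:
    return int(cell) if cell != "" else None


def write_records_csv(
    records: Sequence[KineticsRecord],
    path_or_buf: Union[str, Path, io.TextIOBase],
    temperature_unit: str = "C",
) -> None:
    """Write records as UTF-8 CSV; read back losslessly with
    :func:`read_records_csv`.

    Temperatures are written in degrees Celsius by default
    (``temperature_unit="K"`` switches the column to Kelvin and renames
    its header accordingly).
    """
    if temperature_unit not in ("C", "K"):
        raise ValueError("temperature_unit must be 'C' or 'K'")
    columns = list(_CSV_COLUMNS)
    if temperature_unit == "K":
        columns[columns.index("temperature_c")] = "temperature_k"

    def _render(handle: io.TextIOBase) -> None:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for rec in records:
            if rec.temperature is None:
                temp_cell = ""
            elif temperature_unit == "C":
                temp_cell = repr(rec.temperature.celsius)
            else:
                temp_cell = repr(rec.temperature.kelvin)
            fa, ua = rec.folding_activation, rec.unfolding_activation
            writer.writerow(
                [
                    rec.pdb_code,
                    rec.protein_name,
                    rec.structural_class.value if rec.structural_class else "",
                    rec.scop_fold,
                    _fmt(rec.l_pdb),
                    _fmt(rec.l_experimental),
                    _fmt(rec.ph),
                    temp_cell,
                    rec.folding_type.value if rec.folding_type else "",
                    _fmt(rec.ln_kf_reported),
                    _fmt(rec.ln_kf_corrected),
                    _fmt(rec.ln_kf_provenance),
                    _fmt(rec.ln_ki),
                    _fmt(rec.ln_ku_reported),
                    _fmt(rec.ln_ku_corrected),
                    _fmt(rec.ln_ku_provenance),
                    _fmt(rec.beta_t),
                    _fmt(fa.delta_h_act if fa else None),
                    _fmt(fa.delta_cp_act if fa else None),
                    _fmt(fa.t_ref_k if fa else None),
                    _fmt(ua.delta_h_act if ua else None),
                    _fmt(ua.delta_cp_act if ua else None),
                    _fmt(ua.t_ref_k if ua else None),
                    _fmt(rec.t_target_override_k),
                    ";".join(sorted(rec.flags)),
                    rec.comment,
                ]
            )

    if isinstance(path_or_buf, (str, Path)):
        with open(path_or_buf, "w", newline="", encoding="utf-8") as handle:
            _render(handle)
    else:
        _render(path_or_buf)


def read_records_csv(path_or_buf: Union[str, Path, io.TextIOBase]) -> List[KineticsRecord]:
    """Read records written by :func:`write_records_csv`."""
    if isinstance(path_or_buf, (str, Path)):
        handle: io.TextIOBase = open(path_or_buf, "r", newline="", encoding="utf-8")
        close = True
    else:
        handle, close = path_or_buf, False
    try:
        reader = csv.reader(handle)
        header = next(reader)
        if "temperature_c" in header:
            temp_col, temp_unit = header.index("temperature_c"), "C"
        elif "temperature_k" in header:
            temp_col, temp_unit = header.index("temperature_k"), "K"
        else:
            raise ValueError("no temperature column (temperature_c or temperature_k) in header")
        idx = {name: header.index(name) for name in header}
        records: List[KineticsRecord] = []
        for row in reader:
            if not row:
                continue

            def cell(name: str) -> str:
                return row[idx[name]]

            temp_cell = row[temp_col]
            if temp_cell == "":
                temperature = None
            elif temp_unit == "C":
                temperature = Temperature.from_celsius(float(temp_cell))
            else:
                temperature = Temperature(float(temp_cell))

            def activation(prefix: str) -> Optional[ActivationData]:
                dh = _opt_float(cell(f"{prefix}_dh_act"))
                dcp = _opt_float(cell(f"{prefix}_dcp_act"))
                tref = _opt_float(cell(f"{prefix}_t_ref_k"))
                if dh is None and dcp is None and tref is None:
                    return None
                if dh is None or dcp is None or tref is None:
                    raise ValueError(f"partial {prefix} activation data in row {row!r}")
                return ActivationData(dh, dcp, tref)

            records.append(
                KineticsRecord(
                    pdb_code=cell("pdb_code"),
                    protein_name=cell("protein_name"),
                    structural_class=StructuralClass(cell("structural_class"))
                    if cell("structural_class")
                    else None,
                    scop_fold=cell("scop_fold"),
                    l_pdb=_opt_int(cell("l_pdb")),
                    l_experimental=_opt_int(cell("l_experimental")),
                    ph=_opt_float(cell("ph")),
                    temperature=temperature,
                    folding_type=FoldClass(cell("folding_type")) if cell("folding_type") else None,
                    ln_kf_reported=_opt_float(cell("ln_kf_reported")),
                    ln_kf_corrected=_opt_float(cell("ln_kf_corrected")),
                    ln_kf_provenance=cell("ln_kf_provenance") or None,
                    ln_ki=_opt_float(cell("ln_ki")),
                    ln_ku_reported=_opt_float(cell("ln_ku_reported")),
                    ln_ku_corrected=_opt_float(cell("ln_ku_corrected")),
                    ln_ku_provenance=cell("ln_ku_provenance") or None,
                    beta_t=_opt_float(cell("beta_t")),
                    folding_activation=activation("folding"),
                    unfolding_activation=activation("unfolding"),
                    t_target_override_k=_opt_float(cell("t_target_override_k")),
                    flags=frozenset(f for f in cell("flags").split(";") if f),
                    comment=cell("comment"),
                )
            )
        return records
    finally:
        if close:
            handle.close()
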