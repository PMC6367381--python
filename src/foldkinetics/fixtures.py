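"""Packaged reference fixtures: calibration panels, validation panels,
curation lists, and synthetic stand-in rosters.

The calibration and validation panels transcribe the published
per-protein cells (chain length, measurement temperature, activation
enthalpy and heat capacity, observed and predicted log rates).  The
curation lists carry the named exclusions, duplicate pairs and roster
counts of the source-dataset construction.

Full database rosters are not printed anywhere, so the record lists used
for bookkeeping checks (dataset merging, composition margins) are
*synthetic* stand-ins generated to match the published counts; they carry
made-up kinetics values and are suitable only for structural/arithmetic
tests, never for numeric ones.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .calibration import (
    CorrectionParams,
    Direction,
    FoldClass,
    PairedRateObservation,
    calibrate_folding_panel,
)
from .curation import KineticsRecord, StructuralClass
from .thermo import (
    T_STANDARD,
    Temperature,
    beta_from_activation,
    delta_cp_from_length,
    t_h_from_enthalpy,
)

__all__ = [
    "folding_panel",
    "folding_panel_computed",
    "recalibrated_folding_params",
    "kf_validation_panel",
    "ku_validation_panel",
    "validation_pairs",
    "curation_lists",
    "composition_counts",
    "mean_tanford_beta_n2s",
    "synthetic_pfdb_construction",
]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath("data", name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


@lru_cache(maxsize=None)
def curation_lists() -> Dict:
    """Named exclusions, duplicate pairs and roster counts (read-only)."""
    text = resources.files(__package__).joinpath("data", "curation_lists.json").read_text("utf-8")
    return json.loads(text)


def mean_tanford_beta_n2s() -> Tuple[float, float, int]:
    """Published mean Tanford beta over the non-two-state panel.

    Returns (mean, se, n).  The per-protein values behind it are not
    printed; only this summary is available as an input.
    """
    lists = curation_lists()
    return (
        float(lists["mean_tanford_beta_n2s"]),
        float(lists["mean_tanford_beta_n2s_se"]),
        int(lists["mean_tanford_beta_n2s_n"]),
    )


def folding_panel(fold_class: FoldClass = FoldClass.TWO_STATE) -> pd.DataFrame:
    """The folding calibration panel for one folding class.

    Columns: pdb, l_pdb, temp_k, delta_h_act_kj_mol, delta_cp_act_kj_mol_k
    plus the printed (2 dp) t_hf, dCp and beta_f cells for cross-checks.
    """
    name = (
        "folding_panel_2s.csv"
        if FoldClass(fold_class).effective_two_state
        else "folding_panel_n2s.csv"
    )
    return _read_csv(name)


def folding_panel_computed(fold_class: FoldClass = FoldClass.TWO_STATE) -> pd.DataFrame:
    """Panel with derived columns recomputed from the raw inputs.

    Adds ``delta_cp_computed`` (chain-length regression), ``t_h_computed``
    (T_a - dH_act/dCp_act) and ``beta_computed`` (dCp_act/dCp) next to the
    printed cells.
    """
    df = folding_panel(fold_class).copy()
    df["delta_cp_computed"] = [delta_cp_from_length(l) for l in df["l_pdb"]]
    df["t_h_computed"] = [
        t_h_from_enthalpy(t, dh, dcp).kelvin
        for t, dh, dcp in zip(df["temp_k"], df["delta_h_act_kj_mol"], df["delta_cp_act_kj_mol_k"])
    ]
    df["beta_computed"] = [
        beta_from_activation(dcp_act, dcp_eq)
        for dcp_act, dcp_eq in zip(df["delta_cp_act_kj_mol_k"], df["delta_cp_computed"])
    ]
    return df


def recalibrated_folding_params(fold_class: FoldClass = FoldClass.TWO_STATE) -> CorrectionParams:
    """Panel-average folding CorrectionParams recomputed from the fixture."""
    df = folding_panel(fold_class)
    triples = list(
        zip(df["temp_k"], df["delta_h_act_kj_mol"], df["delta_cp_act_kj_mol_k"])
    )
    return calibrate_folding_panel(
        triples,
        [int(l) for l in df["l_pdb"]],
        fold_class=FoldClass(fold_class),
    )


def kf_validation_panel() -> pd.DataFrame:
    """Folding-rate validation panel: ln k_f at T_x with its observed and
    published-predicted partners at the standard temperature."""
    return _read_csv("kf_validation.csv")


def ku_validation_panel() -> pd.DataFrame:
    """Unfolding-rate validation panel (used for the T_Hu placement)."""
    return _read_csv("ku_validation.csv")


def validation_pairs(
    direction: Direction,
    lengths: Mapping[str, int],
    fold_class: Optional[FoldClass] = None,
) -> Tuple[List[PairedRateObservation], List[str]]:
    """Typed paired observations from a validation panel.

    Chain lengths are not part of the printed panels, so the caller must
    supply a ``{pdb: L_PDB}`` mapping (e.g. from the downloadable
    database) covering every requested protein.  Rows whose T_x equals
    the row's own target temperature carry no correction information and
    are excluded; their ids are returned second.
    """
    direction = Direction(direction)
    df = ku_validation_panel() if direction is Direction.UNFOLDING else kf_validation_panel()
    prefix = "ln_ku" if direction is Direction.UNFOLDING else "ln_kf"
    if fold_class is not None:
        want_2s = FoldClass(fold_class).effective_two_state
        df = df[(df["fold_class"] == "2S") == want_2s]
    pairs: List[PairedRateObservation] = []
    skipped: List[str] = []
    for row in df.itertuples(index=False):
        if getattr(row, "t_x_k") == getattr(row, "t0_k"):
            skipped.append(row.pdb)
            continue
        if row.pdb not in lengths:
            raise KeyError(f"no chain length supplied for {row.pdb}")
        pairs.append(
            PairedRateObservation(
                protein_id=row.pdb,
                ln_k_x=getattr(row, f"{prefix}_tx"),
                t_x_k=getattr(row, "t_x_k"),
                ln_k_0_observed=getattr(row, f"{prefix}_t0_observed"),
                delta_cp_eq=delta_cp_from_length(int(lengths[row.pdb])),
                t_target_k=getattr(row, "t0_k"),
            )
        )
    return pairs, skipped


def composition_counts() -> pd.DataFrame:
    """Published folding-type x structural-class composition counts."""
    df = _read_csv("composition.csv").set_index("folding_type")
    df.columns = [
        StructuralClass.ALPHA.value,
        StructuralClass.BETA.value,
        StructuralClass.ALPHA_PLUS_BETA.value,
        StructuralClass.ALPHA_BETA.value,
    ]
    return df


def _composition_pools() -> Tuple[List[StructuralClass], List[StructuralClass]]:
    counts = composition_counts()
    pools: Dict[str, List[StructuralClass]] = {"2S": [], "N2S": []}
    for ftype in ("2S", "N2S"):
        for cls in StructuralClass:
            pools[ftype].extend([cls] * int(counts.loc[ftype, cls.value]))
    return pools["2S"], pools["N2S"]


def _stub(pdb: str, ftype: FoldClass, sclass: StructuralClass) -> KineticsRecord:
    # synthetic stand-in record: structure/arithmetic only, kinetics values fake
    return KineticsRecord(
        pdb_code=pdb,
        protein_name=f"synthetic stand-in {pdb}",
        structural_class=sclass,
        l_pdb=80,
        temperature=T_STANDARD,
        folding_type=ftype,
        ln_kf_reported=5.0,
        comment="synthetic roster stand-in",
    )


def synthetic_pfdb_construction() -> Dict[str, List[KineticsRecord]]:
    """Synthetic rosters reproducing the published construction arithmetic.

    The real rosters are not printed, so stand-in records are generated to
    the published counts: a filtered first source of 102 proteins, a
    filtered second source of 99 sharing all but 6 (the named unique
    additions), their 108-protein merge, the 33 named new proteins
    (19 two-state, 14 non-two-state), and the final 141-protein roster
    whose folding-type/structural-class composition matches the published
    margins (89 two-state, 52 non-two-state).

    Returns a dict with keys ``acpro_filtered``, ``garbuzynskiy_filtered``,
    ``new_proteins`` and ``full``.
    """
    lists = curation_lists()
    pool_2s, pool_n2s = _composition_pools()

    new_records: List[KineticsRecord] = []
    for pdb in lists["new_proteins_2s"]:
        new_records.append(_stub(pdb, FoldClass.TWO_STATE, pool_2s.pop()))
    for pdb in lists["new_proteins_n2s"]:
        new_records.append(_stub(pdb, FoldClass.NON_TWO_STATE, pool_n2s.pop()))

    # remaining composition slots are dealt to the merged-source roster
    ag_slots = [(FoldClass.TWO_STATE, c) for c in pool_2s] + [
        (FoldClass.NON_TWO_STATE, c) for c in pool_n2s
    ]
    assert len(ag_slots) == lists["ag_dataset_count"]

    unique = list(lists["garbuzynskiy_unique"])
    n_acpro = lists["acpro_filtered_count"]
    acpro: List[KineticsRecord] = []
    garb: List[KineticsRecord] = []
    for i, (ftype, sclass) in enumerate(ag_slots):
        if i < n_acpro:
            rec = _stub(f"A{i:03d}", ftype, sclass)
            acpro.append(rec)
            # the second source shares most of the first source's entries
            if len(garb) < lists["garbuzynskiy_filtered_count"] - len(unique):
                garb.append(rec)
        else:
            garb.append(_stub(unique[i - n_acpro], ftype, sclass))

    merged = acpro + garb[len(garb) - len(unique):]
    full = merged + new_records
    return {
        "acpro_filtered": acpro,
        "garbuzynskiy_filtered": garb,
        "new_proteins": new_records,
        "full": full,
    }
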