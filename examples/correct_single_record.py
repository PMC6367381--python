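"""Standardize one protein's folding rate constant to 25 C.

A two-state protein of 86 residues was measured at 10 C (283.15 K) with
ln k_f = 7.09.  The default policy corrects it with the two-state panel
parameters (T_H = 315 K, beta = -0.62) and an activation heat capacity
scaled from chain length.
"""

from foldkinetics import KineticsRecord, Temperature, correct_record
from foldkinetics.calibration import FoldClass

record = KineticsRecord(
    pdb_code="1IMQ",
    l_pdb=86,
    temperature=Temperature.from_celsius(10.0),
    folding_type=FoldClass.TWO_STATE,
    ln_kf_reported=7.09,
)

out = correct_record(record)
print(f"measured   ln k_f({record.temperature.kelvin:.2f} K) = {record.ln_kf_reported:.2f}")
print(f"corrected  ln k_f(298.15 K) = {out.ln_kf_corrected:.2f}  [{out.ln_kf_provenance}]")
print(
    "The corrected value is the model's prediction of the folding rate the"
    " same experiment would report at the standard 25 C; 'panel_default'"
    " records that the panel-average (T_H, beta) pair was used."
)
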