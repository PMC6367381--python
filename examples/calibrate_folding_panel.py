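"""Average per-protein folding parameters into panel-level values.

The packaged two-state calibration panel carries, for each of 12
proteins, the chain length, measurement temperature, activation enthalpy
and activation heat capacity.  Per-protein T_H and beta are derived and
averaged; the panel mean is the (T_H, beta) pair the default correction
policy uses.
"""

from foldkinetics import fixtures
from foldkinetics.calibration import FoldClass, calibrate_folding_panel

df = fixtures.folding_panel(FoldClass.TWO_STATE)
triples = list(zip(df["temp_k"], df["delta_h_act_kj_mol"], df["delta_cp_act_kj_mol_k"]))
params = calibrate_folding_panel(triples, [int(l) for l in df["l_pdb"]])

print(f"panel of {params.n_proteins} two-state proteins")
print(f"T_Hf  = {params.t_h.kelvin:.2f} +/- {params.t_h_se:.2f} K")
print(f"beta_f = {params.beta:.2f} +/- {params.beta_se:.2f}")
print(
    "These are the standard-error panel means; rounded they give the"
    " headline two-state folding policy (315 K, -0.62), and"
    " beta_u = 1 + beta_f = 0.38 follows for unfolding."
)
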