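{
  "acpro_input_count": 126,
  "acpro_filtered_count": 102,
  "acpro_exclusions": {
    "too_short": ["1PGB (41-56)", "1L2Y", "3M48"],
    "disulfide": ["2HQI", "1HEL", "1E65", "1HMK"],
    "prosthetic_group": ["1YCC", "1YEA", "256B", "1HRC"],
    "irrelevant_rate": ["1AON", "1BD8", "1JON"],
    "denaturant_present": ["1QOP (chain B)"],
    "missing_coordinates": ["1EAL"],
    "missing_reference": ["1PSF"]
  },
  "duplicate_pairs": [
    ["1NTI", "2FDQ"],
    ["1SRL", "1FMK"],
    ["1BF4", "1BNZ"],
    ["1POH", "2HPR"],
    ["1O6X", "1PBA"],
    ["1EAL", "2EAL"]
  ],
  "garbuzynskiy_input_count": 107,
  "garbuzynskiy_filtered_count": 99,
  "garbuzynskiy_exclusions": {
    "too_short": ["1L2Y", "1T8J", "1PGB (41-56)", "G-DATASET-ENTRY-3"],
    "irrelevant_rate": ["1AON", "1BD8"],
    "missing_coordinates": ["1EAL"],
    "prosthetic_group": ["256B"]
  },
  "garbuzynskiy_unique": ["1IFC", "1CBI", "1IGS", "1OPA", "2MYO", "3H08"],
  "ag_dataset_count": 108,
  "new_proteins_2s": [
    "1DKT", "1FGA", "1IO2", "1KDX", "1NFI", "1QAU", "1RG8", "2BKF",
    "2GA5", "2J5A", "2JMC", "2LLH", "2L6R", "2WQG", "3O48", "3O49",
    "3O4D", "3ZRT (N-terminal)", "3ZRT (C-terminal)"
  ],
  "new_proteins_n2s": [
    "1DWR", "1EKG", "1FA3", "1HRH", "1OKS", "1THF", "1UCH", "2BJD",
    "2FS6", "2KDI", "2KLL", "2X7Z", "3BLM", "5L8I"
  ],
  "pfdb_total": 141,
  "pfdb_2s": 89,
  "pfdb_n2s": 52,
  "mean_tanford_beta_n2s": 0.79,
  "mean_tanford_beta_n2s_se": 0.02,
  "mean_tanford_beta_n2s_n": 38,
  "tanford_beta_off_pathway_excluded": ["1FTG"],
  "denaturant_activity_convention": ["1PHP (1-175)", "1PHP (186-394)", "1L63", "1HNG", "1TTG"],
  "parallel_pathway_proteins": ["1RA9", "1B9C", "1FA3", "2PQE"],
  "thermophilic_caveat": true
}
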