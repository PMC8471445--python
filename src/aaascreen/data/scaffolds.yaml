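- category: aristolochic_acid
  smarts: '[#8]=[#6](-[#8])-[#6]1:[#6]:[#6]2:[#6](:[#6]3:[#6]:1:[#6](-[#7](=[#8])-[#8]):[#6]:[#6]1:[#6]:3:[#6]:[#6]:[#6]:[#6]:1)-[#8]-[#6]-[#8]-2'
  core_smiles: O=C(O)c1cc2c(c3c1c([N+](=O)[O-])cc1ccccc13)OCO2
  features:
  - nitro
  - methylenedioxy
  - carboxylic_acid
  provenance: MCS of the 45-member synthetic surrogate reference set (seed 20240901)
  policy_hash: 44e20c9c412e
- category: aristolactam
  smarts: '[#8]=[#6]1-[#7]-[#6]2:[#6]3:[#6]-1:[#6]:[#6]1:[#6](:[#6]:3:[#6]3:[#6](:[#6]:2):[#6]:[#6]:[#6]:[#6]:3)-[#8]-[#6]-[#8]-1'
  core_smiles: O=C1Nc2cc3ccccc3c3c4c(cc1c23)OCO4
  features:
  - methylenedioxy
  - lactam_carbonyl
  provenance: MCS of the 45-member synthetic surrogate reference set (seed 20240901)
  policy_hash: 44e20c9c412e
- category: dioxoaporphine
  smarts: '[#6]-[#8]-[#6]1:[#6](-[#8]):[#6]:[#6]2:[#6]3:[#6]:1:[#6]1:[#6]:[#6]:[#6]:[#6]:[#6]:1:[#6]:[#6]:3-[#7]-[#6](-[#6]-2=[#8])=[#8]'
  core_smiles: CN1C(=O)C(=O)c2cc3c(c4c2c1cc1ccccc14)OCO3
  features:
  - methylenedioxy
  - lactam_carbonyl
  - ring_dione
  provenance: MCS of the 19-member synthetic surrogate reference set (seed 20240901)
  policy_hash: 44e20c9c412e
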