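# Three-group amino-acid partitions used by the property CTD descriptors.
# One row per (property, group); groups A/B/C are disjoint and together
# cover all 20 amino acids.  Partitions follow the standard CTD descriptor
# convention (hydrophobicity: polar/neutral/hydrophobic, etc.).
property	group	residues
hydrophobicity	A	RKEDQN
hydrophobicity	B	GASTPHY
hydrophobicity	C	CLVIMFW
normalized_vdw_volume	A	GASTPDC
normalized_vdw_volume	B	NVEQIL
normalized_vdw_volume	C	MHKFRYW
polarity	A	LIFWCMVY
polarity	B	PATGS
polarity	C	HQRKNED
polarizability	A	GASDT
polarizability	B	CPNVEQIL
polarizability	C	KMHFRYW
charge	A	KR
charge	B	ANCQGHILMFPSTWYV
charge	C	DE
secondary_structure	A	EALMQKRH
secondary_structure	B	VIYCWFT
secondary_structure	C	GNPSD
solvent_accessibility	A	ALFCGIVW
solvent_accessibility	B	RKQEND
solvent_accessibility	C	MSPTHY
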