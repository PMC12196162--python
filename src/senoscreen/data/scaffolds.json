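{
 "version": 1,
 "comment": "Synthetic scaffold grammar for fixture libraries. Templates carry {R1}/{R2} slots filled from the substituent list; every combination parses under RDKit. 'active' cores are the planted senolytic-like scaffolds, 'decoy' cores build the inactive background.",
 "active_templates": [
  "c1cc({R1})cc2c1nc(s2)N1CCN(CC1)C(=O)c1ccc({R2})cc1",
  "c1cc({R1})c2[nH]c(c(c2c1)CC(=O)N1CCOCC1)c1ccc({R2})cc1C",
  "O=C(Nc1ccc2nc({R1})oc2c1)c1ccc(cc1)S(=O)(=O)N1CCC({R2})CC1",
  "c1cc({R1})nc2c1cc(cn2)C(=O)Nc1ccc(cc1)OCC(=O)N1CCC({R2})CC1"
 ],
 "decoy_templates": [
  "C1CC({R1})CCC1{R2}",
  "C1CC({R1})CN(C1)C(=O){R2}",
  "O=C({R1})NC({R2})C",
  "C1OC({R1})CC1O{R2}",
  "c1cc({R1})ccc1OCC(=O)N{R2}",
  "C({R1})CC(=O)OC{R2}",
  "O=S(=O)(N{R1})c1ccc({R2})cc1",
  "N({R1})C(=O)C1CCC({R2})CC1"
 ],
 "substituents": [
  "C", "CC", "CCC", "CCCC", "O", "OC", "OCC", "N", "NC", "N(C)C",
  "F", "Cl", "Br", "C(=O)O", "C(=O)OC", "C(=O)N", "C#N", "C(F)(F)F",
  "CO", "CN", "CCO", "CCN", "C(C)C", "C(C)(C)C"
 ]
}
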