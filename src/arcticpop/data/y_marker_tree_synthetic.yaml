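# Synthetic Y-chromosome biallelic marker tree.
#
# A SYNTHETIC stand-in for a curated NRY haplogroup reference: the hierarchy
# is a simplified rendering of the standard YCC topology restricted to the
# 28 biallelic markers typed in Northeast Eurasian population surveys
# (M9, TAT, SRY1532, 92R7, M207, M20, M89, P43, P37, M231, M35, M78, M269,
# M412, M458, M48, M52, M70, M130, M170, M173, M175, M201, M217, M253,
# M407, YAP, 12f2). Marker-to-branch placement is approximate; edit this
# file to refine it. Tokens are marker names, so the same classifier used
# for mtDNA trees applies unchanged.
name: y-synthetic
root: Y-MRCA
nodes:
  C:        {parent: Y-MRCA, variants: [M130]}
  C3:       {parent: C, variants: [M217]}
  C3c:      {parent: C3, variants: [M48]}
  C3d:      {parent: C3, variants: [M407]}
  DE:       {parent: Y-MRCA, variants: [YAP]}
  E1b1b1:   {parent: DE, variants: [M35]}
  E1b1b1a:  {parent: E1b1b1, variants: [M78]}
  F:        {parent: Y-MRCA, variants: [M89]}
  G:        {parent: F, variants: [M201]}
  H1:       {parent: F, variants: [M52]}
  I:        {parent: F, variants: [M170]}
  I1:       {parent: I, variants: [M253]}
  I2a:      {parent: I, variants: [P37]}
  J:        {parent: F, variants: [12f2]}
  K:        {parent: F, variants: [M9]}
  L:        {parent: K, variants: [M20]}
  T:        {parent: K, variants: [M70]}
  N:        {parent: K, variants: [M231]}
  N1b:      {parent: N, variants: [P43]}
  N1c:      {parent: N, variants: [TAT]}
  O:        {parent: K, variants: [M175]}
  P:        {parent: K, variants: [92R7]}
  R:        {parent: P, variants: [M207]}
  R1:       {parent: R, variants: [M173]}
  R1a:      {parent: R1, variants: [SRY1532]}
  R1a-M458: {parent: R1a, variants: [M458]}
  R1b:      {parent: R1, variants: [M269]}
  R1b-M412: {parent: R1b, variants: [M412]}
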