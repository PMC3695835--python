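# Synthetic mtDNA haplogroup marker tree.
#
# This is a SYNTHETIC stand-in for a curated haplogroup reference tree: the
# clade hierarchy covers the haplogroups discussed for Northeast Eurasian
# populations, but most coding-region defining markers are invented
# placeholders chosen only to be internally consistent (unique positions,
# outside the excluded poly-C stretches). The handful of defining variants
# that are documented for the terminal clades of interest are real:
#   C4b9   : 3306C  (transition T3306C)
#   Z1a1b  : 7521A + 8251A
#   Z1a3   : 11252G
#   C5a2a  : back-mutation 16189C! (on top of 16189C carried by C5a2)
#   C4a1c1 : back-mutation 16298C! (on top of 16298C carried by C)
#   R1     : motif 1391C + 16311C (16519T omitted: excluded site)
# Edit or replace this file to use a fuller reference tree; the classifier
# only needs the parent/variants schema below.
name: mt-synthetic
root: mt-MRCA
nodes:
  M:       {parent: mt-MRCA, variants: [10400T, 14783C, 15043A]}
  N:       {parent: mt-MRCA, variants: [8701A, 9540T]}
  C:       {parent: M, variants: [9545G, 13263G, 14318C, 16298C, 16327T]}
  C4:      {parent: C, variants: [6026T, 11969A]}
  C4a:     {parent: C4, variants: [2232A]}
  C4a1:    {parent: C4a, variants: [12062G]}
  C4a1c:   {parent: C4a1, variants: [12672G]}
  C4a1c1:  {parent: C4a1c, variants: [16298C!]}
  C4a1d:   {parent: C4a1, variants: [14180C]}
  C4a2:    {parent: C4a, variants: [8584A]}
  C4b:     {parent: C4, variants: [15204C]}
  C4b1:    {parent: C4b, variants: [16093C]}
  C4b2:    {parent: C4b, variants: [16257A]}
  C4b3:    {parent: C4b, variants: [4715G]}
  C4b3a:   {parent: C4b3, variants: [9962A]}
  C4b7:    {parent: C4b, variants: [5147A]}
  C4b9:    {parent: C4b, variants: [3306C]}
  C5:      {parent: C, variants: [8614C, 9165C]}
  C5a:     {parent: C5, variants: [15930A]}
  C5a1:    {parent: C5a, variants: [1598A]}
  C5a2:    {parent: C5a, variants: [16189C]}
  C5a2a:   {parent: C5a2, variants: [16189C!]}
  C5b:     {parent: C5, variants: [11151T]}
  C5b1:    {parent: C5b, variants: [12358G]}
  C5b1a:   {parent: C5b1, variants: [6131C]}
  C5b1b:   {parent: C5b1, variants: [7694T]}
  C5d:     {parent: C5, variants: [14020C]}
  C5d1:    {parent: C5d, variants: [1719A]}
  C7:      {parent: C, variants: [13368A]}
  C7a1c:   {parent: C7, variants: [6340T]}
  Z:       {parent: M, variants: [9090C, 15784C, 16260T]}
  Z1:      {parent: Z, variants: [16185T]}
  Z1a:     {parent: Z1, variants: [6752C]}
  Z1a1:    {parent: Z1a, variants: [14002C]}
  Z1a1b:   {parent: Z1a1, variants: [7521A, 8251A]}
  Z1a2:    {parent: Z1a, variants: [16129A]}
  Z1a2a:   {parent: Z1a2, variants: [11151C]}
  Z1a3:    {parent: Z1a, variants: [11252G]}
  Z3:      {parent: Z, variants: [6249A]}
  Z3a:     {parent: Z3, variants: [7852A]}
  D:       {parent: M, variants: [4883T, 5178a]}
  D2:      {parent: D, variants: [11215T]}
  D2a:     {parent: D2, variants: [16129G]}
  D4:      {parent: D, variants: [3010A]}
  D4b:     {parent: D4, variants: [8020A]}
  D4b1a2a: {parent: D4b, variants: [9181G]}
  D4i:     {parent: D4, variants: [10181T]}
  D4i2:    {parent: D4i, variants: [15071C]}
  D4j:     {parent: D4, variants: [11696A]}
  D4j2:    {parent: D4j, variants: [4952C]}
  D4o:     {parent: D4, variants: [13651G]}
  D4o2:    {parent: D4o, variants: [7256C]}
  D5:      {parent: D, variants: [1107C]}
  D5a:     {parent: D5, variants: [5301G]}
  D5a2:    {parent: D5a, variants: [16172C]}
  D5a2a:   {parent: D5a2, variants: [752C]}
  D5a2a2:  {parent: D5a2a, variants: [16092C]}
  G:       {parent: M, variants: [4833G]}
  G1:      {parent: G, variants: [15323A]}
  G1b:     {parent: G1, variants: [8200C]}
  G2:      {parent: G, variants: [7600A]}
  G2a5:    {parent: G2, variants: [9575A]}
  M13:     {parent: M, variants: [6498T]}
  M13a1b:  {parent: M13, variants: [14502C]}
  A:       {parent: N, variants: [663G]}
  A2a:     {parent: A, variants: [16265G]}
  A2b:     {parent: A, variants: [11365C]}
  A8:      {parent: A, variants: [16242T]}
  Y:       {parent: N, variants: [8392A]}
  Y1a:     {parent: Y, variants: [16189C, 16231C]}
  R:       {parent: N, variants: [12705C]}
  H:       {parent: R, variants: [2706G, 7028C]}
  H8:      {parent: H, variants: [13101A]}
  H20:     {parent: H, variants: [16218T]}
  H20a:    {parent: H20, variants: [13680T]}
  HV1:     {parent: R, variants: [8014T]}
  HV1a:    {parent: HV1, variants: [15218G]}
  HV1a1a:  {parent: HV1a, variants: [16234T]}
  J:       {parent: R, variants: [295T, 16069T]}
  U:       {parent: R, variants: [11467G, 12308G]}
  R1:      {parent: R, variants: [1391C, 16311C]}
  R1a:     {parent: R1, variants: [6620C]}
  R1b:     {parent: R1, variants: [9266A]}
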