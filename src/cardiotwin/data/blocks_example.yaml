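# EXAMPLE ion-channel inhibition table (IC50 in uM, Hill coefficient).
# Values are illustrative, assembled to be in the order of magnitude of
# public patch-clamp reports for tricyclic antidepressants; they are NOT a
# validated parameterization and downstream quantitative claims must not
# rest on them.
schema: cardiotwin-blocks-1
AT:
  IKr:  {ic50_uM: 3.26, hill: 1.0}
  INa:  {ic50_uM: 25.0, hill: 1.0}
  ICaL: {ic50_uM: 15.0, hill: 1.0}
  IKs:  {ic50_uM: 60.0, hill: 1.0}
NT:
  IKr:  {ic50_uM: 4.0,  hill: 1.0}
  INa:  {ic50_uM: 40.0, hill: 1.0}
  ICaL: {ic50_uM: 20.0, hill: 1.0}
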