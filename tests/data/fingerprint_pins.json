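{
 "CCO": [
  33,
  80,
  222,
  294,
  386,
  807
 ],
 "c1ccccc1": [
  64,
  389,
  849
 ],
 "CC(=O)Nc1ccc(O)cc1": [
  33,
  53,
  128,
  191,
  245,
  289,
  356,
  530,
  578,
  650,
  726,
  745,
  754,
  792,
  807,
  843,
  849,
  893,
  1017
 ],
 "CN1CCC[C@H]1c1cccnc1": [
  4,
  19,
  33,
  56,
  64,
  121,
  168,
  231,
  255,
  288,
  301,
  356,
  368,
  378,
  437,
  446,
  456,
  486,
  511,
  562,
  579,
  639,
  726,
  749,
  842,
  849,
  926,
  935,
  1019
 ],
 "CC(=O)NO": [
  33,
  128,
  239,
  245,
  607,
  650,
  807,
  878,
  893,
  1017
 ]
}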