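{
 "version": "2026.09-default",
 "provenance": {
  "ks_table": "Monte-Carlo: iid Normal(90,30) noise on a (25,256,256) lattice, anisotropy-scaled 3D Scharr kernels, seed 20230711",
  "k2_model": "deviation-rate -0.2 refit on synthetic tube scenes (20x320x320, radii 1.5-10 px, seeds 200-205), K grid geomspace(1,3000,9); 4 usable samples",
  "simulator": "Burr-XII fit on two bootstrap artificial scenes (32x160x160, seeds 300-301); exponential from the same bootstrap (reproduction mode only)"
 },
 "ks_table": {
  "0.1": [
   0.7130275132320918,
   0.36843758469954013
  ],
  "0.2": [
   0.6216908760315629,
   0.31257798288971705
  ],
  "0.3": [
   0.5578864014861773,
   0.27095356605572885
  ],
  "0.4": [
   0.5117013400209387,
   0.23975256623144872
  ],
  "0.5": [
   0.4773406113113379,
   0.21637648864280248
  ],
  "0.6": [
   0.4512157826589956,
   0.19896260942051863
  ],
  "0.7": [
   0.43100180775280056,
   0.18611929782375586
  ],
  "0.8": [
   0.41513511428001054,
   0.1767789464521861
  ],
  "0.9": [
   0.40253186997018425,
   0.17011047898673057
  ],
  "1.0": [
   0.392421273932377,
   0.16546543350113266
  ]
 },
 "k2_log10_a": -1.7781157636705793,
 "k2_log10_b": 0.8177047481010857
}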