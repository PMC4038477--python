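{
 "kind": "circakit-reduced",
 "ref_state": "B_m",
 "params": {
  "kt1": 0.24541705950870787,
  "kt2": 0.3763359311963635,
  "kt3": 0.19097936152646727,
  "kt4": 0.23210930304509655,
  "ktt": 1.0,
  "a1": 2,
  "g1": 0.5874663859480209,
  "a2": 4,
  "g2": 0.36261839346806635,
  "a3": 3,
  "g3": 0.34184709637337546,
  "h1": 7,
  "r1": 0.3184587246080463,
  "h2": 8,
  "r2": 0.1332022001913597,
  "h3": 8,
  "r3": 0.1952270572883771,
  "h4": 7,
  "r4": 0.2612116310149946,
  "h5": 3,
  "r5": 0.7189661013112569,
  "kp_p": 0.3049222746332249,
  "kp_c": 0.5364213372514607,
  "kp_b": 0.14785615144277717,
  "k_ass": 0.9900719294155794,
  "dm_p": 0.14687555269571487,
  "dm_c": 0.17278347349768008,
  "dm_b": 0.15306344425740062,
  "dp_p": 0.08719651419474694,
  "dp_c": 0.1168808255106484,
  "dp_b": 0.1524980174705432,
  "d_PC": 0.40774497884681354,
  "d_R": 0.11780163827110972
 }
}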