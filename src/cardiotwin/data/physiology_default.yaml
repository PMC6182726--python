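# Default adult physiology scaffold (70 kg reference individual).
# Plausible textbook volumes/flows for a perfusion-limited PBPK model;
# config-driven by design so alternative parameterizations can be loaded.
schema: cardiotwin-physiology-1
lumped: false
V_venous: 3.7
V_arterial: 1.85
cardiac_output: 390.0
age: 35
sex: M
body_weight: 70.0
tissues:
  - {name: lung,    volume: 0.5,   flow: 390.0}
  - {name: adipose, volume: 18.0,  flow: 18.0}
  - {name: bone,    volume: 10.5,  flow: 15.0}
  - {name: brain,   volume: 1.45,  flow: 42.0}
  - {name: gut,     volume: 1.65,  flow: 40.0}
  - {name: heart,   volume: 0.33,  flow: 15.6}
  - {name: kidney,  volume: 0.31,  flow: 66.0}
  - {name: liver,   volume: 1.8,   flow: 80.0}
  - {name: muscle,  volume: 29.0,  flow: 50.0}
  - {name: skin,    volume: 3.3,   flow: 17.0}
  - {name: rest,    volume: 5.0,   flow: 20.0}
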