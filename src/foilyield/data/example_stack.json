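[
 {
  "material": "Kapton",
  "thickness_um": 75,
  "role": "window",
  "name": "kapton-window"
 },
 {
  "material": "Air",
  "areal_density_ug_cm2": 14457.5,
  "role": "air_gap",
  "name": "air-gap-12cm"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-01"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-01"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-01"
 },
 {
  "material": "Al",
  "thickness_um": 2000,
  "role": "degrader",
  "name": "Al-deg-01"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-02"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-02"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-02"
 },
 {
  "material": "Al",
  "thickness_um": 2200,
  "role": "degrader",
  "name": "Al-deg-02"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-03"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-03"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-03"
 },
 {
  "material": "Al",
  "thickness_um": 2400,
  "role": "degrader",
  "name": "Al-deg-03"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-04"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-04"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-04"
 },
 {
  "material": "Al",
  "thickness_um": 2600,
  "role": "degrader",
  "name": "Al-deg-04"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-05"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-05"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-05"
 },
 {
  "material": "Al",
  "thickness_um": 2800,
  "role": "degrader",
  "name": "Al-deg-05"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-06"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-06"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-06"
 },
 {
  "material": "Al",
  "thickness_um": 3200,
  "role": "degrader",
  "name": "Al-deg-06"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-07"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-07"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-07"
 },
 {
  "material": "Al",
  "thickness_um": 1900,
  "role": "degrader",
  "name": "Al-deg-07"
 },
 {
  "material": "Ti48",
  "areal_density_ug_cm2": 500.0,
  "role": "target",
  "name": "Ti48-08"
 },
 {
  "material": "Ni",
  "thickness_um": 25,
  "role": "monitor",
  "name": "Ni-08"
 },
 {
  "material": "Al",
  "thickness_um": 10,
  "role": "catcher",
  "name": "Al-catch-08"
 }
]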