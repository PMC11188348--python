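# Default pollutant breakpoint tables and secondary standards.
# Values modeled on the Chinese ambient air quality grading scheme
# (24-h averages; 8-h for O3; mg/m3 for CO, ug/m3 otherwise).
# Fully user-overridable: pass your own file with the same schema.
_schema: breakpoints/1
_version: "1"

pm25:
  units: ug/m3
  s_p: 35.0          # annual secondary standard
  rows:
    - [0, 35, 0, 50]
    - [35, 75, 50, 100]
    - [75, 115, 100, 150]
    - [115, 150, 150, 200]
    - [150, 250, 200, 300]
    - [250, 350, 300, 400]
    - [350, 500, 400, 500]

pm10:
  units: ug/m3
  s_p: 70.0
  rows:
    - [0, 50, 0, 50]
    - [50, 150, 50, 100]
    - [150, 250, 100, 150]
    - [250, 350, 150, 200]
    - [350, 420, 200, 300]
    - [420, 500, 300, 400]
    - [500, 600, 400, 500]

no2:
  units: ug/m3
  s_p: 40.0
  rows:
    - [0, 40, 0, 50]
    - [40, 80, 50, 100]
    - [80, 180, 100, 150]
    - [180, 280, 150, 200]
    - [280, 565, 200, 300]
    - [565, 750, 300, 400]
    - [750, 940, 400, 500]

o3:
  units: ug/m3
  s_p: 160.0         # 8-h average secondary standard
  rows:
    - [0, 100, 0, 50]
    - [100, 160, 50, 100]
    - [160, 215, 100, 150]
    - [215, 265, 150, 200]
    - [265, 800, 200, 300]

so2:
  units: ug/m3
  s_p: 60.0
  rows:
    - [0, 50, 0, 50]
    - [50, 150, 50, 100]
    - [150, 475, 100, 150]
    - [475, 800, 150, 200]
    - [800, 1600, 200, 300]

co:
  units: mg/m3
  s_p: 4.0           # daily average secondary standard
  rows:
    - [0, 2, 0, 50]
    - [2, 4, 50, 100]
    - [4, 14, 100, 150]
    - [14, 24, 150, 200]
    - [24, 36, 200, 300]
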