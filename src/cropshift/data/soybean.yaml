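# Illustrative (synthetic) soybean requirement set for testing and
# examples — plausible ranges, NOT a published crop parameterization.
crop: soybean
season:
  start: 120
  end: 270
parameters:
  - name: temperature
    kind: trapezoid
    breakpoints: [6, 15, 28, 38]
    aggregator: mean
  - name: precipitation
    kind: trapezoid
    breakpoints: [300, 500, 1600, 2500]
    aggregator: sum
  - name: solar_radiation
    kind: trapezoid
    breakpoints: [6, 11, 30, 34]
    aggregator: mean
  - name: ph
    kind: trapezoid
    breakpoints: [5.0, 5.5, 7.0, 8.0]
  - name: organic_carbon
    kind: trapezoid
    breakpoints: [0.3, 1.0, 10, 15]
  - name: salinity
    kind: trapezoid
    breakpoints: [0, 0, 1.5, 6]
  - name: sodicity
    kind: trapezoid
    breakpoints: [0, 0, 12, 35]
  - name: slope
    kind: trapezoid
    breakpoints: [0, 0, 10, 35]
  - name: elevation
    kind: trapezoid
    breakpoints: [-400, -400, 2200, 3500]
  - name: available_water_capacity
    kind: trapezoid
    breakpoints: [40, 90, 300, 300]
  - name: texture_class
    kind: categorical
    classes: {1: 0.7, 2: 1.0, 3: 0.9}
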