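# Illustrative (synthetic) maize requirement set for testing and examples.
# These breakpoints are plausible agronomic ranges, NOT a published
# crop parameterization; do not use for real assessments.
crop: maize
season:
  start: 110
  end: 260
parameters:
  - name: temperature            # growing-season mean, degC
    kind: trapezoid
    breakpoints: [8, 16, 30, 40]
    aggregator: mean
  - name: precipitation          # growing-season sum, mm
    kind: trapezoid
    breakpoints: [250, 450, 1800, 3000]
    aggregator: sum
  - name: solar_radiation        # growing-season mean, MJ m-2 d-1
    kind: trapezoid
    breakpoints: [5, 10, 32, 35]
    aggregator: mean
  - name: ph
    kind: trapezoid
    breakpoints: [4.5, 5.5, 7.5, 8.5]
  - name: organic_carbon         # topsoil, %
    kind: trapezoid
    breakpoints: [0.2, 0.8, 10, 15]
  - name: salinity               # dS m-1
    kind: trapezoid
    breakpoints: [0, 0, 2, 8]
  - name: sodicity               # exchangeable sodium percentage
    kind: trapezoid
    breakpoints: [0, 0, 15, 40]
  - name: slope                  # %
    kind: trapezoid
    breakpoints: [0, 0, 8, 30]
  - name: elevation              # m
    kind: trapezoid
    breakpoints: [-400, -400, 2500, 4000]
  - name: available_water_capacity   # mm, stand-in for soil hydraulics
    kind: trapezoid
    breakpoints: [30, 80, 300, 300]
  - name: texture_class
    kind: categorical
    classes: {1: 0.6, 2: 1.0, 3: 0.8}
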