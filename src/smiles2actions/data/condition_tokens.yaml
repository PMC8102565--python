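# Interval-token tables for reaction conditions.
#
# Each kind defines strictly increasing boundaries of half-open intervals
# [b_i, b_{i+1}) (low-inclusive), one representative value lying inside each
# interval, and the glyph wrapping the 1-based token index in action text.
# Units: temperature in degrees Celsius, duration in seconds, pH unitless.
temperature:
  glyph: "#"
  unit: degC
  boundaries: [-.inf, -60, -10, 10, 40, 80, 120, .inf]
  representatives: [-78, -30, 0, 25, 60, 100, 150]
duration:
  glyph: "@"
  unit: s
  boundaries: [0, 1800, 10800, 36000, 172800, .inf]
  representatives: [600, 3600, 28800, 86400, 259200]
ph:
  glyph: "%"
  unit: pH
  boundaries: [-.inf, 3, 6, 8, 11, .inf]
  representatives: [1, 5, 7, 9, 13]

# Predefined values for phrases that carry no explicit number.
phrases:
  duration:
    overnight: 57600        # 16 h
    "over night": 57600
    "over the weekend": 230400   # 64 h
    "over weekend": 230400
    weekend: 230400
    "half an hour": 1800
    "half hour": 1800
  temperature:
    rt: 25
    r.t.: 25
    "room temperature": 25
    "ambient temperature": 25
    ambient: 25
    "ice bath": 0
    "ice-bath": 0
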