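"""Derived columns as printed in the solubility tables (g/L on the x10 scale;
enhancement factors as plain ratios), frozen for comparison tests."""

# (T/K, P/MPa) -> printed mass solubility x10 (g/L)
PRINTED_S_X10 = {
    (308, 12): 0.88,
    (308, 15): 1.14,
    (308, 18): 1.57,
    (308, 21): 1.82,
    (308, 24): 2.28,
    (308, 27): 2.74,
    (308, 30): 3.55,
    (318, 12): 0.57,
    (318, 15): 1.15,
    (318, 18): 1.66,
    (318, 21): 2.28,
    (318, 24): 2.84,
    (318, 27): 3.18,
    (318, 30): 3.69,
    (328, 12): 0.36,
    (328, 15): 0.86,
    (328, 18): 1.68,
    (328, 21): 2.54,
    (328, 24): 3.0,
    (328, 27): 3.57,
    (328, 30): 3.98,
    (338, 12): 0.14,
    (338, 15): 0.52,
    (338, 18): 1.63,
    (338, 21): 2.47,
    (338, 24): 3.05,
    (338, 27): 3.69,
    (338, 30): 4.21,
}

# (T/K, P/MPa, ethanol mol%) -> printed enhancement factor
PRINTED_ENHANCEMENT = {
    (308, 12, 1): 3.22,
    (308, 12, 3): 9.49,
    (308, 15, 1): 2.65,
    (308, 15, 3): 8.47,
    (308, 18, 1): 2.47,
    (308, 18, 3): 7.17,
    (308, 21, 1): 2.39,
    (308, 21, 3): 6.83,
    (308, 24, 1): 2.3,
    (308, 24, 3): 6.44,
    (308, 27, 1): 2.21,
    (308, 27, 3): 6.08,
    (308, 30, 1): 1.79,
    (308, 30, 3): 5.88,
    (318, 12, 1): 3.91,
    (318, 12, 3): 11.18,
    (318, 15, 1): 3.3,
    (318, 15, 3): 9.42,
    (318, 18, 1): 3.0,
    (318, 18, 3): 8.58,
    (318, 21, 1): 2.74,
    (318, 21, 3): 7.82,
    (318, 24, 1): 2.42,
    (318, 24, 3): 6.91,
    (318, 27, 1): 2.39,
    (318, 27, 3): 6.83,
    (318, 30, 1): 2.35,
    (318, 30, 3): 6.72,
    (328, 12, 1): 4.21,
    (328, 12, 3): 12.65,
    (328, 15, 1): 3.35,
    (328, 15, 3): 11.35,
    (328, 18, 1): 3.17,
    (328, 18, 3): 9.06,
    (328, 21, 1): 2.95,
    (328, 21, 3): 8.41,
    (328, 24, 1): 2.88,
    (328, 24, 3): 8.22,
    (328, 27, 1): 2.72,
    (328, 27, 3): 7.76,
    (328, 30, 1): 2.62,
    (328, 30, 3): 7.55,
    (338, 12, 1): 5.19,
    (338, 12, 3): 15.7,
    (338, 15, 1): 4.69,
    (338, 15, 3): 13.5,
    (338, 18, 1): 3.46,
    (338, 18, 3): 9.88,
    (338, 21, 1): 3.04,
    (338, 21, 3): 8.7,
    (338, 24, 1): 2.96,
    (338, 24, 3): 8.46,
    (338, 27, 1): 2.91,
    (338, 27, 3): 8.32,
    (338, 30, 1): 2.9,
    (338, 30, 3): 8.3,
}
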