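"""Feature and target column schemas for the modelling layer.

The model consumes exactly 37 inputs per cow recording: 4 video biometrics,
18 head-movement statistics and 15 weather/psychrometric variables; the 5
targets are eye temperature, the two milk-productivity measures and the two
milk-composition percentages.
"""

BIOMETRIC_COLUMNS = ["hr_bpm", "hr_amplitude", "rr_brpm", "rr_amplitude"]

MOVEMENT_COLUMNS = (
    [f"q{q}_mean_x" for q in range(1, 5)]
    + [f"q{q}_mean_y" for q in range(1, 5)]
    + [f"q{q}_var_x" for q in range(1, 5)]
    + [f"q{q}_var_y" for q in range(1, 5)]
    + ["var_x", "var_y"]
)

WEATHER_COLUMNS = ["T", "RH", "wind_speed", "wind_dir", "Tdp", "Twet"] + [
    f"THI{i}" for i in range(1, 10)
]

FEATURE_COLUMNS = BIOMETRIC_COLUMNS + MOVEMENT_COLUMNS + WEATHER_COLUMNS
assert len(FEATURE_COLUMNS) == 37

TARGET_COLUMNS = [
    "eye_temp_c",
    "milk_kg_day",
    "milk_kg_milking",
    "fat_pct",
    "protein_pct",
]
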