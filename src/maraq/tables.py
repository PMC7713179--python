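"""Published acquisition protocols and per-material HU statistics.

These numbers describe a hip-prosthesis phantom study on a dual-source
research scanner combining a conventional energy-integrating detector (EID)
with a photon-counting detector (PCD).  PCD series are high-energy threshold
images (HTI): only photons above the stated keV threshold contribute.  Macro
mode groups all 4x4 detector subpixels under one threshold pair; Chess mode
alternates subpixels between two threshold settings, so each setting sees
half the photons (noise up by sqrt(2)).

``PROTOCOL_STATS`` holds, per protocol, the measured mean/SD of CT numbers
(HU) in cortical bone, bone marrow, the water bath with the phantom present,
and the water bath alone.  The simulator uses these as its material model and
noise magnitudes, and the CNR computation consumes them directly.
"""

from __future__ import annotations

MATERIALS = ("cortical_bone", "bone_marrow", "water")

#: (mean, SD) in HU per material; "water" is the bath with phantom present,
#: "water_only" the bath scanned without the phantom (the noise reference).
PROTOCOL_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "Macro-HTI 140/75": {
        "cortical_bone": (595.96, 125.94),
        "bone_marrow": (-647.91, 112.03),
        "water": (-0.03, 56.87),
        "water_only": (0.18, 55.23),
    },
    "Chess-HTI 140/75": {
        "cortical_bone": (614.68, 123.64),
        "bone_marrow": (-661.37, 119.87),
        "water": (0.38, 80.12),
        "water_only": (0.02, 77.25),
    },
    "Chess-HTI 140/65": {
        "cortical_bone": (607.59, 141.91),
        "bone_marrow": (-632.69, 117.38),
        "water": (1.70, 65.26),
        "water_only": (1.34, 63.21),
    },
    "EID-CT 140": {
        "cortical_bone": (679.70, 80.93),
        "bone_marrow": (-674.12, 81.22),
        "water": (-0.34, 34.62),
        "water_only": (-0.27, 32.95),
    },
    "Macro-HTI 120/70": {
        "cortical_bone": (615.25, 139.17),
        "bone_marrow": (-641.32, 111.60),
        "water": (1.08, 57.10),
        "water_only": (1.60, 55.62),
    },
    "Chess-HTI 120/70": {
        "cortical_bone": (640.22, 124.91),
        "bone_marrow": (-665.98, 121.25),
        "water": (0.73, 79.89),
        "water_only": (0.26, 76.92),
    },
    "Chess-HTI 120/60": {
        "cortical_bone": (652.25, 128.28),
        "bone_marrow": (-650.65, 115.25),
        "water": (0.36, 62.67),
        "water_only": (-0.09, 60.28),
    },
    "EID-CT 120": {
        "cortical_bone": (711.29, 84.67),
        "bone_marrow": (-676.49, 81.12),
        "water": (-0.36, 34.60),
        "water_only": (-0.12, 32.80),
    },
    "Macro-HTI 100/65": {
        "cortical_bone": (652.69, 141.56),
        "bone_marrow": (-645.39, 104.58),
        "water": (0.54, 57.81),
        "water_only": (0.29, 55.53),
    },
    "Chess-HTI 100/65": {
        "cortical_bone": (671.94, 142.05),
        "bone_marrow": (-665.54, 120.07),
        "water": (0.09, 80.84),
        "water_only": (0.17, 77.37),
    },
    "Chess-HTI 100/55": {
        "cortical_bone": (709.94, 121.90),
        "bone_marrow": (-667.90, 104.16),
        "water": (-0.78, 61.96),
        "water_only": (-0.66, 59.24),
    },
    "EID-CT 100": {
        "cortical_bone": (761.15, 86.63),
        "bone_marrow": (-679.67, 80.87),
        "water": (-0.29, 35.57),
        "water_only": (0.35, 33.64),
    },
}

#: detector, mode, tube potential [kVp], energy threshold [keV], CTDIvol [mGy]
#: (dose recorded as metadata only; it plays no computational role).
PROTOCOL_ACQUISITION: dict[str, dict] = {
    "EID-CT 140": {"detector": "EID", "mode": None, "kvp": 140, "kev": None, "ctdi_mgy": 20.0},
    "EID-CT 120": {"detector": "EID", "mode": None, "kvp": 120, "kev": None, "ctdi_mgy": 20.0},
    "EID-CT 100": {"detector": "EID", "mode": None, "kvp": 100, "kev": None, "ctdi_mgy": 20.0},
    "Macro-HTI 140/75": {"detector": "PCD", "mode": "Macro", "kvp": 140, "kev": 75, "ctdi_mgy": 20.0},
    "Macro-HTI 120/70": {"detector": "PCD", "mode": "Macro", "kvp": 120, "kev": 70, "ctdi_mgy": 20.0},
    "Macro-HTI 100/65": {"detector": "PCD", "mode": "Macro", "kvp": 100, "kev": 65, "ctdi_mgy": 20.0},
    "Chess-HTI 140/75": {"detector": "PCD", "mode": "Chess", "kvp": 140, "kev": 75, "ctdi_mgy": 20.0},
    "Chess-HTI 140/65": {"detector": "PCD", "mode": "Chess", "kvp": 140, "kev": 65, "ctdi_mgy": 20.0},
    "Chess-HTI 120/70": {"detector": "PCD", "mode": "Chess", "kvp": 120, "kev": 70, "ctdi_mgy": 20.0},
    "Chess-HTI 120/60": {"detector": "PCD", "mode": "Chess", "kvp": 120, "kev": 60, "ctdi_mgy": 20.0},
    "Chess-HTI 100/65": {"detector": "PCD", "mode": "Chess", "kvp": 100, "kev": 65, "ctdi_mgy": 20.0},
    "Chess-HTI 100/55": {"detector": "PCD", "mode": "Chess", "kvp": 100, "kev": 55, "ctdi_mgy": 20.0},
}
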