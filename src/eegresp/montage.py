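"""The 19-channel 10-20 montage used throughout the package.

Channel order follows the conventional anterior-to-posterior reading of the
10-20 layout.  The 2-D coordinates are a schematic azimuthal projection onto
the unit head disc (nose up, left ear at negative x); they are used for
topographic interpolation and artifact spatial falloff, not for source
modelling.
"""

from __future__ import annotations

import math

CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: scalp region per channel (frontal / central / parietal / occipital / temporal)
REGIONS: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F3": "frontal", "F4": "frontal",
    "F7": "frontal", "F8": "frontal", "Fz": "frontal",
    "C3": "central", "C4": "central", "Cz": "central",
    "P3": "parietal", "P4": "parietal", "Pz": "parietal",
    "O1": "occipital", "O2": "occipital",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
}


def _ring(azimuth_deg: float, radius: float) -> tuple[float, float]:
    a = math.radians(azimuth_deg)
    return (radius * math.sin(a), radius * math.cos(a))


#: schematic 2-D electrode coordinates on the unit head disc
MONTAGE_XY: dict[str, tuple[float, float]] = {
    "Fp1": _ring(-18, 0.8), "Fp2": _ring(18, 0.8),
    "F7": _ring(-54, 0.8), "F8": _ring(54, 0.8),
    "T3": _ring(-90, 0.8), "T4": _ring(90, 0.8),
    "T5": _ring(-126, 0.8), "T6": _ring(126, 0.8),
    "O1": _ring(-162, 0.8), "O2": _ring(162, 0.8),
    "F3": (-0.33, 0.36), "F4": (0.33, 0.36),
    "C3": (-0.40, 0.0), "C4": (0.40, 0.0),
    "P3": (-0.33, -0.36), "P4": (0.33, -0.36),
    "Fz": (0.0, 0.40), "Cz": (0.0, 0.0), "Pz": (0.0, -0.40),
}


def validate_channels(labels) -> None:
    """Raise ``ValueError`` if any label is not a 10-20 channel."""
    unknown = [c for c in labels if c not in CHANNELS_1020]
    if unknown:
        raise ValueError(f"unknown 10-20 channel label(s): {unknown}")
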