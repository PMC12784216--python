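"""10-20 montage conventions for the 19-channel dry-headset layout.

Channel order follows the headset's referential montage.  The Hjorth
(small-Laplacian) neighbor sets are fixed here so that spatial filtering is
deterministic and auditable; neighbors are the nearest 10-20 electrodes.
"""

from __future__ import annotations

CHANNELS_19: tuple[str, ...] = (
    "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "T7", "T8",
    "Pz", "P3", "P4", "P7", "P8",
    "O1", "O2",
)

# Aliases between the modern and classic 10-20 names (T7=T3, T8=T4, P7=T5, P8=T6).
ALIASES: dict[str, str] = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

# Hjorth neighbor table (nearest 10-20 neighbors).  The central and parietal
# sets follow the standard small-Laplacian choice for sensorimotor analyses.
NEIGHBORS: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F3", "F7", "Fz"),
    "Fp2": ("Fp1", "F4", "F8", "Fz"),
    "Fz":  ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F3":  ("Fp1", "Fz", "F7", "C3"),
    "F4":  ("Fp2", "Fz", "F8", "C4"),
    "F7":  ("Fp1", "F3", "T7"),
    "F8":  ("Fp2", "F4", "T8"),
    "Cz":  ("Fz", "C3", "C4", "Pz"),
    "C3":  ("F3", "P3", "Cz", "T7"),
    "C4":  ("F4", "P4", "Cz", "T8"),
    "T7":  ("F7", "C3", "P7"),
    "T8":  ("F8", "C4", "P8"),
    "Pz":  ("Cz", "P3", "P4", "O1", "O2"),
    "P3":  ("C3", "Pz", "P7", "O1"),
    "P4":  ("C4", "O2", "Pz", "P8"),
    "P7":  ("T7", "P3", "O1"),
    "P8":  ("T8", "P4", "O2"),
    "O1":  ("P3", "Pz", "O2", "P7"),
    "O2":  ("P4", "Pz", "O1", "P8"),
}


def canonical(name: str) -> str:
    """Map a 10-20 channel name to its canonical form (e.g. T3 -> T7)."""
    name = name.strip()
    return ALIASES.get(name, name)


def contralateral_channel(hand: str) -> str:
    """Analysis channel for a stimulated hand: C4 for left, C3 for right."""
    hand = hand.lower()
    if hand == "left":
        return "C4"
    if hand == "right":
        return "C3"
    raise ValueError(f"hand must be 'left' or 'right', got {hand!r}")
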