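"""Scalp montage: the 56-channel extended 10-20 layout used throughout.

Channel order is fixed (anterior to posterior, left to right within a row)
and every array in the package that carries one value per scalp channel
follows this order.  The EOG lead is appended as the 57th channel of a
recording but is never part of the scalp montage.
"""
from __future__ import annotations

import numpy as np

# 56 scalp electrodes, extended 10-20 system, montage order.
SCALP_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "POz", "PO8",
    "O1", "O2",
)

EOG_CHANNEL = "EOG"
N_SCALP = len(SCALP_CHANNELS)

_ROW_OF_PREFIX = {
    "Fp": 0, "AF": 1, "F": 2, "FT": 3, "FC": 3,
    "T": 4, "C": 4, "TP": 5, "CP": 5, "P": 6, "PO": 7, "O": 8,
}

# Blink leakage from the ocular source into anterior scalp channels
# (coefficient relative to the EOG amplitude).
FRONTAL_LEAK = {
    "Fp1": 0.3, "Fp2": 0.3,
    "AF7": 0.15, "AF3": 0.15, "AF4": 0.15, "AF8": 0.15,
}


def grid_position(name: str) -> tuple[int, int]:
    """Approximate (row, column) of an electrode on the 10-20 grid.

    Row 0 is the Fp line, row 8 the occipital line.  Column 0 is the
    midline; odd electrode numbers map to negative (left) columns and
    even numbers to positive (right) columns, one grid step per
    10-20 increment (e.g. F3 -> column -2, T8 -> column +4).
    """
    prefix = name.rstrip("0123456789z")
    if prefix not in _ROW_OF_PREFIX:
        raise ValueError(f"unknown electrode name {name!r}")
    row = _ROW_OF_PREFIX[prefix]
    suffix = name[len(prefix):]
    if suffix == "z":
        col = 0
    else:
        num = int(suffix)
        col = -(num + 1) // 2 if num % 2 else num // 2
    return row, col


def graph_distance(name: str, ref: str) -> int:
    """Chebyshev distance between two electrodes on the 10-20 grid."""
    r1, c1 = grid_position(name)
    r2, c2 = grid_position(ref)
    return max(abs(r1 - r2), abs(c1 - c2))


def errp_topography(decay: float = 0.6) -> np.ndarray:
    """Spatial weight of the error-potential template per scalp channel.

    Weight 1.0 at the fronto-central maximum (Cz and FCz), attenuated by
    ``decay`` per grid step of distance to the nearer of the two.
    """
    w = np.empty(N_SCALP)
    for i, ch in enumerate(SCALP_CHANNELS):
        d = min(graph_distance(ch, "Cz"), graph_distance(ch, "FCz"))
        w[i] = decay ** d
    return w


def posterior_mask() -> np.ndarray:
    """Boolean mask of parieto-occipital channels (alpha-rhythm sites)."""
    return np.array([grid_position(ch)[0] >= 6 for ch in SCALP_CHANNELS])
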