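"""30-channel 10/20 scalp montage: labels, approximate 2D positions, region map.

The reference electrodes A1/A2 are not part of the analysis montage.
Positions are normalized head coordinates (x toward the right ear, y toward
the nasion, head radius 1); they are used only to derive smooth ERP
topography gain vectors, not for source modelling.
"""

from __future__ import annotations

import numpy as np

#: The 30 scalp channels of the acquisition montage, in recording order.
CHANNELS_30: tuple[str, ...] = (
    "FP1", "FP2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "FZ", "CZ", "PZ", "FC5",
    "FC1", "FC2", "FC6", "CP5", "CP1", "CP2", "CP6", "FPZ", "POZ", "OZ",
)

#: Approximate 2D positions (x, y) on the unit head disc.
POSITIONS: dict[str, tuple[float, float]] = {
    "FP1": (-0.31, 0.95), "FP2": (0.31, 0.95), "FPZ": (0.0, 1.0),
    "F7": (-0.81, 0.59), "F3": (-0.42, 0.54), "FZ": (0.0, 0.50),
    "F4": (0.42, 0.54), "F8": (0.81, 0.59),
    "FC5": (-0.69, 0.28), "FC1": (-0.25, 0.27), "FC2": (0.25, 0.27),
    "FC6": (0.69, 0.28),
    "T3": (-1.0, 0.0), "C3": (-0.50, 0.0), "CZ": (0.0, 0.0),
    "C4": (0.50, 0.0), "T4": (1.0, 0.0),
    "CP5": (-0.69, -0.28), "CP1": (-0.25, -0.27), "CP2": (0.25, -0.27),
    "CP6": (0.69, -0.28),
    "T5": (-0.81, -0.59), "P3": (-0.42, -0.54), "PZ": (0.0, -0.50),
    "P4": (0.42, -0.54), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "OZ": (0.0, -1.0), "O2": (0.31, -0.95),
    "POZ": (0.0, -0.72),
}

#: Four-region partition of the 30-channel montage.
REGIONS: dict[str, tuple[str, ...]] = {
    "frontal": ("FP1", "FP2", "FPZ", "F3", "F4", "F7", "F8", "FZ",
                "FC1", "FC2", "FC5", "FC6"),
    "central-parietal": ("C3", "C4", "CZ", "CP1", "CP2", "CP5", "CP6",
                         "P3", "P4", "PZ", "POZ"),
    "temporal": ("T3", "T4", "T5", "T6"),
    "occipital": ("O1", "O2", "OZ"),
}


def topography_gains(labels: list[str] | tuple[str, ...],
                     center_labels: tuple[str, ...],
                     spread: float = 0.55) -> np.ndarray:
    """Smooth per-channel gain vector peaking near the given electrodes.

    The gain is a Gaussian of the Euclidean distance to the centroid of
    ``center_labels``, renormalized so the maximum over ``labels`` is 1.

    Parameters
    ----------
    labels
        Channel labels to produce gains for (must be in :data:`POSITIONS`).
    center_labels
        Electrodes defining the topography centroid.
    spread
        Gaussian width in normalized head units.
    """
    cx = float(np.mean([POSITIONS[c][0] for c in center_labels]))
    cy = float(np.mean([POSITIONS[c][1] for c in center_labels]))
    pos = np.array([POSITIONS[lb] for lb in labels], dtype=float)
    d2 = (pos[:, 0] - cx) ** 2 + (pos[:, 1] - cy) ** 2
    g = np.exp(-d2 / (2.0 * spread**2))
    return g / g.max()
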