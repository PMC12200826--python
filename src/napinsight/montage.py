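"""Electrode montage with 2-D positions for the sleep-scoring channels.

Positions are approximate 10-20 projections onto the unit disc (nasion up);
only relative distances matter, since adjacency is built from a radius in
the same units.
"""

from __future__ import annotations

#: Eight-channel sleep-scoring montage (frontal, central, parietal, occipital).
DEFAULT_MONTAGE: dict[str, tuple[float, float]] = {
    "F3": (-0.40, 0.55),
    "F4": (0.40, 0.55),
    "C3": (-0.55, 0.00),
    "Cz": (0.00, 0.00),
    "C4": (0.55, 0.00),
    "Pz": (0.00, -0.45),
    "O1": (-0.30, -0.85),
    "O2": (0.30, -0.85),
}

#: Default neighbourhood radius for cluster adjacency on DEFAULT_MONTAGE.
#: Chosen so every channel has at least one neighbour and left/right
#: homologues (e.g. F3-F4) are connected, without making the graph complete.
DEFAULT_ADJACENCY_RADIUS = 0.85
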