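"""Scalp montage: 32 channels of the international 10-10 system.

Positions are 2-D azimuthal-projection coordinates on the unit disc
(nose up, +x toward the right ear). They are used only to build spatial
templates (ocular topographies, channel groups), never for source
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# (label, x, y) — approximate 10-10 layout positions, outer ring |r| ~ 0.9.
_STANDARD_32 = [
    ("Fp1", -0.28, 0.86), ("Fpz", 0.00, 0.90), ("Fp2", 0.28, 0.86),
    ("AF3", -0.20, 0.68), ("AF4", 0.20, 0.68),
    ("F7", -0.73, 0.53), ("F3", -0.37, 0.47), ("Fz", 0.00, 0.45),
    ("F4", 0.37, 0.47), ("F8", 0.73, 0.53),
    ("FC5", -0.60, 0.27), ("FC1", -0.20, 0.23), ("FC2", 0.20, 0.23),
    ("FC6", 0.60, 0.27),
    ("T7", -0.90, 0.00), ("C3", -0.45, 0.00), ("Cz", 0.00, 0.00),
    ("C4", 0.45, 0.00), ("T8", 0.90, 0.00),
    ("CP5", -0.60, -0.27), ("CP1", -0.20, -0.23), ("CP2", 0.20, -0.23),
    ("CP6", 0.60, -0.27),
    ("P7", -0.73, -0.53), ("P3", -0.37, -0.47), ("Pz", 0.00, -0.45),
    ("P4", 0.37, -0.47), ("P8", 0.73, -0.53),
    ("POz", 0.00, -0.68),
    ("O1", -0.28, -0.86), ("Oz", 0.00, -0.90), ("O2", 0.28, -0.86),
]

#: Named channel groups used to target spectral effects at scalp regions.
CHANNEL_GROUPS: dict[str, tuple[str, ...]] = {
    "frontal": ("Fp1", "Fpz", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8"),
    "central": ("FC5", "FC1", "FC2", "FC6", "C3", "Cz", "C4"),
    "temporal": ("T7", "T8"),
    "parietal": ("CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8"),
    "occipital": ("POz", "O1", "Oz", "O2"),
}


@dataclass(frozen=True)
class ChannelMontage:
    """An ordered set of scalp channels with 2-D layout positions."""

    names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("montage channel labels must be unique")
        if self.positions.shape != (len(self.names), 2):
            raise ValueError("positions must be (n_channels, 2)")
        if not {"Fp1", "Fp2"} <= set(self.names):
            raise ValueError(
                "montage must include frontal-polar channels Fp1/Fp2 "
                "(required for ocular templates)"
            )

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        return self.names.index(label)

    def group_indices(self, group: str) -> np.ndarray:
        """Channel indices for a named scalp region, or all channels."""
        if group == "all":
            return np.arange(self.n_channels)
        try:
            labels = CHANNEL_GROUPS[group]
        except KeyError:
            raise KeyError(
                f"unknown channel group {group!r}; "
                f"choose from {sorted(CHANNEL_GROUPS)} or 'all'"
            ) from None
        return np.array([self.index(lb) for lb in labels if lb in self.names])


def standard_montage() -> ChannelMontage:
    """The study's 32-electrode 10-10 montage."""
    names = tuple(lb for lb, _, _ in _STANDARD_32)
    pos = np.array([[x, y] for _, x, y in _STANDARD_32])
    return ChannelMontage(names=names, positions=pos)
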