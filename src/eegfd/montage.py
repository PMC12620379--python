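"""The 19-channel 10-20 scalp montage used throughout the package.

Electrode order is the clinical convention Fp1, Fp2, F7, F3, Fz, F4, F8,
T3, C3, Cz, C4, T4, T5, P3, Pz, P4, T6, O1, O2 (left/right prefrontal,
frontal, temporal, central, parietal and occipital sites).  Channel indices
are 1-based wherever they face the user, matching how EEG channels are
numbered on clinical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

STANDARD_1020_NAMES: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

# Nearest-neighbour sets on the 10-20 scalp layout (geometric adjacency).
_ADJACENCY: dict[str, tuple[str, ...]] = {
    "Fp1": ("Fp2", "F7", "F3", "Fz"),
    "Fp2": ("Fp1", "Fz", "F4", "F8"),
    "F7": ("Fp1", "F3", "T3", "C3"),
    "F3": ("Fp1", "F7", "Fz", "C3"),
    "Fz": ("Fp1", "Fp2", "F3", "F4", "Cz"),
    "F4": ("Fp2", "Fz", "F8", "C4"),
    "F8": ("Fp2", "F4", "T4", "C4"),
    "T3": ("F7", "C3", "T5"),
    "C3": ("F3", "F7", "T3", "Cz", "P3"),
    "Cz": ("Fz", "C3", "C4", "Pz"),
    "C4": ("F4", "F8", "T4", "Cz", "P4"),
    "T4": ("F8", "C4", "T6"),
    "T5": ("T3", "P3", "O1"),
    "P3": ("C3", "T5", "Pz", "O1"),
    "Pz": ("Cz", "P3", "P4", "O1", "O2"),
    "P4": ("C4", "Pz", "T6", "O2"),
    "T6": ("T4", "P4", "O2"),
    "O1": ("T5", "P3", "Pz", "O2"),
    "O2": ("O1", "Pz", "P4", "T6"),
}


@dataclass(frozen=True)
class Montage:
    """Ordered electrode labels plus their scalp adjacency.

    Parameters
    ----------
    names
        Electrode labels, in channel order.
    adjacency
        Mapping electrode -> neighbouring electrodes.  Must be symmetric
        and give every electrode at least two neighbours.
    """

    names: tuple[str, ...] = STANDARD_1020_NAMES
    adjacency: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(_ADJACENCY))

    def __post_init__(self) -> None:
        for name, nbrs in self.adjacency.items():
            if len(nbrs) < 2:
                raise ValueError(f"electrode {name!r} has fewer than 2 neighbours")
            for other in nbrs:
                if name not in self.adjacency.get(other, ()):
                    raise ValueError(f"adjacency not symmetric: {name!r}/{other!r}")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        """0-based channel index of an electrode label."""
        return self.names.index(name)

    def neighbors_of(self, channel: int) -> list[int]:
        """0-based indices of the neighbours of 0-based ``channel``."""
        name = self.names[channel]
        return [self.index(n) for n in self.adjacency[name] if n in self.names]


def standard_1020() -> Montage:
    """The default 19-channel montage."""
    return Montage()
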