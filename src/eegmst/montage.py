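"""Default montage, frequency bands, and scalp regions.

The defaults mirror a 64-channel equidistant Neuroscan recording from which
nine artifact-laden channels were dropped, leaving the 55 channels analyzed
throughout: connectivity matrices, spanning trees and regional betweenness
summaries are all indexed by these labels.
"""

from __future__ import annotations

from dataclasses import dataclass

#: The 55 analyzed scalp channels, in montage order.
CHANNELS_55: tuple[str, ...] = (
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "FZ", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "CZ", "C2", "C4", "C6", "T8",
    "CP5", "CP3", "CP1", "CPZ", "CP2", "CP4", "CP6",
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
)

#: Frontal / fronto-central channels used for the anterior regional mean (20).
ANTERIOR_CHANNELS: frozenset[str] = frozenset({
    "FP1", "FPZ", "FP2", "AF3", "AF4",
    "F7", "F5", "F3", "FZ", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
})

#: Parietal / parieto-occipital / occipital channels for the posterior mean (19).
POSTERIOR_CHANNELS: frozenset[str] = frozenset({
    "P7", "P5", "P3", "P1", "PZ", "P2", "P4", "P6", "P8",
    "PO7", "PO5", "PO3", "POZ", "PO4", "PO6", "PO8",
    "O1", "OZ", "O2",
})


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band with edges in Hz (0 < low < high)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"low={self.low}, high={self.high}"
            )

    def validate_against_fs(self, fs: float) -> None:
        if self.high >= fs / 2.0:
            raise ValueError(
                f"band {self.name!r} upper edge {self.high} Hz reaches the "
                f"Nyquist frequency {fs / 2.0} Hz"
            )


#: The six analysis bands.
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.5, 4.0),
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 7.0, 13.0),
    BandSpec("beta", 13.0, 30.0),
    BandSpec("gamma1", 30.0, 48.0),
    BandSpec("gamma2", 52.0, 70.0),
)

#: Default estimator per band: phase-based wPLI in the slow bands, where phase
#: estimates are reliable, and amplitude-envelope correlation with leakage
#: correction (AEC-c) in alpha and above.
DEFAULT_ROUTING: dict[str, str] = {
    "delta": "wPLI",
    "theta": "wPLI",
    "alpha": "AEC-c",
    "beta": "AEC-c",
    "gamma1": "AEC-c",
    "gamma2": "AEC-c",
}


def band_by_name(name: str) -> BandSpec:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(f"unknown band {name!r}; known: {[b.name for b in DEFAULT_BANDS]}")
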