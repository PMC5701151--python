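"""Frequency-band definitions used throughout the pipeline.

The clinical-EEG convention splits the spectrum into five canonical
rhythms.  All per-band analyses (connectivity, graph topology, group
statistics) iterate over these definitions.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval in Hz.

    Parameters
    ----------
    name
        Band label, e.g. ``"alpha"``.
    low, high
        Band edges in Hz; ``0 < low < high`` is required.
    """

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise ValueError(
                f"band {self.name!r}: need 0 < low < high, got "
                f"low={self.low}, high={self.high}"
            )

    @property
    def center(self) -> float:
        """Arithmetic center frequency in Hz."""
        return 0.5 * (self.low + self.high)

    @property
    def width(self) -> float:
        return self.high - self.low


#: The five canonical clinical EEG rhythms.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 48.0),
)


def band_by_name(name: str) -> BandDefinition:
    """Look up one of the default bands by its label."""
    for band in DEFAULT_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown band {name!r}; known: "
                   f"{[b.name for b in DEFAULT_BANDS]}")
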