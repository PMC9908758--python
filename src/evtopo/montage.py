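"""Electrode montages: channel names and 3-D unit-sphere positions.

Positions are head-centred unit vectors; physical scalp radius is applied
only where a forward model needs it.  The default montage is the standard
64-channel Biosemi layout (10-10 extension of the 10-20 system).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ElectrodeMontage", "default_montage"]

_MIDLINE_REQUIRED = ("Fz", "Cz", "Pz", "Oz")


@dataclass(frozen=True)
class ElectrodeMontage:
    """A set of EEG electrodes with unit-sphere positions.

    Parameters
    ----------
    labels
        Unique channel names.
    positions
        ``(n_channels, 3)`` head-centred coordinates.  They are normalised
        to the unit sphere on construction.
    """

    labels: tuple[str, ...]
    positions: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        labels = tuple(str(l) for l in self.labels)
        pos = np.asarray(self.positions, dtype=float)
        if len(set(labels)) != len(labels):
            raise ValueError("montage labels must be unique")
        if len(labels) < 2:
            raise ValueError("montage needs at least 2 channels")
        if pos.shape != (len(labels), 3):
            raise ValueError(f"positions must have shape ({len(labels)}, 3), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("montage positions must be finite")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("montage positions must be nonzero")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos / norms[:, None])

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElectrodeMontage):
            return NotImplemented
        return self.labels == other.labels and np.allclose(
            self.positions, other.positions, atol=1e-12
        )


def default_montage() -> ElectrodeMontage:
    """Standard 64-channel Biosemi montage on the unit sphere.

    Uses the idealised positions bundled with :mod:`mne`; includes the
    conventional midline sites Fz, Cz, Pz and Oz.
    """
    import mne

    std = mne.channels.make_standard_montage("biosemi64")
    pos_dict = std.get_positions()["ch_pos"]
    labels = tuple(std.ch_names)
    pos = np.array([pos_dict[ch] for ch in labels])
    # mne positions are in a head frame in metres; recentre on the best-fit
    # sphere centre before normalising so electrodes lie on one sphere.
    centre = pos.mean(axis=0)
    pos = pos - centre
    m = ElectrodeMontage(labels, pos)
    missing = [ch for ch in _MIDLINE_REQUIRED if ch not in m.labels]
    if missing:  # pragma: no cover - guards against montage-source changes
        raise RuntimeError(f"default montage is missing midline sites {missing}")
    return m
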