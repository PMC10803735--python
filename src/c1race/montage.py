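"""Electrode montage and left/right mirror map.

The default montage is a 32-channel 10/20 cap with additional low frontal
electrodes (F9/F10) used for saccade monitoring.  Lateralized trials are
analysed after reflecting the scalp across the nasion–inion axis: every
left-hemisphere electrode swaps its time series with its right homologue
while midline electrodes stay fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: 32-channel cap, in recording order.
CHANNELS_32: tuple[str, ...] = (
    "FP1", "FP2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FCz", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2", "F9", "F10",
)

#: Left/right homologue pairs of the 10/20 system for the 32-channel cap.
MIRROR_PAIRS_32: tuple[tuple[str, str], ...] = (
    ("FP1", "FP2"), ("F7", "F8"), ("F3", "F4"), ("FC5", "FC6"),
    ("FC1", "FC2"), ("T7", "T8"), ("C3", "C4"), ("TP9", "TP10"),
    ("CP5", "CP6"), ("CP1", "CP2"), ("P7", "P8"), ("P3", "P4"),
    ("O1", "O2"), ("F9", "F10"),
)

#: Midline electrodes (on the nasion–inion axis, fixed under mirroring).
MIDLINE_32: tuple[str, ...] = ("Fz", "FCz", "Cz", "Pz")


@dataclass(frozen=True)
class MontageMirrorMap:
    """Left/right channel pairing plus the midline set.

    Invariants: ``pairs`` and ``midline`` together cover every channel of the
    montage exactly once, and applying the induced permutation twice is the
    identity.
    """

    pairs: tuple[tuple[str, str], ...] = MIRROR_PAIRS_32
    midline: tuple[str, ...] = MIDLINE_32

    def channels(self) -> set[str]:
        out: set[str] = set(self.midline)
        for a, b in self.pairs:
            out.add(a)
            out.add(b)
        return out

    def validate(self, channel_names) -> None:
        """Check the map covers ``channel_names`` exactly once each."""
        seen: list[str] = list(self.midline)
        for a, b in self.pairs:
            seen.extend((a, b))
        if len(seen) != len(set(seen)):
            raise ValueError("mirror map lists a channel more than once")
        missing = set(channel_names) - set(seen)
        if missing:
            raise ValueError(f"channels missing from mirror map: {sorted(missing)}")

    def permutation(self, channel_names) -> list[int]:
        """Index permutation that swaps homologues, for ``channel_names`` order."""
        self.validate(channel_names)
        names = list(channel_names)
        index = {c: i for i, c in enumerate(names)}
        perm = list(range(len(names)))
        for a, b in self.pairs:
            if a in index and b in index:
                perm[index[a]] = index[b]
                perm[index[b]] = index[a]
            elif (a in index) != (b in index):
                raise ValueError(f"unpaired channel present: {a if a in index else b}")
        return perm


DEFAULT_MIRROR_MAP = MontageMirrorMap()
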