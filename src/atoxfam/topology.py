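"""Transmembrane topology screening by Kyte–Doolittle hydropathy.

A GPCR has seven transmembrane (TM) helices, an extracellular N-terminus and
an intracellular C-terminus, with the helices linked by three extracellular
and three intracellular loops.  This module calls TM segments from a
sliding-window hydropathy profile and, for sequences with exactly seven
calls, derives the alternating structural region map

    N-terminal, TMI, IC Loop 1, TMII, EC Loop 1, TMIII, IC Loop 2,
    TMIV, EC Loop 2, TMV, IC Loop 3, TMVI, EC Loop 3, TMVII, C-terminal

(orientation fixed by the family: N-terminus extracellular, so the loop
after TMI is intracellular).  All coordinates are 0-based, half-open.

The defaults (window 19, threshold 1.6, minimum length 15, merge gap 3) are
the classic hydropathy-plot settings for membrane-helix detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import ProteinSequence

#: Kyte–Doolittle hydropathy scale; the unknown residue X is neutral (0).
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

TM_LABELS = ("TMI", "TMII", "TMIII", "TMIV", "TMV", "TMVI", "TMVII")
N_TERMINAL = "N-terminal"
C_TERMINAL = "C-terminal"


class TopologyError(ValueError):
    """Raised for invalid topology inputs."""


@dataclass(frozen=True)
class TopologyParams:
    window: int = 19
    threshold: float = 1.6
    min_len: int = 15
    merge_gap: int = 3


@dataclass
class HydropathyProfile:
    """Per-residue windowed mean hydropathy (dimensionless)."""

    values: np.ndarray
    window: int


@dataclass
class Topology:
    """Seven TM segments and the derived region map of one sequence."""

    tm_segments: list[tuple[int, int]]
    seq_len: int
    _labels: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        segs = self.tm_segments
        if len(segs) != 7:
            raise TopologyError(f"expected 7 TM segments, got {len(segs)}")
        prev_end = 0
        for k, (a, b) in enumerate(segs):
            if not (0 <= a < b <= self.seq_len):
                raise TopologyError(f"segment {k} out of bounds: ({a}, {b})")
            if a < prev_end:
                raise TopologyError(f"segment {k} overlaps its predecessor")
            prev_end = b
        if not self._labels:
            self._labels = self._build_labels()

    def _build_labels(self) -> list[str]:
        labels = [N_TERMINAL] * self.seq_len
        for k, (a, b) in enumerate(self.tm_segments):
            for i in range(a, b):
                labels[i] = TM_LABELS[k]
        # loops alternate IC/EC starting intracellular after TMI
        for k in range(6):
            a = self.tm_segments[k][1]
            b = self.tm_segments[k + 1][0]
            name = f"IC Loop {k // 2 + 1}" if k % 2 == 0 else f"EC Loop {k // 2 + 1}"
            for i in range(a, b):
                labels[i] = name
        for i in range(self.tm_segments[6][1], self.seq_len):
            labels[i] = C_TERMINAL
        return labels

    def region(self, index: int) -> str:
        """Structural region label of residue *index*."""
        if not 0 <= index < self.seq_len:
            raise TopologyError(f"residue index {index} out of range")
        return self._labels[index]

    def span_regions(self, start: int, end: int) -> list[str]:
        """Distinct region labels covered by [start, end), in order."""
        labels: list[str] = []
        for i in range(start, end):
            lab = self.region(i)
            if not labels or labels[-1] != lab:
                labels.append(lab)
        return labels

    def loop(self, kind: str, number: int) -> tuple[int, int]:
        """Interval of ``IC``/``EC`` loop *number* (1-based)."""
        k = (number - 1) * 2 + (0 if kind == "IC" else 1)
        return self.tm_segments[k][1], self.tm_segments[k + 1][0]


def hydropathy_profile(seq: ProteinSequence, window: int = 19) -> HydropathyProfile:
    """Windowed mean Kyte–Doolittle hydropathy, one value per residue.

    Edge windows are truncated (profile length equals sequence length).
    """
    if window < 5 or window % 2 == 0:
        raise TopologyError("window must be an odd integer >= 5")
    n = len(seq.residues)
    if n < window:
        raise TopologyError(
            f"sequence {seq.id!r} shorter ({n}) than window ({window})"
        )
    raw = np.array([KYTE_DOOLITTLE[c] for c in seq.residues])
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(raw)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    values = (csum[hi] - csum[lo]) / (hi - lo)
    return HydropathyProfile(values=values, window=window)


def find_tm_segments(
    profile: HydropathyProfile,
    threshold: float = 1.6,
    min_len: int = 15,
    merge_gap: int = 3,
) -> list[tuple[int, int]]:
    """Call TM segments as above-threshold runs of the hydropathy profile.

    Maximal runs with value >= threshold are found; runs separated by at
    most *merge_gap* positions are merged; merged runs shorter than
    *min_len* are discarded.
    """
    above = profile.values >= threshold
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    return [(a, b) for a, b in merged if b - a >= min_len]


def assign_regions(segments: list[tuple[int, int]], seq_len: int) -> Topology:
    """Build the alternating region map from exactly seven TM segments."""
    return Topology(tm_segments=list(segments), seq_len=seq_len)


def screen_seven_tm(
    seq: ProteinSequence, params: TopologyParams = TopologyParams()
) -> tuple[bool, Topology | None]:
    """Pass iff hydropathy calling yields exactly seven TM segments."""
    profile = hydropathy_profile(seq, params.window)
    segments = find_tm_segments(
        profile, params.threshold, params.min_len, params.merge_gap
    )
    if len(segments) != 7:
        return False, None
    return True, assign_regions(segments, len(seq.residues))
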