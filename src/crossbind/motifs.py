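"""IUPAC consensus-motif scanning, central enrichment, and pairwise spacing profiles.

The motifs of interest are short degenerate consensi for transcription-factor
core binding sites, e.g. SOX2 = ``ACAAW`` (ACAAA/ACAAT), ZEB1 = ``CWCACCTG``,
OTX1 = ``TAATCCCC``, FOXA1 = ``GTAAAYA``. Scanning reports every occurrence on
both strands (overlapping matches included); central enrichment asks whether
the best hit per peak concentrates near the peak center more than a uniform
placement would allow (a fixed-window binomial test); spacing profiles collect
signed start-to-start distances between two motifs co-occurring in one peak.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "IUPAC_CODES",
    "MotifPattern",
    "MotifHit",
    "SpacingProfile",
    "CentralEnrichmentResult",
    "parse_iupac",
    "reverse_complement",
    "scan_sequence",
    "scan_peaks",
    "central_enrichment",
    "spacing_profile",
    "CORE_CONSENSI",
]

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: Core consensus sites used throughout: SOX2 ACAAA/T, ZEB1 CA/TCACCTG,
#: OTX1 TAATCCCC, FOXA1 GTAAAC/TA.
CORE_CONSENSI: dict[str, str] = {
    "SOX2": "ACAAW",
    "ZEB1": "CWCACCTG",
    "OTX1": "TAATCCCC",
    "FOXA1": "GTAAAYA",
}


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/IUPAC string (degenerate codes map to their complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """A named IUPAC consensus with a compiled overlapping-match regex per strand.

    An ``N`` in the *scanned sequence* never matches anything, including a
    pattern ``N`` (unknown bases cannot support a motif call); pattern codes
    therefore compile to explicit [ACGT...] classes.
    """

    name: str
    iupac: str
    _fwd: re.Pattern = field(repr=False, compare=False, default=None)
    _rev: re.Pattern = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if not self.iupac:
            raise ValueError("IUPAC pattern must be non-empty")
        for pos, ch in enumerate(self.iupac):
            if ch.upper() not in IUPAC_CODES:
                raise ValueError(
                    f"invalid IUPAC character {ch!r} at position {pos} in {self.iupac!r}"
                )
        object.__setattr__(self, "iupac", self.iupac.upper())
        object.__setattr__(self, "_fwd", _compile(self.iupac))
        object.__setattr__(self, "_rev", _compile(reverse_complement(self.iupac)))

    def __len__(self) -> int:
        return len(self.iupac)

    def matches(self, word: str) -> bool:
        """Exact match of a word of the same length against the + strand pattern."""
        return len(word) == len(self.iupac) and self._fwd.match(word.upper()) is not None


def _compile(iupac: str) -> re.Pattern:
    # lookahead so overlapping occurrences are all found
    body = "".join(
        ch if len(IUPAC_CODES[ch]) == 1 else "[" + "".join(sorted(IUPAC_CODES[ch])) + "]"
        for ch in iupac
    )
    return re.compile(f"(?=({body}))")


def parse_iupac(pattern: str, name: str = "") -> MotifPattern:
    """Validate and compile an IUPAC consensus string into a matcher."""
    return MotifPattern(name or pattern, pattern)


@dataclass(frozen=True, order=True)
class MotifHit:
    """One motif occurrence: offset of the match span start (+ strand coords) within its peak."""

    peak_id: str
    offset: int
    strand: str
    pattern: str


def scan_sequence(
    sequence: str,
    pattern: MotifPattern,
    both_strands: bool = True,
    peak_id: str = "",
) -> list[MotifHit]:
    """All occurrences of `pattern` in `sequence`.

    Minus-strand occurrences are found by scanning with the reverse-complement
    pattern and reported with strand '-' and the + strand coordinate of the
    match span start. Overlapping matches are all reported.
    """
    seq = sequence.upper()
    hits = [
        MotifHit(peak_id, m.start(), "+", pattern.name)
        for m in pattern._fwd.finditer(seq)
    ]
    if both_strands:
        hits += [
            MotifHit(peak_id, m.start(), "-", pattern.name)
            for m in pattern._rev.finditer(seq)
        ]
    return sorted(hits)


def scan_peaks(
    peak_sequences: Mapping[str, str],
    pattern: MotifPattern,
    both_strands: bool = True,
) -> dict[str, list[MotifHit]]:
    """Scan each peak sequence; returns peak_id -> hits (peaks with no hit omitted)."""
    out = {}
    for peak_id, seq in peak_sequences.items():
        hits = scan_sequence(seq, pattern, both_strands, peak_id=peak_id)
        if hits:
            out[peak_id] = hits
    return out


@dataclass(frozen=True)
class CentralEnrichmentResult:
    """Binomial test of best-hit concentration in a central window."""

    n_peaks_with_hit: int
    n_central: int
    fraction_central: float
    expected_fraction: float
    p_value: float
    undefined: bool = False

    def to_dict(self) -> dict:
        return {
            "n_peaks_with_hit": self.n_peaks_with_hit,
            "n_central": self.n_central,
            "fraction_central": self.fraction_central,
            "expected_fraction": self.expected_fraction,
            "p_value": self.p_value,
            "undefined": self.undefined,
        }


def central_enrichment(
    hits_per_peak: Mapping[str, Sequence[MotifHit]],
    peak_width: int,
    central_window: int = 100,
    pattern_length: Optional[int] = None,
) -> CentralEnrichmentResult:
    """Central enrichment of a motif within fixed-width peaks.

    Per peak the *best* hit is the one whose match center lies nearest the
    peak center; the statistic is the number of best hits whose center falls
    inside the central window, tested against an upper-tail binomial with
    n = peaks with >=1 hit and p0 = central_window / (peak_width - L + 1),
    the uniform-placement probability over the L-length match positions.
    """
    if central_window >= peak_width:
        raise ValueError("central_window must be smaller than peak_width")
    if pattern_length is None:
        raise ValueError("pattern_length is required (IUPAC length of the scanned motif)")
    peaks_with_hit = [p for p, hits in hits_per_peak.items() if len(hits) > 0]
    if not peaks_with_hit:
        return CentralEnrichmentResult(0, 0, float("nan"), float("nan"), float("nan"), True)
    L = pattern_length
    half = L // 2
    center = peak_width // 2
    lo, hi = center - central_window // 2, center - central_window // 2 + central_window
    n_central = 0
    for p in peaks_with_hit:
        centers = np.array([h.offset + half for h in hits_per_peak[p]])
        best = centers[np.argmin(np.abs(centers - center))]
        if lo <= best < hi:
            n_central += 1
    n = len(peaks_with_hit)
    p0 = central_window / (peak_width - L + 1)
    p_value = float(stats.binom.sf(n_central - 1, n, min(p0, 1.0)))
    return CentralEnrichmentResult(n, n_central, n_central / n, p0, p_value)


@dataclass(frozen=True)
class SpacingProfile:
    """Signed spacing histogram between two motifs with 5-bp rolling mean, median, mode.

    Spacing is start(B) - start(A) in + strand coordinates for every (A, B)
    hit pair co-occurring in one peak; the rolling mean is centered, window 5,
    truncated at the support edges. Mode ties break to the smallest spacing.
    """

    histogram: dict[int, int]
    rolling: dict[int, float]
    median_spacing: Optional[float]
    mode_spacing: Optional[int]
    n_pairs: int
    empty: bool

    def to_dataframe(self) -> pd.DataFrame:
        spacings = sorted(self.histogram)
        return pd.DataFrame(
            {
                "spacing": spacings,
                "count": [self.histogram[s] for s in spacings],
                "rolling_mean": [self.rolling[s] for s in spacings],
            }
        )


def spacing_profile(
    hits_a: Mapping[str, Sequence[MotifHit]],
    hits_b: Mapping[str, Sequence[MotifHit]],
    rolling_window: int = 5,
    convention: str = "start",
    len_a: int = 0,
    len_b: int = 0,
    orient_by_a_strand: bool = False,
) -> SpacingProfile:
    """Pairwise spacing profile between motif A and motif B hits within shared peaks.

    Every (A, B) pair in a peak containing >=1 hit of each contributes one
    signed spacing; peaks missing either motif contribute nothing. An empty
    profile (no co-occurring peaks) is returned flagged, not raised.

    Spacing is measured start-to-start on the + strand axis by default;
    convention="center" measures match-center to match-center (pass the
    pattern lengths). With orient_by_a_strand the sign is flipped for pairs
    whose A hit lies on the - strand, so spacings read in the A motif's own
    orientation.
    """
    if convention not in ("start", "center"):
        raise ValueError("convention must be 'start' or 'center'")
    shift_a = len_a // 2 if convention == "center" else 0
    shift_b = len_b // 2 if convention == "center" else 0
    spacings: list[int] = []
    for peak_id, a_hits in hits_a.items():
        b_hits = hits_b.get(peak_id)
        if not b_hits:
            continue
        for ha in a_hits:
            sign = -1 if (orient_by_a_strand and ha.strand == "-") else 1
            for hb in b_hits:
                spacings.append(sign * ((hb.offset + shift_b) - (ha.offset + shift_a)))
    if not spacings:
        return SpacingProfile({}, {}, None, None, 0, True)
    values, counts = np.unique(np.array(spacings), return_counts=True)
    support = np.arange(values.min(), values.max() + 1)
    dense = np.zeros(support.shape[0])
    dense[values - values.min()] = counts
    half = rolling_window // 2
    rolling = {}
    for i, s in enumerate(support):
        lo, hi = max(0, i - half), min(len(support), i + half + 1)
        rolling[int(s)] = float(dense[lo:hi].mean())
    histogram = {int(v): int(c) for v, c in zip(values, counts)}
    rolling = {s: rolling[s] for s in histogram}  # same support as histogram
    median = float(np.median(spacings))
    mode = int(values[np.argmax(counts)])  # np.argmax takes first max -> smallest spacing
    return SpacingProfile(histogram, rolling, median, mode, len(spacings), False)
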