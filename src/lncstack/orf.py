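"""Open-reading-frame enumeration on the forward strand.

An ORF starts at an ATG and runs in-frame to the first stop codon
(TAA/TAG/TGA), which is *included* in its length; when no in-frame stop
exists the ORF runs to the last complete codon and is flagged
``has_stop=False``. Inputs are transcripts (mRNA sense), so only the
three forward frames are scanned.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass(frozen=True)
class OrfAnnotation:
    """One candidate ORF: 0-based half-open [start, end), end-start % 3 == 0."""

    frame: int
    start: int
    end: int
    has_stop: bool

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OrfProfile:
    """Per-transcript ORF summary used by several feature blocks."""

    length: int
    first_orf: Optional[OrfAnnotation] = None
    longest_orf: Optional[OrfAnnotation] = None
    per_frame_longest: list = field(default_factory=lambda: [None, None, None])

    @property
    def per_frame_longest_len(self) -> tuple[int, int, int]:
        return tuple(0 if o is None else o.length for o in self.per_frame_longest)

    @property
    def utr5(self) -> tuple[int, int]:
        """5' untranslated interval [0, longest_orf.start); empty when no ORF."""
        if self.longest_orf is None:
            return (0, 0)
        return (0, self.longest_orf.start)

    @property
    def utr3(self) -> tuple[int, int]:
        """3' untranslated interval [longest_orf.end, L); empty when no ORF."""
        if self.longest_orf is None:
            return (0, 0)
        return (self.longest_orf.end, self.length)


def find_orfs(seq: str) -> list[OrfAnnotation]:
    """Enumerate every ATG-initiated ORF in the three forward frames.

    Nested in-frame ATGs each yield their own candidate (sharing the
    downstream stop).
    """
    L = len(seq)
    orfs: list[OrfAnnotation] = []
    for frame in range(3):
        starts = []
        stops = []
        for i in range(frame, L - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG":
                starts.append(i)
            elif codon in STOP_CODONS:
                stops.append(i)
        last_codon_end = frame + 3 * ((L - frame) // 3)
        for s in starts:
            j = bisect_left(stops, s + 3)
            if j < len(stops):
                orfs.append(OrfAnnotation(frame, s, stops[j] + 3, True))
            else:
                orfs.append(OrfAnnotation(frame, s, last_codon_end, False))
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def orf_profile(seq: str) -> OrfProfile:
    """Summarize a transcript's ORFs with deterministic tie-breaking.

    First ORF: smallest start (then prefer a stop-terminated, then a
    longer candidate). Longest ORF: maximum length (ties: smallest
    start, then stop-terminated).
    """
    orfs = find_orfs(seq)
    profile = OrfProfile(length=len(seq))
    if not orfs:
        return profile
    profile.first_orf = min(
        orfs, key=lambda o: (o.start, not o.has_stop, -o.length)
    )
    profile.longest_orf = min(
        orfs, key=lambda o: (-o.length, o.start, not o.has_stop)
    )
    for f in range(3):
        in_frame = [o for o in orfs if o.frame == f]
        if in_frame:
            profile.per_frame_longest[f] = min(
                in_frame, key=lambda o: (-o.length, o.start, not o.has_stop)
            )
    return profile


def orf_scalar_block(profile: OrfProfile, length: Optional[int] = None) -> dict:
    """The six ORF scalars: lengths, coverages, integrity, frame score.

    Integrity is +1 iff the longest ORF is stop-terminated (so it has
    both a canonical start and stop), else -1. The frame score is the
    population variance of the three per-frame longest ORF lengths.
    """
    L = profile.length if length is None else length
    first = profile.first_orf
    longest = profile.longest_orf
    first_len = 0 if first is None else first.length
    longest_len = 0 if longest is None else longest.length
    integrity = 1 if (longest is not None and longest.has_stop) else -1
    frame_score = float(np.var(profile.per_frame_longest_len))
    return {
        "first_ORF_length": float(first_len),
        "longest_ORF_length": float(longest_len),
        "longest_ORF_coverage": longest_len / L if L else 0.0,
        "first_ORF_coverage": first_len / L if L else 0.0,
        "ORF_integrity": float(integrity),
        "ORF_frame_score": frame_score,
    }


def longest_orf_seq(seq: str, profile: Optional[OrfProfile] = None) -> str:
    """Subsequence of the longest ORF ('' when the transcript has none)."""
    if profile is None:
        profile = orf_profile(seq)
    if profile.longest_orf is None:
        return ""
    return seq[profile.longest_orf.start : profile.longest_orf.end]


def write_orf_bed(seq_id: str, orfs: list[OrfAnnotation], path) -> None:
    """Dump ORF coordinates as BED-like TSV (0-based, half-open)."""
    with open(path, "a", encoding="utf-8") as fh:
        for o in orfs:
            fh.write(
                f"{seq_id}\t{o.start}\t{o.end}\tframe{o.frame}"
                f"\t{int(o.has_stop)}\t+\n"
            )
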