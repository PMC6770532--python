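"""Coding-sequence (CDS) feature block.

The most-likely CDS is taken to be the longest ORF, scored by a
transparent deterministic function of its length, completeness and
hexamer composition:

    score = len * (1 + max(0, hexamer_score)) + 50*[has stop] + 50*[starts ATG]

which is monotone in ORF length and in coding-like composition. A
reader for externally computed CDS calls (UCSC txCdsPredict
tab-separated output) is provided so real calls can override the
built-in scoring when available.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hexamer import HexamerTable, hexamer_score
from .orf import OrfProfile, longest_orf_seq


@dataclass(frozen=True)
class CdsCall:
    """A CDS interval call: 0-based half-open [start, end) and a score."""

    start: int
    end: int
    score: float

    def __post_init__(self):
        if not (0 <= self.start <= self.end):
            raise ValueError("invalid CDS interval")
        if self.score < 0:
            raise ValueError("CDS score must be nonnegative")


def cds_block(seq: str, profile: OrfProfile, table: HexamerTable) -> dict:
    """CDS length, percentage of the transcript, and score (above)."""
    L = len(seq)
    orf = profile.longest_orf
    if orf is None or L == 0:
        return {"CDS_length": 0.0, "CDS_percentage": 0.0, "CDS_score": 0.0}
    cds_len = orf.length
    hx = hexamer_score(longest_orf_seq(seq, profile), table)
    score = cds_len * (1.0 + max(0.0, hx))
    if orf.has_stop:
        score += 50.0
    if seq[orf.start : orf.start + 3] == "ATG":
        score += 50.0
    return {
        "CDS_length": float(cds_len),
        "CDS_percentage": cds_len / L,
        "CDS_score": score,
    }


def cds_block_from_call(call: CdsCall, length: int) -> dict:
    """CDS features from an external call (overrides the built-in scoring)."""
    cds_len = call.end - call.start
    return {
        "CDS_length": float(cds_len),
        "CDS_percentage": cds_len / length if length else 0.0,
        "CDS_score": call.score,
    }


def read_txcdspredict(path) -> dict[str, CdsCall]:
    """Read UCSC txCdsPredict tab-separated output.

    Expects at least the columns name, start, end, score (columns 1-4);
    extra columns are ignored.
    """
    calls: dict[str, CdsCall] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            name, start, end, score = fields[0], fields[1], fields[2], fields[3]
            calls[name] = CdsCall(int(start), int(end), float(score))
    return calls
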