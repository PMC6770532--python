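"""In-frame hexamer usage tables and the hexamer log-ratio score.

The table holds smoothed in-frame (step 3) hexamer frequencies from a
coding and a noncoding training set; a transcript's longest ORF is then
scored by the mean log coding/noncoding frequency ratio of its in-frame
hexamers. Positive scores are coding-like, negative noncoding-like.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .orf import longest_orf_seq

BASES = "ACGT"
HEXAMERS = tuple(
    "".join(p) for p in itertools.product(BASES, repeat=6)
)
_HEX_INDEX = {h: i for i, h in enumerate(HEXAMERS)}


@dataclass
class HexamerTable:
    """Smoothed in-frame hexamer frequencies for the two classes."""

    coding_freq: np.ndarray
    noncoding_freq: np.ndarray
    pseudocount: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for arr in (self.coding_freq, self.noncoding_freq):
            if arr.shape != (4096,):
                raise ValueError("hexamer frequency arrays must have 4096 cells")
            if not np.all(arr > 0):
                raise ValueError("hexamer frequencies must be strictly positive")

    @classmethod
    def neutral(cls) -> "HexamerTable":
        """Uninformative table (all log ratios are 0); useful as a
        placeholder before training."""
        u = np.full(4096, 1.0 / 4096)
        return cls(coding_freq=u, noncoding_freq=u.copy(), pseudocount=1.0)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# pseudocount={self.pseudocount!r}\n")
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}={v}\n")
            fh.write("hexamer\tcoding_freq\tnoncoding_freq\n")
            for h, c, n in zip(HEXAMERS, self.coding_freq, self.noncoding_freq):
                fh.write(f"{h}\t{c:.12g}\t{n:.12g}\n")

    @classmethod
    def from_tsv(cls, path) -> "HexamerTable":
        coding = np.zeros(4096)
        noncoding = np.zeros(4096)
        pseudocount = 1.0
        meta: dict = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    if key == "pseudocount":
                        pseudocount = float(val)
                    elif key:
                        meta[key] = val
                    continue
                if line.startswith("hexamer\t") or not line:
                    continue
                h, c, n = line.split("\t")
                coding[_HEX_INDEX[h]] = float(c)
                noncoding[_HEX_INDEX[h]] = float(n)
        return cls(coding, noncoding, pseudocount=pseudocount, meta=meta)


def _inframe_hexamer_counts(seqs: Iterable[str]) -> np.ndarray:
    counts = np.zeros(4096)
    for seq in seqs:
        for i in range(0, len(seq) - 5, 3):
            idx = _HEX_INDEX.get(seq[i : i + 6])
            if idx is not None:
                counts[idx] += 1
    return counts


def train_hexamer_table(
    coding: Sequence[str],
    noncoding: Sequence[str],
    pseudocount: float = 1.0,
) -> HexamerTable:
    """Count in-frame hexamers of the coding sequences' longest ORFs and
    of the raw noncoding sequences, smooth and normalize."""
    if not coding or not noncoding:
        raise ValueError("both training collections must be non-empty")
    coding_counts = _inframe_hexamer_counts(
        longest_orf_seq(s) for s in coding
    )
    noncoding_counts = _inframe_hexamer_counts(noncoding)
    coding_freq = (coding_counts + pseudocount) / (
        coding_counts.sum() + 4096 * pseudocount
    )
    noncoding_freq = (noncoding_counts + pseudocount) / (
        noncoding_counts.sum() + 4096 * pseudocount
    )
    return HexamerTable(
        coding_freq,
        noncoding_freq,
        pseudocount=pseudocount,
        meta={"n_coding": len(coding), "n_noncoding": len(noncoding)},
    )


def hexamer_score(orf_seq: str, table: HexamerTable) -> float:
    """Mean log(coding/noncoding) frequency ratio over the in-frame
    hexamers of the (longest-ORF) sequence; 0 when it has none."""
    total = 0.0
    m = 0
    for i in range(0, len(orf_seq) - 5, 3):
        idx = _HEX_INDEX.get(orf_seq[i : i + 6])
        if idx is None:
            continue
        total += math.log(table.coding_freq[idx] / table.noncoding_freq[idx])
        m += 1
    return total / m if m else 0.0
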