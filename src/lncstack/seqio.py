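"""Reading, validating and filtering transcript sequences.

Transcripts are handled as mRNA-sense DNA strings over {A, C, G, T}.
RNA input (U) is folded to DNA; IUPAC ambiguity codes are tolerated up
to a fraction of the sequence and kept as the sentinel ``N`` so that
downstream k-window statistics can skip them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: fraction of non-ACGT characters above which a sequence is rejected
MAX_AMBIGUOUS_FRACTION = 0.10

#: default length window: lncRNAs are defined as >200 nt and the model
#: is trained on transcripts under 3000 nt
DEFAULT_MIN_LEN = 200
DEFAULT_MAX_LEN = 3000

_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class Transcript:
    """A single validated transcript sequence."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.seq)


def normalize_sequence(raw: str) -> str:
    """Uppercase, fold U->T and map residual ambiguity codes to N.

    Raises ``ValueError`` for empty input or when more than
    ``MAX_AMBIGUOUS_FRACTION`` of the characters are outside {A,C,G,T}
    after case/U folding.
    """
    if not raw:
        raise ValueError("empty sequence")
    s = raw.upper().replace("U", "T")
    n_bad = sum(1 for c in s if c not in _VALID)
    if n_bad / len(s) > MAX_AMBIGUOUS_FRACTION:
        raise ValueError(
            f"too ambiguous: {n_bad}/{len(s)} characters outside ACGT"
        )
    if n_bad:
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_fasta(path, reject_log=None) -> list[Transcript]:
    """Read a FASTA file into a list of :class:`Transcript`.

    Records failing :func:`normalize_sequence` are dropped; each
    rejection is logged and, when *reject_log* is given, appended to
    that plain-text file as ``id<TAB>reason`` lines. Record order is
    preserved. Raises ``ValueError`` when no record can be parsed.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    rejections: list[tuple[str, str]] = []
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        name = rec.id or "<unnamed>"
        try:
            seq = normalize_sequence(str(rec.seq))
        except ValueError as exc:
            rejections.append((name, str(exc)))
            logger.warning("rejected record %s: %s", name, exc)
            continue
        transcripts.append(Transcript(id=name, seq=seq))
    if n_records == 0:
        raise ValueError(f"no parseable FASTA records in {path}")
    if reject_log is not None and rejections:
        with open(reject_log, "a", encoding="utf-8") as fh:
            for name, reason in rejections:
                fh.write(f"{name}\t{reason}\n")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path) -> None:
    """Write transcripts to FASTA (one record per transcript)."""
    records = [
        SeqRecord(Seq(t.seq), id=t.id, description="") for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def filter_by_length(
    transcripts: Sequence[Transcript],
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[Transcript]:
    """Keep transcripts with ``min_len < length < max_len``.

    Both bounds are strict: a lncRNA must *exceed* 200 nt, and the
    model's training window stays *under* 3000 nt.
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    return [t for t in transcripts if min_len < t.length < max_len]
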