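"""The canonical 260-dimension feature vector and its table format.

Six feature categories are concatenated in a fixed order:

    codon (9) | ORF (22) | GC (7) | CDS (3) | transcript (213) | structure (6)

Names are stable across runs and machines; the feature table is a TSV
with ``id`` and ``label`` bookkeeping columns ahead of the 260 features.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from . import cdsfeat, seqfeat
from .hexamer import HexamerTable, hexamer_score, train_hexamer_table
from .orf import orf_profile, orf_scalar_block, longest_orf_seq
from .pepfeat import peptide_block
from .seqio import Transcript

CATEGORIES = ("codon", "ORF", "GC", "CDS", "transcript", "structure")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names and their category boundaries."""

    names: tuple
    category_sizes: dict

    @property
    def n_features(self) -> int:
        return len(self.names)

    @property
    def schema_hash(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class FeatureVector:
    """One transcript's 260 feature values, aligned to the schema."""

    transcript_id: str
    values: np.ndarray
    label: Optional[int] = None  # 1 = lncRNA, 0 = coding


def _schema_names() -> tuple[list[str], dict]:
    codon = [
        "stop_codon_count",
        "stop_codon_frequency",
        "stop_codon_frame_score",
        "stop_codon_frequency_frame_score",
        "A_pos_fickett",
        "C_pos_fickett",
        "G_pos_fickett",
        "T_pos_fickett",
        "fickett_score",
    ]
    orf_names = [
        "first_ORF_length",
        "longest_ORF_length",
        "longest_ORF_coverage",
        "first_ORF_coverage",
        "ORF_integrity",
        "ORF_frame_score",
    ] + [f"EDP_ORF_k_mer_{a}{b}" for a in "ACGT" for b in "ACGT"]
    # whole-transcript GC content is "GC_content" (the bare mer string
    # "GC" names the dinucleotide frequency in the k-mer block)
    gc = ["GC_content", "GC1", "GC2", "GC3", "GC1_frame_score",
          "UTR5_GC", "UTR3_GC"]
    cds = ["CDS_length", "CDS_percentage", "CDS_score"]
    transcript = (
        ["transcript_length"]
        + seqfeat.kmer_names()
        + [f"{b}_dis_{f}" for b in "ACGT" for f in (0, 25, 50, 75, 100)]
        + ["Hexamer_score", "SNR", "UTR5_coverage", "UTR3_coverage"]
        + [f"EDP_fea_{aa}" for aa in seqfeat.AMINO_ACIDS]
    )
    structure = ["Mw", "pI", "pI_Mw", "pI_Mw_frame_score", "Gravy",
                 "Instability_index"]
    blocks = {
        "codon": codon,
        "ORF": orf_names,
        "GC": gc,
        "CDS": cds,
        "transcript": transcript,
        "structure": structure,
    }
    names = [n for cat in CATEGORIES for n in blocks[cat]]
    sizes = {cat: len(blocks[cat]) for cat in CATEGORIES}
    return names, sizes


_NAMES, _SIZES = _schema_names()
_SCHEMA = FeatureSchema(names=tuple(_NAMES), category_sizes=_SIZES)


def feature_schema() -> FeatureSchema:
    """The canonical 260-name schema (a shared immutable instance)."""
    return _SCHEMA


def extract_features(
    t: Transcript,
    table: HexamerTable,
    label: Optional[int] = None,
) -> FeatureVector:
    """Compute all feature blocks for one transcript in schema order."""
    seq = t.seq
    profile = orf_profile(seq)
    orf_seq = longest_orf_seq(seq, profile)
    vals: dict[str, float] = {}
    vals.update(seqfeat.stop_codon_block(seq))
    vals.update(seqfeat.position_frequency_block(seq))
    vals["fickett_score"] = seqfeat.fickett_score(seq)
    vals.update(orf_scalar_block(profile))
    vals.update(seqfeat.edp_orf_block(orf_seq))
    vals.update(seqfeat.gc_block(seq, profile))
    vals.update(cdsfeat.cds_block(seq, profile, table))
    vals["transcript_length"] = float(len(seq))
    vals.update(seqfeat.kmer_block(seq, orf_seq))
    vals.update(seqfeat.ctd_distribution(seq))
    vals["Hexamer_score"] = hexamer_score(orf_seq, table)
    vals["SNR"] = seqfeat.snr(seq)
    vals.update(seqfeat.utr_coverage(profile))
    vals.update(seqfeat.edp_transcript_block(seq))
    vals.update(peptide_block(seq, profile))
    values = np.array([vals[name] for name in _SCHEMA.names], dtype=float)
    if not np.all(np.isfinite(values)):
        bad = [n for n, v in zip(_SCHEMA.names, values) if not np.isfinite(v)]
        raise ValueError(f"non-finite feature values for {t.id}: {bad}")
    return FeatureVector(transcript_id=t.id, values=values, label=label)


def extract_matrix(
    transcripts: Sequence[Transcript],
    table: HexamerTable,
    labels=None,
) -> pd.DataFrame:
    """Feature table for many transcripts: id/label columns + 260 features."""
    if labels is None:
        labels = [None] * len(transcripts)
    rows = [extract_features(t, table, lab) for t, lab in zip(transcripts, labels)]
    df = pd.DataFrame(
        [r.values for r in rows], columns=list(_SCHEMA.names)
    )
    df.insert(0, "id", [r.transcript_id for r in rows])
    df.insert(1, "label", [r.label for r in rows])
    return df


def write_feature_table(df: pd.DataFrame, path, meta: Optional[dict] = None):
    """Write a feature table as TSV ('.' decimal, 12 significant digits).

    Optional *meta* key/value pairs (seed, config hash, ...) are stored
    as leading ``#`` comment lines.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in sorted((meta or {}).items()):
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table, validating the column layout against the
    canonical schema; raises naming the first offending column."""
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["id", "label"] + list(_SCHEMA.names)
    got = list(df.columns)
    if len(got) != len(expected):
        raise ValueError(
            f"schema mismatch: expected {len(expected)} columns, got {len(got)}"
        )
    for e, g in zip(expected, got):
        if e != g:
            raise ValueError(f"schema mismatch at column {g!r} (expected {e!r})")
    return df


class TranscriptFeatureExtractor(TransformerMixin, BaseEstimator):
    """Transform transcripts into the 260-dimension feature matrix.

    ``fit(X, y)`` trains the in-frame hexamer table from the labelled
    sequences (y: 1 = lncRNA/noncoding, 0 = coding) unless a pre-trained
    ``hexamer_table`` was supplied. ``transform(X)`` accepts an iterable
    of :class:`~lncstack.seqio.Transcript` or raw sequence strings and
    returns an ``(n, 260)`` array.
    """

    def __init__(self, hexamer_table: Optional[HexamerTable] = None,
                 pseudocount: float = 1.0):
        self.hexamer_table = hexamer_table
        self.pseudocount = pseudocount

    @staticmethod
    def _as_transcripts(X) -> list[Transcript]:
        out = []
        for i, x in enumerate(X):
            if isinstance(x, Transcript):
                out.append(x)
            else:
                out.append(Transcript(id=f"seq{i}", seq=str(x)))
        return out

    def fit(self, X, y=None):
        if self.hexamer_table is not None:
            self.hexamer_table_ = self.hexamer_table
        else:
            if y is None:
                raise ValueError(
                    "labels are required to train the hexamer table"
                )
            ts = self._as_transcripts(X)
            y = np.asarray(y)
            coding = [t.seq for t, lab in zip(ts, y) if lab == 0]
            noncoding = [t.seq for t, lab in zip(ts, y) if lab == 1]
            self.hexamer_table_ = train_hexamer_table(
                coding, noncoding, pseudocount=self.pseudocount
            )
        self.n_features_out_ = _SCHEMA.n_features
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "hexamer_table_")
        ts = self._as_transcripts(X)
        return np.vstack(
            [extract_features(t, self.hexamer_table_).values for t in ts]
        ) if ts else np.empty((0, _SCHEMA.n_features))

    def get_feature_names_out(self, input_features=None):
        return np.asarray(_SCHEMA.names, dtype=object)
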