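"""Codon-, GC- and transcript-level sequence feature blocks.

All blocks return ``{feature_name: float}`` dictionaries whose keys are
the canonical schema names (see :mod:`lncstack.assemble`). Degenerate
inputs (no ORF, too-short sequence, absent base) map to zeros so that
the assembled vector is always finite. Windows containing the ambiguity
sentinel ``N`` are skipped and excluded from denominators.
"""

from __future__ import annotations

import itertools
import math
from typing import Optional

import numpy as np

from .orf import OrfProfile, longest_orf_seq
from .pepfeat import translate

BASES = "ACGT"

# ---------------------------------------------------------------------------
# Fickett TESTCODE lookup tables (Fickett, NAR 1982, as distributed with CPAT).
# Rows run from the highest parameter bracket down to the catch-all bracket.
# ---------------------------------------------------------------------------
_FICKETT_POSITION_PROB = {
    "A": [0.51, 0.55, 0.57, 0.52, 0.48, 0.58, 0.57, 0.54, 0.50, 0.36],
    "C": [0.29, 0.44, 0.55, 0.49, 0.52, 0.60, 0.60, 0.56, 0.42, 0.32],
    "G": [0.62, 0.67, 0.74, 0.65, 0.61, 0.62, 0.52, 0.41, 0.31, 0.29],
    "T": [0.51, 0.60, 0.69, 0.64, 0.62, 0.67, 0.58, 0.48, 0.39, 0.24],
}
_FICKETT_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
_FICKETT_POSITION_PARA = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]

_FICKETT_CONTENT_PROB = {
    "A": [0.40, 0.55, 0.58, 0.58, 0.52, 0.48, 0.45, 0.45, 0.38, 0.19],
    "C": [0.50, 0.63, 0.59, 0.50, 0.46, 0.45, 0.47, 0.56, 0.59, 0.33],
    "G": [0.21, 0.40, 0.47, 0.50, 0.52, 0.56, 0.57, 0.52, 0.44, 0.23],
    "T": [0.30, 0.49, 0.56, 0.53, 0.48, 0.48, 0.52, 0.57, 0.60, 0.51],
}
_FICKETT_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
_FICKETT_CONTENT_PARA = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


def _codon_position_counts(seq: str) -> dict[str, list[int]]:
    """Counts of each base at codon positions 1..3, reading complete
    frame-0 codons of the whole transcript."""
    n_codons = len(seq) // 3
    counts = {b: [0, 0, 0] for b in BASES}
    for i in range(3 * n_codons):
        b = seq[i]
        if b in counts:
            counts[b][i % 3] += 1
    return counts


def position_frequency_block(seq: str) -> dict[str, float]:
    """Fickett position parameters: max/(min+1) of per-codon-position
    base counts, one value per base."""
    names = [f"{b}_pos_fickett" for b in BASES]
    if len(seq) < 3:
        return dict.fromkeys(names, 0.0)
    counts = _codon_position_counts(seq)
    out = {}
    for b in BASES:
        c = counts[b]
        out[f"{b}_pos_fickett"] = max(c) / (min(c) + 1)
    return out


def _fickett_lookup(value: float, para: list, prob: list) -> float:
    for threshold, p in zip(para, prob):
        if value >= threshold:
            return p
    return prob[-1]


def fickett_score(seq: str) -> float:
    """Fickett TESTCODE score: weighted table lookup of the four base
    position parameters and four base content fractions."""
    if len(seq) < 3:
        return 0.0
    pos = position_frequency_block(seq)
    total = len(seq)
    score = 0.0
    for b in BASES:
        p = _fickett_lookup(
            pos[f"{b}_pos_fickett"],
            _FICKETT_POSITION_PARA,
            _FICKETT_POSITION_PROB[b],
        )
        score += p * _FICKETT_POSITION_WEIGHT[b]
        content = seq.count(b) / total
        c = _fickett_lookup(
            content, _FICKETT_CONTENT_PARA, _FICKETT_CONTENT_PROB[b]
        )
        score += c * _FICKETT_CONTENT_WEIGHT[b]
    return score


def stop_codon_block(seq: str) -> dict[str, float]:
    """Frame-0 stop-codon count/frequency plus the population variance
    of both statistics across the three frames."""
    names = [
        "stop_codon_count",
        "stop_codon_frequency",
        "stop_codon_frame_score",
        "stop_codon_frequency_frame_score",
    ]
    if len(seq) < 3:
        return dict.fromkeys(names, 0.0)
    stops = {"TAA", "TAG", "TGA"}
    counts, freqs = [], []
    for frame in range(3):
        n_codons = (len(seq) - frame) // 3
        c = sum(
            1
            for i in range(frame, frame + 3 * n_codons, 3)
            if seq[i : i + 3] in stops
        )
        counts.append(c)
        freqs.append(c / n_codons if n_codons else 0.0)
    return {
        "stop_codon_count": float(counts[0]),
        "stop_codon_frequency": freqs[0],
        "stop_codon_frame_score": float(np.var(counts)),
        "stop_codon_frequency_frame_score": float(np.var(freqs)),
    }


def _gc_fraction(seq: str) -> float:
    denom = sum(1 for c in seq if c in BASES)
    if denom == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / denom


def gc_block(seq: str, profile: OrfProfile) -> dict[str, float]:
    """GC content of the transcript, of the three codon positions of the
    longest ORF (frame-0 whole-transcript codons when no ORF), the
    population variance of (GC1,GC2,GC3), and UTR GC contents."""
    L = len(seq)
    gc = (seq.count("G") + seq.count("C")) / L if L else 0.0
    codon_src = longest_orf_seq(seq, profile) or seq
    n_codons = len(codon_src) // 3
    gc123 = [0.0, 0.0, 0.0]
    if n_codons:
        for pos in range(3):
            hits = sum(
                1
                for i in range(pos, 3 * n_codons, 3)
                if codon_src[i] in "GC"
            )
            gc123[pos] = hits / n_codons
    u5s, u5e = profile.utr5
    u3s, u3e = profile.utr3
    return {
        "GC_content": gc,
        "GC1": gc123[0],
        "GC2": gc123[1],
        "GC3": gc123[2],
        "GC1_frame_score": float(np.var(gc123)),
        "UTR5_GC": _gc_fraction(seq[u5s:u5e]),
        "UTR3_GC": _gc_fraction(seq[u3s:u3e]),
    }


def kmer_names() -> list[str]:
    """Transcript k-mer names (the mer itself) then ORF k-mer names,
    k = 1..3, lexicographic A<C<G<T within each k."""
    mers = [
        "".join(p)
        for k in (1, 2, 3)
        for p in itertools.product(BASES, repeat=k)
    ]
    return mers + [f"ORF_k_mer_{m}" for m in mers]


def _kmer_freqs(seq: str, k: int) -> dict[str, float]:
    mers = ["".join(p) for p in itertools.product(BASES, repeat=k)]
    counts = dict.fromkeys(mers, 0)
    valid = 0
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if w in counts:
            counts[w] += 1
            valid += 1
    if valid == 0:
        return dict.fromkeys(mers, 0.0)
    return {m: c / valid for m, c in counts.items()}


def kmer_block(seq: str, orf_seq: str) -> dict[str, float]:
    """168 k-mer frequencies (k=1,2,3) on the transcript and on its
    longest ORF (zeros when no ORF)."""
    out: dict[str, float] = {}
    for k in (1, 2, 3):
        out.update(_kmer_freqs(seq, k))
    for k in (1, 2, 3):
        for m, v in _kmer_freqs(orf_seq, k).items():
            out[f"ORF_k_mer_{m}"] = v
    return out


_CTD_FRACTIONS = (0, 25, 50, 75, 100)


def ctd_distribution(seq: str) -> dict[str, float]:
    """Distribution descriptors: the relative transcript position of the
    first, 25%, 50%, 75% and last occurrence of each base."""
    L = len(seq)
    out: dict[str, float] = {}
    for b in BASES:
        positions = [i + 1 for i, c in enumerate(seq) if c == b]
        m = len(positions)
        for f in _CTD_FRACTIONS:
            name = f"{b}_dis_{f}"
            if m == 0 or L == 0:
                out[name] = 0.0
            else:
                q = max(1, math.ceil(m * f / 100))
                out[name] = positions[q - 1] / L
    return out


def edp_profile(counts) -> np.ndarray:
    """Entropy density profile: s_i = -p_i*log(p_i)/H.

    Each symbol's share of the total Shannon entropy; sums to 1. A
    one-hot distribution (H = 0) is returned unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("edp_profile requires at least one positive count")
    p = counts / total
    nz = p > 0
    plogp = np.zeros_like(p)
    plogp[nz] = -p[nz] * np.log(p[nz])
    H = plogp.sum()
    if H == 0.0:
        return p
    return plogp / H


def edp_orf_block(orf_seq: str) -> dict[str, float]:
    """EDP over the 16 overlapping-dinucleotide counts of the longest
    ORF; zeros when there is no ORF or no valid dinucleotide."""
    mers = ["".join(p) for p in itertools.product(BASES, repeat=2)]
    names = [f"EDP_ORF_k_mer_{m}" for m in mers]
    counts = np.zeros(16)
    for i in range(len(orf_seq) - 1):
        w = orf_seq[i : i + 2]
        if w[0] in BASES and w[1] in BASES:
            counts[mers.index(w)] += 1
    if counts.sum() == 0:
        return dict.fromkeys(names, 0.0)
    return dict(zip(names, edp_profile(counts)))


def edp_transcript_block(seq: str) -> dict[str, float]:
    """EDP over the 20 amino-acid counts of the frame-0 translation of
    the whole transcript (stop codons skipped)."""
    names = [f"EDP_fea_{aa}" for aa in AMINO_ACIDS]
    pep = translate(seq)
    counts = np.array([pep.count(aa) for aa in AMINO_ACIDS], dtype=float)
    if counts.sum() == 0:
        return dict.fromkeys(names, 0.0)
    return dict(zip(names, edp_profile(counts)))


def snr(seq: str) -> float:
    """Codon-periodicity signal-to-noise ratio via the DFT.

    Power spectra of the four base indicator sequences are summed; the
    SNR is the power at the one-third frequency bin k* = round(N/3)
    divided by the mean power over all non-DC bins. Degenerate spectra
    (no non-DC power) give 0.
    """
    N = len(seq)
    if N < 6:
        return 0.0
    power = np.zeros(N)
    for b in BASES:
        indicator = np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)
        power += np.abs(np.fft.fft(indicator.astype(float))) ** 2
    noise = power[1:].mean()
    if noise == 0.0:
        return 0.0
    k_star = round(N / 3)
    return float(power[k_star] / noise)


def utr_coverage(profile: OrfProfile, length: Optional[int] = None) -> dict:
    """Fractions of the transcript occupied by the 5' and 3' UTRs."""
    L = profile.length if length is None else length
    if L == 0 or profile.longest_orf is None:
        return {"UTR5_coverage": 0.0, "UTR3_coverage": 0.0}
    u5s, u5e = profile.utr5
    u3s, u3e = profile.utr3
    return {
        "UTR5_coverage": (u5e - u5s) / L,
        "UTR3_coverage": (u3e - u3s) / L,
    }
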