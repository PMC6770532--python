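"""Peptide-level ("structure") features of the predicted ORF product.

The longest ORF is translated with the standard genetic code and six
physicochemical descriptors are derived: molecular weight (average
masses, ExPASy convention), theoretical isoelectric point (Bjellqvist
pKa set, bisection), log10(pI/Mw) and its across-frame variance, the
Kyte-Doolittle GRAVY and the Guruprasad instability index.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from Bio.SeqUtils.ProtParamData import DIWV, kd

_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]
_FORWARD = dict(_CODON_TABLE.forward_table)
_STOPS = set(_CODON_TABLE.stop_codons)

# Bjellqvist pKa values (ExPASy "Compute pI/Mw" convention)
_PKA_POSITIVE = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_PKA_NEGATIVE = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}


def translate(orf_seq: str) -> str:
    """Standard-code translation of successive codons.

    Trailing partial codons are dropped; stop codons and codons
    containing an ambiguous base yield no residue. May return ''.
    """
    residues = []
    for i in range(0, len(orf_seq) - 2, 3):
        codon = orf_seq[i : i + 3]
        if codon in _STOPS:
            continue
        aa = _FORWARD.get(codon)
        if aa is not None:
            residues.append(aa)
    return "".join(residues)


def molecular_weight(pep: str) -> float:
    """Average molecular weight in daltons; 0 for the empty peptide."""
    if not pep:
        return 0.0
    return float(ProteinAnalysis(pep).molecular_weight())


def peptide_charge(pep: str, pH: float) -> float:
    """Net charge of the peptide at a given pH (Henderson-Hasselbalch
    over termini and D/E/C/Y/H/K/R side chains)."""
    pos = [_PKA_POSITIVE["Nterm"]]
    neg = [_PKA_NEGATIVE["Cterm"]]
    for aa in pep:
        if aa in _PKA_POSITIVE:
            pos.append(_PKA_POSITIVE[aa])
        elif aa in _PKA_NEGATIVE:
            neg.append(_PKA_NEGATIVE[aa])
    charge = sum(1.0 / (1.0 + 10 ** (pH - pk)) for pk in pos)
    charge -= sum(1.0 / (1.0 + 10 ** (pk - pH)) for pk in neg)
    return charge


def isoelectric_point(pep: str, tol: float = 1e-3) -> float:
    """pH of zero net charge, found by bisection on [0, 14]."""
    if not pep:
        return 0.0
    lo, hi = 0.0, 14.0
    # charge is monotonically decreasing in pH
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if peptide_charge(pep, mid) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def gravy(pep: str) -> float:
    """Grand average of hydropathicity (mean Kyte-Doolittle value)."""
    if not pep:
        return 0.0
    return sum(kd[aa] for aa in pep) / len(pep)


def instability_index(pep: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide
    instability weights over consecutive residue pairs; 0 for L < 2."""
    L = len(pep)
    if L < 2:
        return 0.0
    total = sum(DIWV[pep[i]][pep[i + 1]] for i in range(L - 1))
    return (10.0 / L) * total


def _log10_pi_mw(pep: str) -> float:
    pi = isoelectric_point(pep)
    mw = molecular_weight(pep)
    if pi <= 0 or mw <= 0:
        return 0.0
    return math.log10(pi / mw)


def peptide_block(seq: str, profile) -> dict[str, float]:
    """The six structure features of the longest-ORF peptide.

    The pI/Mw frame score is the population variance of log10(pI/Mw)
    over the longest ORF of each of the three frames (a frame with no
    ORF contributes a 0 term). All zeros when the transcript has no ORF.
    """
    names = ["Mw", "pI", "pI_Mw", "pI_Mw_frame_score", "Gravy",
             "Instability_index"]
    if profile.longest_orf is None:
        return dict.fromkeys(names, 0.0)
    pep = translate(seq[profile.longest_orf.start : profile.longest_orf.end])
    per_frame = []
    for ann in profile.per_frame_longest:
        if ann is None:
            per_frame.append(0.0)
        else:
            per_frame.append(_log10_pi_mw(translate(seq[ann.start : ann.end])))
    return {
        "Mw": molecular_weight(pep),
        "pI": isoelectric_point(pep),
        "pI_Mw": _log10_pi_mw(pep),
        "pI_Mw_frame_score": float(np.var(per_frame)),
        "Gravy": gravy(pep),
        "Instability_index": instability_index(pep),
    }
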