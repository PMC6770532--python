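"""Synthetic labelled transcripts for end-to-end testing.

Coding-like transcripts carry a long (>=60% of the transcript by
default) ATG..stop ORF whose codons are drawn from a per-dataset
codon-usage distribution sharpened by ``codon_bias_strength``, flanked
by background-composition UTRs. Noncoding-like transcripts are drawn
from a low-order Markov background tuned to a target GC content, with
no enforced codon structure.

Setting ``codon_bias_strength = 0`` switches the coding generator into
a *null-calibration* mode: both classes are drawn from the same
GC-matched background process, so a classifier should do no better
than chance. This is the designed negative control; it deliberately
drops the ORF scaffold, which by itself would make the classes
separable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .orf import STOP_CODONS, orf_profile
from .seqio import Transcript, write_fasta

BASES = "ACGT"
SENSE_CODONS = tuple(
    c for c in ("".join(p) for p in itertools.product(BASES, repeat=3))
    if c not in STOP_CODONS
)
_STOPS = tuple(sorted(STOP_CODONS))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults give a clearly separable dataset
    inside the model's 200-3000 nt training window."""

    n_coding: int = 500
    n_noncoding: int = 500
    len_min: int = 200
    len_max: int = 3000
    codon_bias_strength: float = 0.75
    gc_target: float = 0.5
    markov_order: int = 2
    orf_min_coverage: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_coding < 0 or self.n_noncoding < 0:
            raise ValueError("counts must be nonnegative")
        if self.len_min >= self.len_max:
            raise ValueError("len_min must be < len_max")
        if not 0.0 <= self.codon_bias_strength <= 1.0:
            raise ValueError("codon_bias_strength must lie in [0, 1]")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError("gc_target must lie in (0, 1)")


class _MarkovBackground:
    """Order-k Markov sampler whose expected base distribution matches
    the GC target; per-context transition probabilities get a mild
    Dirichlet perturbation so datasets have nontrivial correlations."""

    def __init__(self, cfg: SynthConfig, rng: np.random.Generator):
        gc = cfg.gc_target
        self.base_probs = np.array(
            [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        )
        self.order = cfg.markov_order
        n_ctx = 4**self.order
        alpha = np.maximum(self.base_probs * 60.0, 1e-3)
        self.transitions = rng.dirichlet(alpha, size=n_ctx)

    def sample(self, length: int, rng: np.random.Generator) -> str:
        out = list(
            rng.choice(4, size=min(self.order, length), p=self.base_probs)
        )
        ctx = 0
        for b in out:
            ctx = (ctx * 4 + int(b)) % (4**self.order)
        while len(out) < length:
            b = int(rng.choice(4, p=self.transitions[ctx]))
            out.append(b)
            ctx = (ctx * 4 + b) % (4**self.order)
        return "".join(BASES[b] for b in out)


def _codon_usage(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-dataset sense-codon distribution: a Dirichlet-sharpened draw
    mixed with the uniform distribution by codon_bias_strength."""
    s = cfg.codon_bias_strength
    uniform = np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
    spiky = rng.dirichlet(np.full(len(SENSE_CODONS), 0.5))
    return (1.0 - s) * uniform + s * spiky


def _sample_length(cfg: SynthConfig, rng: np.random.Generator) -> int:
    # strict interior of the window so the length filter keeps everything
    return int(rng.integers(cfg.len_min + 1, cfg.len_max))


def generate_noncoding(
    cfg: SynthConfig, rng: Optional[np.random.Generator] = None,
    background: Optional[_MarkovBackground] = None,
) -> list[Transcript]:
    """Markov-background transcripts with no enforced codon structure."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if background is None:
        background = _MarkovBackground(cfg, rng)
    out = []
    for i in range(cfg.n_noncoding):
        L = _sample_length(cfg, rng)
        out.append(Transcript(id=f"noncoding_{i}", seq=background.sample(L, rng)))
    return out


def generate_coding(
    cfg: SynthConfig, rng: Optional[np.random.Generator] = None,
    background: Optional[_MarkovBackground] = None,
) -> list[Transcript]:
    """UTR + ATG + biased codons + stop + UTR transcripts.

    Every emitted transcript is checked to have a stop-terminated
    longest ORF covering at least ``orf_min_coverage`` of its length
    (rare violating draws are resampled). With
    ``codon_bias_strength == 0`` the null-calibration background
    process is used instead (see module docstring).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if background is None:
        background = _MarkovBackground(cfg, rng)
    if cfg.codon_bias_strength == 0.0:
        return [
            Transcript(
                id=f"coding_{i}",
                seq=background.sample(_sample_length(cfg, rng), rng),
            )
            for i in range(cfg.n_coding)
        ]
    usage = _codon_usage(cfg, rng)
    out = []
    for i in range(cfg.n_coding):
        for _ in range(100):
            L = _sample_length(cfg, rng)
            cov = rng.uniform(cfg.orf_min_coverage, 0.95)
            n_codons = max(3, int(cov * L) // 3)
            n_codons = min(n_codons, L // 3)
            orf_len = 3 * n_codons
            utr5_len = int(rng.integers(0, L - orf_len + 1))
            body = "".join(
                SENSE_CODONS[j]
                for j in rng.choice(len(SENSE_CODONS), size=n_codons - 2,
                                    p=usage)
            )
            seq = (
                background.sample(utr5_len, rng)
                + "ATG"
                + body
                + _STOPS[int(rng.integers(len(_STOPS)))]
                + background.sample(L - orf_len - utr5_len, rng)
            )
            profile = orf_profile(seq)
            longest = profile.longest_orf
            if (
                longest is not None
                and longest.has_stop
                and longest.length / L >= cfg.orf_min_coverage
            ):
                out.append(Transcript(id=f"coding_{i}", seq=seq))
                break
        else:  # pragma: no cover - essentially unreachable
            raise RuntimeError("failed to generate a valid coding transcript")
    return out


def generate_dataset(
    cfg: SynthConfig, outdir=None
) -> tuple[list[Transcript], np.ndarray]:
    """Generate a labelled dataset (label 1 = lncRNA-like/noncoding,
    0 = coding); deterministic for a given config.

    When *outdir* is given, writes coding.fa, noncoding.fa, labels.tsv
    and metadata.json there.
    """
    rng = np.random.default_rng(cfg.seed)
    background = _MarkovBackground(cfg, rng)
    coding = generate_coding(cfg, rng, background)
    noncoding = generate_noncoding(cfg, rng, background)
    transcripts = coding + noncoding
    labels = np.array([0] * len(coding) + [1] * len(noncoding))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(coding, outdir / "coding.fa")
        write_fasta(noncoding, outdir / "noncoding.fa")
        with open(outdir / "labels.tsv", "w", encoding="utf-8") as fh:
            fh.write(f"# seed={cfg.seed}\nid\tlabel\n")
            for t, lab in zip(transcripts, labels):
                fh.write(f"{t.id}\t{lab}\n")
        with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump({"config": asdict(cfg)}, fh, indent=1)
    return transcripts, labels
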