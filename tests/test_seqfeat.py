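import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lncstack.orf import orf_profile
from lncstack.seqfeat import (
    ctd_distribution,
    edp_orf_block,
    edp_profile,
    edp_transcript_block,
    fickett_score,
    gc_block,
    kmer_block,
    position_frequency_block,
    snr,
    stop_codon_block,
    utr_coverage,
)

from conftest import random_dna

# ---------------------------------------------------------------- stop codons


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("TAATAA", [2, 1.0, 8 / 9, 2 / 9]),
        ("AAAAAA", [0, 0.0, 0.0, 0.0]),
        ("AA", [0, 0, 0, 0]),
    ],
)
def test_stop_codon_block_worked_values(seq, expected):
    assert list(stop_codon_block(seq).values()) == pytest.approx(expected)


def test_stop_codon_block_frame0_saturated():
    b = stop_codon_block("TAGTAGTAG")
    assert b["stop_codon_count"] == 3 and b["stop_codon_frequency"] == 1.0


def _stop_oracle(seq):
    stops = {"TAA", "TAG", "TGA"}
    counts, freqs = [], []
    for f in range(3):
        codons = [seq[i : i + 3] for i in range(f, len(seq) - 2, 3)]
        c = sum(1 for cd in codons if cd in stops)
        counts.append(c)
        freqs.append(c / len(codons) if codons else 0.0)
    mean_c = sum(counts) / 3
    mean_f = sum(freqs) / 3
    return [
        counts[0],
        freqs[0],
        sum((c - mean_c) ** 2 for c in counts) / 3,
        sum((f - mean_f) ** 2 for f in freqs) / 3,
    ]


def test_stop_codon_block_matches_enumeration_oracle():
    # reduced-alphabet exhaustive enumeration keeps the space small while
    # still hitting all three stop codons (TAA/TAG/TGA all use A/T/G)
    for n in (3, 4, 5, 6):
        for tup in itertools.product("ATG", repeat=n):
            seq = "".join(tup)
            assert list(stop_codon_block(seq).values()) == pytest.approx(
                _stop_oracle(seq)
            )


# ------------------------------------------------------- position frequencies


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGATGATG", {"A": 3.0, "C": 0.0, "G": 3.0, "T": 3.0}),
        ("AAAAAAAAA", {"A": 0.75, "C": 0.0, "G": 0.0, "T": 0.0}),
        ("AT", {"A": 0.0, "C": 0.0, "G": 0.0, "T": 0.0}),
    ],
)
def test_position_frequency_worked_values(seq, expected):
    block = position_frequency_block(seq)
    for b, v in expected.items():
        assert block[f"{b}_pos_fickett"] == pytest.approx(v)


# ----------------------------------------------------------------- Fickett


def test_fickett_golden_value():
    # frozen from an independent step-by-step table evaluation
    seq = "ATGGCAGATTACAAGGATGACGACGATAAGTGGCGAATTCTGCAGTCGACGGTACCGCGG"
    assert fickett_score(seq) == pytest.approx(0.7513, abs=1e-12)


def test_fickett_score_within_table_bounds(rng):
    for _ in range(50):
        s = fickett_score(random_dna(rng, int(rng.integers(3, 200))))
        assert 0.0 < s < 1.6  # sum of weights bounds the lookup output


def test_fickett_prefers_codon_periodic_sequences(rng):
    pos_bias = {0: "GGGA", 1: "AAAC", 2: "TTTC"}  # strong positional skew
    periodic, uniform = [], []
    for _ in range(100):
        seq = "".join(
            pos_bias[i % 3][rng.integers(4)] for i in range(300)
        )
        periodic.append(fickett_score(seq))
        uniform.append(fickett_score(random_dna(rng, 300)))
    assert np.mean(periodic) > np.mean(uniform)


# ---------------------------------------------------------------------- GC


@pytest.mark.parametrize(
    "seq,gc,gc123",
    [
        # codons ATG,GGG,TAA: third positions G,G,A -> GC3 = 2/3
        ("ATGGGGTAA", 4 / 9, (1 / 3, 1 / 3, 2 / 3)),
        ("ATGC", 0.5, (0.0, 0.0, 1.0)),
        ("A" * 12, 0.0, (0.0, 0.0, 0.0)),
    ],
)
def test_gc_block_worked_values(seq, gc, gc123):
    b = gc_block(seq, orf_profile(seq))
    assert b["GC_content"] == pytest.approx(gc)
    assert (b["GC1"], b["GC2"], b["GC3"]) == pytest.approx(gc123)


def test_gc_frame_score_zero_for_balanced_codons():
    # GGGGGG: every codon position is all-G, so GC1=GC2=GC3=1
    b = gc_block("GGGGGG", orf_profile("GGGGGG"))
    assert b["GC1_frame_score"] == pytest.approx(0.0)


def test_gc_block_matches_direct_count_oracle(rng):
    for _ in range(100):
        seq = random_dna(rng, int(rng.integers(3, 30)))
        profile = orf_profile(seq)
        b = gc_block(seq, profile)
        assert b["GC_content"] == pytest.approx(
            (seq.count("G") + seq.count("C")) / len(seq)
        )
        src = (
            seq[profile.longest_orf.start : profile.longest_orf.end]
            if profile.longest_orf
            else seq
        )
        n = len(src) // 3
        for pos in (0, 1, 2):
            expect = (
                sum(src[i] in "GC" for i in range(pos, 3 * n, 3)) / n
                if n
                else 0.0
            )
            assert b[f"GC{pos + 1}"] == pytest.approx(expect)


def test_utr_gc_of_flanks():
    # ORF at [3, 12); 5'UTR = GGC, 3'UTR = AT
    seq = "GGC" + "ATGAAATAA" + "AT"
    b = gc_block(seq, orf_profile(seq))
    assert b["UTR5_GC"] == pytest.approx(1.0)
    assert b["UTR3_GC"] == pytest.approx(0.0)


# -------------------------------------------------------------------- k-mer


def test_kmer_one_hot_homopolymer():
    b = kmer_block("AAAA", "")
    assert b["A"] == 1.0 and b["AA"] == 1.0 and b["AAA"] == 1.0
    assert b["C"] == 0.0 and b["ORF_k_mer_A"] == 0.0
    assert sum(v for k, v in b.items() if not k.startswith("ORF")) == 3.0


def test_kmer_uniform_mononucleotides():
    b = kmer_block("ACGT", "ACGT")
    for base in "ACGT":
        assert b[base] == 0.25
        assert b[f"ORF_k_mer_{base}"] == 0.25


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTN", min_size=3, max_size=60))
def test_kmer_groups_normalize(seq):
    b = kmer_block(seq, seq)
    mers1 = [m for m in b if len(m) == 1]
    for k in (1, 2, 3):
        group = [v for m, v in b.items()
                 if not m.startswith("ORF") and len(m) == k]
        total = sum(group)
        assert total == pytest.approx(1.0) or total == 0.0
    assert all(0.0 <= v <= 1.0 for v in b.values())
    del mers1


# ---------------------------------------------------------------------- CTD


def test_ctd_single_occurrence_bases():
    b = ctd_distribution("ACGT")
    for base, pos in zip("ACGT", (0.25, 0.5, 0.75, 1.0)):
        for f in (0, 25, 50, 75, 100):
            assert b[f"{base}_dis_{f}"] == pytest.approx(pos)


def test_ctd_homopolymer_quantiles():
    b = ctd_distribution("AAAA")
    got = [b[f"A_dis_{f}"] for f in (0, 25, 50, 75, 100)]
    assert got == pytest.approx([0.25, 0.25, 0.5, 0.75, 1.0])
    assert all(b[f"{x}_dis_{f}"] == 0.0 for x in "CGT" for f in (0, 25, 50, 75, 100))


def test_ctd_values_in_unit_interval_and_nondecreasing(rng):
    for _ in range(50):
        seq = random_dna(rng, int(rng.integers(4, 50)))
        b = ctd_distribution(seq)
        for base in "ACGT":
            vals = [b[f"{base}_dis_{f}"] for f in (0, 25, 50, 75, 100)]
            assert all(0.0 <= v <= 1.0 for v in vals)
            assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))


# ---------------------------------------------------------------------- EDP


def test_edp_uniform_counts():
    assert edp_profile(np.ones(16)) == pytest.approx(np.full(16, 1 / 16))
    assert edp_profile(np.ones(20)) == pytest.approx(np.full(20, 1 / 20))


def test_edp_one_hot_degenerate_rule():
    out = edp_profile([0, 5, 0, 0])
    assert out == pytest.approx([0, 1, 0, 0])


def test_edp_rejects_all_zero_counts():
    with pytest.raises(ValueError):
        edp_profile([0, 0, 0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 50), min_size=2, max_size=20).filter(
    lambda c: sum(c) > 0))
def test_edp_sums_to_one(counts):
    assert edp_profile(counts).sum() == pytest.approx(1.0)


def test_edp_blocks_on_sequences():
    orf = "ATGAAATAA"
    b = edp_orf_block(orf)
    assert len(b) == 16 and sum(b.values()) == pytest.approx(1.0)
    t = edp_transcript_block("ATGAAA")  # translation "MK"
    assert sum(t.values()) == pytest.approx(1.0)
    assert t["EDP_fea_M"] > 0 and t["EDP_fea_K"] > 0
    assert len(edp_orf_block("")) == 16
    assert sum(edp_orf_block("").values()) == 0.0


# ---------------------------------------------------------------------- SNR


def test_snr_worked_value_period_three():
    assert snr("ATGATGATGATG") == pytest.approx(5.5)


def test_snr_homopolymer_defined_as_zero():
    assert snr("A" * 30) == 0.0
    assert snr("ACGT") == 0.0  # below minimum length


def test_snr_invariant_under_base_relabeling(rng):
    for _ in range(20):
        seq = random_dna(rng, 48)
        relabeled = seq.translate(str.maketrans("ACGT", "GTAC"))
        assert snr(seq) == pytest.approx(snr(relabeled))


def test_snr_periodic_exceeds_iid_median(rng):
    iid = [snr(random_dna(rng, 60)) for _ in range(200)]
    periodic = snr("ATG" * 20)
    assert periodic > float(np.median(iid))


# ------------------------------------------------------------- UTR coverage


@pytest.mark.parametrize(
    "seq,expected",
    [
        ("ATGAAATAA", [0.0, 0.0]),
        ("CCCATGAAATAA", [0.25, 0.0]),
        ("CCCCCC", [0.0, 0.0]),
    ],
)
def test_utr_coverage_worked_values(seq, expected):
    cov = utr_coverage(orf_profile(seq))
    assert list(cov.values()) == pytest.approx(expected)


def test_frequency_outputs_bounded(rng):
    for _ in range(30):
        seq = random_dna(rng, int(rng.integers(6, 80)))
        p = orf_profile(seq)
        assert stop_codon_block(seq)["stop_codon_frame_score"] >= 0
        assert gc_block(seq, p)["GC1_frame_score"] >= 0
        for v in utr_coverage(p).values():
            assert 0.0 <= v <= 1.0
        assert math.isfinite(snr(seq))
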