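"""Seed-site prediction against exhaustive window-scan oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from placmir.seed_match import (
    MatureMiRNA,
    SeedSite,
    TranscriptRegions,
    annotate_site_position,
    extract_seed,
    find_seed_sites,
    read_mirna_fasta,
    read_transcripts,
    render_alignment,
    revcomp,
    score_3prime_supplementary,
)
from placmir.synthetic import simulate_transcripts, write_transcripts, write_mirnas

WC = {"A": "U", "U": "A", "G": "C", "C": "G"}


def brute_force_sites(seed: str, seq: str, max_mm: int, wobble: bool = False):
    """Independent oracle: per-window pairing count by direct loops."""
    out = []
    k = len(seed)
    for start in range(1, len(seq) - k + 2):
        window = seq[start - 1 : start - 1 + k]
        mm = 0
        for j, tbase in enumerate(window):
            mbase = seed[k - 1 - j]
            paired = WC[mbase] == tbase or (
                wobble and (mbase, tbase) in (("G", "U"), ("U", "G"))
            )
            mm += not paired
        if mm <= max_mm:
            out.append((start, mm))
    return out


def random_transcript(rng, length):
    n5 = max(1, length // 5)
    ncds = max(1, length // 2)
    return TranscriptRegions(
        "g", "".join(rng.choice(list("ACGU"), length)),
        (("5UTR", 1, n5), ("CDS", n5 + 1, n5 + ncds), ("3UTR", n5 + ncds + 1, length)),
    )


def test_extract_seed_definition(mir99a):
    assert extract_seed(mir99a) == "ACCCGUA"
    with pytest.raises(ValueError):
        extract_seed(mir99a, first=2, last=40)


def test_short_mirna_rejected():
    with pytest.raises(ValueError, match="shorter than 16"):
        MatureMiRNA("tiny", "ACCCGUA")


def test_dna_input_transcribed_with_warning():
    with pytest.warns(UserWarning, match="T->U"):
        m = MatureMiRNA("m", "AACCCGTAGATCCGATCTTGTG")
    assert "T" not in m.sequence


def test_planted_exact_site_found(mir99a, small_transcript):
    sites = find_seed_sites(mir99a, small_transcript, max_mismatch=0)
    assert [(s.start, s.end, s.mismatches, s.region) for s in sites] == [
        (11, 17, 0, "CDS")
    ]


def test_one_substitution_gives_one_mismatch(mir99a):
    seq = "A" * 10 + "UACGGGU" + "A" * 43
    seq = seq[:12] + "A" + seq[13:]  # break one position of the planted site
    tr = TranscriptRegions("g", seq, (("5UTR", 1, 10), ("CDS", 11, 40), ("3UTR", 41, 60)))
    sites = {s.start: s.mismatches for s in find_seed_sites(mir99a, tr, max_mismatch=1)}
    assert sites[11] == 1


@pytest.mark.parametrize("wobble", [False, True])
@pytest.mark.parametrize("max_mm", [0, 1, 2])
def test_scan_equals_brute_force_oracle(mir99a, max_mm, wobble):
    rng = np.random.default_rng(100 * max_mm + wobble)
    for _ in range(10):
        tr = random_transcript(rng, int(rng.integers(60, 300)))
        got = [(s.start, s.mismatches)
               for s in find_seed_sites(mir99a, tr, max_mm, allow_wobble=wobble)]
        assert got == brute_force_sites(extract_seed(mir99a), tr.sequence, max_mm, wobble)


def test_mismatch_monotonicity(mir99a):
    rng = np.random.default_rng(7)
    tr = random_transcript(rng, 500)
    prev = set()
    for k in (0, 1, 2):
        cur = {(s.start, s.end) for s in find_seed_sites(mir99a, tr, k)}
        assert prev <= cur
        prev = cur


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_duplex_symmetry(seed):
    """Pairing counts are invariant to reverse-complementing both partners."""
    rng = np.random.default_rng(seed)
    mirna = MatureMiRNA("m", "".join(rng.choice(list("ACGU"), 22)))
    tr = random_transcript(rng, 120)
    for s in find_seed_sites(mirna, tr, max_mismatch=2):
        window = tr.sequence[s.start - 1 : s.end]
        seedseq = extract_seed(mirna)
        direct = sum(a != b for a, b in zip(window, revcomp(seedseq)))
        flipped = sum(a != b for a, b in zip(revcomp(window), seedseq))
        assert direct == flipped == s.mismatches


def test_supplementary_score_planted(mir99a):
    """Target built as the full complement of nt 13-16 at the opposed offset."""
    # site at start=50: miRNA nt k pairs target position 50 + 8 - k
    seq = list("A" * 120)
    seed_site = revcomp(extract_seed(mir99a))
    seq[49:56] = seed_site
    for k in range(13, 17):
        seq[50 + 8 - k - 1] = WC[mir99a.sequence[k - 1]]
    tr = TranscriptRegions("g", "".join(seq), (("CDS", 1, 80), ("3UTR", 81, 120)))
    site = next(s for s in find_seed_sites(mir99a, tr, 0) if s.start == 50)
    assert score_3prime_supplementary(mir99a, tr, site) == 4


def test_supplementary_score_no_self_pairing():
    # miRNA with A at nt 13-16 against an all-A target: A does not pair A
    m = MatureMiRNA("m", "ACCCGUAGAUCCAAAAGUCG")
    tr = TranscriptRegions("g", "U" * 30 + revcomp(extract_seed(m)) + "U" * 30,
                           (("CDS", 1, 67),))
    site = next(s for s in find_seed_sites(m, tr, 0) if s.start == 31)
    # opposed bases are U (pairs A); rebuild with A bases opposite the window
    seq = list(tr.sequence)
    for k in range(13, 17):
        seq[31 + 8 - k - 1] = "A"
    tr2 = TranscriptRegions("g", "".join(seq), (("CDS", 1, 67),))
    assert score_3prime_supplementary(m, tr2, site) == 0


def test_supplementary_window_beyond_mirna_errors(mir99a, small_transcript):
    site = find_seed_sites(mir99a, small_transcript, 0)[0]
    with pytest.raises(ValueError, match="beyond miRNA"):
        score_3prime_supplementary(mir99a, small_transcript, site, window=(13, 40))


def test_supplementary_matches_enumeration_oracle(mir99a):
    rng = np.random.default_rng(42)
    for _ in range(20):
        tr = random_transcript(rng, 200)
        for site in find_seed_sites(mir99a, tr, 2):
            expected = 0
            for k in range(13, 17):
                tpos = site.start + 8 - k
                if 1 <= tpos <= len(tr.sequence):
                    expected += WC[mir99a.sequence[k - 1]] == tr.sequence[tpos - 1]
            assert site.supplementary_score == expected


def test_alignment_star_counts(mir99a, small_transcript):
    site = find_seed_sites(mir99a, small_transcript, 0)[0]
    lines = site.alignment.splitlines()
    assert lines[1].startswith("target 5'-")
    # columns of the seed span (positions 11..17 of the target line)
    star_line = lines[2]
    target_line = lines[1]
    left = int(lines[0].split()[1].split("..")[0])
    col0 = len("target 5'-") + (site.start - left)
    seed_stars = star_line[col0 : col0 + 7]
    assert seed_stars == "*******"


def test_alignment_mismatch_star_count(mir99a):
    seq = list("A" * 10 + "UACGGGU" + "A" * 43)
    seq[11], seq[13] = "C", "C"  # two seed mismatches
    tr = TranscriptRegions("g", "".join(seq), (("CDS", 1, 60),))
    site = next(s for s in find_seed_sites(mir99a, tr, 2) if s.start == 11)
    assert site.mismatches == 2
    lines = site.alignment.splitlines()
    left = int(lines[0].split()[1].split("..")[0])
    col0 = len("target 5'-") + (site.start - left)
    assert lines[2][col0 : col0 + 7].count("*") == 5


def test_alignment_deterministic(mir99a, small_transcript):
    a = render_alignment(mir99a, small_transcript,
                         find_seed_sites(mir99a, small_transcript, 0)[0])
    b = render_alignment(mir99a, small_transcript,
                         find_seed_sites(mir99a, small_transcript, 0)[0])
    assert a == b


def test_distance_to_3utr_convention(mir99a):
    # site ending at 100, 3'UTR starting at 199 -> 98 nt strictly between
    seq = "A" * 93 + revcomp(extract_seed(mir99a)) + "A" * 200
    tr = TranscriptRegions("g", seq, (("CDS", 1, 198), ("3UTR", 199, 300)))
    site = next(s for s in find_seed_sites(mir99a, tr, 0) if s.end == 100)
    region, dist = annotate_site_position(site, tr)
    assert (region, dist) == ("CDS", 98)


def test_distance_inside_3utr_is_zero(mir99a):
    seq = "A" * 200 + revcomp(extract_seed(mir99a)) + "A" * 50
    tr = TranscriptRegions("g", seq, (("CDS", 1, 198), ("3UTR", 199, 257)))
    site = next(s for s in find_seed_sites(mir99a, tr, 0) if s.start == 201)
    assert annotate_site_position(site, tr) == ("3UTR", 0)


def test_distance_random_oracle(mir99a):
    rng = np.random.default_rng(9)
    for _ in range(20):
        tr = random_transcript(rng, 300)
        utr_start = tr.region_span("3UTR")[0]
        for s in find_seed_sites(mir99a, tr, 2):
            _, dist = annotate_site_position(s, tr)
            if s.start >= utr_start:
                assert dist == 0
            else:
                assert dist == utr_start - 1 - s.end


def test_no_3utr_distance_undefined(mir99a):
    tr = TranscriptRegions("g", "A" * 10 + revcomp(extract_seed(mir99a)) + "A" * 43,
                           (("CDS", 1, 60),))
    site = find_seed_sites(mir99a, tr, 0)[0]
    region, dist = annotate_site_position(site, tr)
    assert region == "CDS" and dist is None


def test_fasta_roundtrip(tmp_path, mir99a):
    genes, _ = simulate_transcripts([mir99a], n_genes=3, length_range=(100, 200),
                                    seed=5)
    write_transcripts(genes, tmp_path / "t.fa", tmp_path / "r.tsv")
    write_mirnas([mir99a], tmp_path / "m.fa")
    back = read_transcripts(tmp_path / "t.fa", tmp_path / "r.tsv")
    assert [g.sequence for g in back] == [g.sequence for g in genes]
    assert [g.regions for g in back] == [g.regions for g in genes]
    assert read_mirna_fasta(tmp_path / "m.fa")[0].sequence == mir99a.sequence
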