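"""MicroRNA seed-site prediction on annotated transcripts.

The seed is nucleotides 2-8 of the mature microRNA (5'->3').  A candidate
site is any 7-nt transcript window whose bases, read 5'->3', pair
antiparallel with the seed: window position j (0-based) pairs with seed
position 6-j.  Pairing is Watson-Crick by default; G:U wobble can optionally
count as a match.  Sites with up to a configured number of mismatched
positions are reported, annotated with the transcript region (5'UTR / CDS /
3'UTR) containing the window midpoint, a 3'-supplementary pairing score for
microRNA nucleotides 13-16 on the opposed target bases, and a fixed-width
text alignment.

Coordinates are 1-based inclusive transcript positions throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "MatureMiRNA",
    "TranscriptRegions",
    "SeedSite",
    "extract_seed",
    "find_seed_sites",
    "score_3prime_supplementary",
    "render_alignment",
    "annotate_site_position",
    "read_mirna_fasta",
    "read_transcripts",
    "write_sites_tsv",
]

_WC = {"A": "U", "U": "A", "G": "C", "C": "G"}
REGION_LABELS = ("5UTR", "CDS", "3UTR")


def _to_rna(seq: str, what: str) -> str:
    s = seq.strip().upper()
    if "T" in s:
        warnings.warn(f"{what}: DNA alphabet detected, converting T->U", stacklevel=3)
        s = s.replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"{what}: invalid nucleotides {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement in the RNA alphabet."""
    return "".join(_WC[b] for b in reversed(seq))


@dataclass(frozen=True)
class MatureMiRNA:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _to_rna(self.sequence, f"miRNA {self.id}"))
        if len(self.sequence) < 16:
            raise ValueError(f"miRNA {self.id}: mature sequence shorter than 16 nt")


@dataclass(frozen=True)
class TranscriptRegions:
    """A transcript sequence with ordered, non-overlapping region spans."""

    gene_id: str
    sequence: str
    regions: tuple[tuple[str, int, int], ...]  # (label, start, end), 1-based incl.

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", _to_rna(self.sequence, f"transcript {self.gene_id}")
        )
        object.__setattr__(self, "regions", tuple(tuple(r) for r in self.regions))
        prev_end = 0
        for label, start, end in self.regions:
            if label not in REGION_LABELS:
                raise ValueError(f"{self.gene_id}: unknown region label {label!r}")
            if not (1 <= start <= end <= len(self.sequence)):
                raise ValueError(f"{self.gene_id}: region {label} out of bounds")
            if start <= prev_end:
                raise ValueError(f"{self.gene_id}: regions overlap or are unordered")
            prev_end = end

    def region_at(self, pos: int) -> str | None:
        for label, start, end in self.regions:
            if start <= pos <= end:
                return label
        return None

    def region_span(self, label: str) -> tuple[int, int] | None:
        for lab, start, end in self.regions:
            if lab == label:
                return start, end
        return None


@dataclass
class SeedSite:
    """One predicted binding site (7-nt seed match window)."""

    mirna_id: str
    gene_id: str
    start: int  # 1-based inclusive
    end: int
    region: str
    mismatches: int
    supplementary_score: int = 0
    alignment: str = ""
    boundary: bool = False  # window straddles a region boundary


def extract_seed(mirna: MatureMiRNA, first: int = 2, last: int = 8) -> str:
    """Seed region of the mature sequence, positions first..last (1-based)."""
    if last > len(mirna.sequence) or first < 1 or first > last:
        raise ValueError(
            f"seed positions {first}..{last} out of range for miRNA "
            f"{mirna.id} (length {len(mirna.sequence)})"
        )
    return mirna.sequence[first - 1 : last]


def _pairs(mirna_base: str, target_base: str, wobble: bool) -> bool:
    if _WC[mirna_base] == target_base:
        return True
    return wobble and (mirna_base, target_base) in (("G", "U"), ("U", "G"))


def find_seed_sites(
    mirna: MatureMiRNA,
    tr: TranscriptRegions,
    max_mismatch: int = 2,
    allow_wobble: bool = False,
    seed_first: int = 2,
    seed_last: int = 8,
) -> list[SeedSite]:
    """Scan every 7-nt window for an antiparallel seed match.

    Mismatch count = number of window positions not pairing with the seed.
    Emitted sites carry the region of the window midpoint, the nt 13-16
    supplementary pairing score, and a rendered alignment; sorted by start.
    """
    seq = tr.sequence
    k = seed_last - seed_first + 1
    if len(seq) < k:
        raise ValueError(f"transcript {tr.gene_id} shorter than the seed ({k} nt)")
    if not 0 <= max_mismatch <= k:
        raise ValueError("max_mismatch out of range")
    seed = extract_seed(mirna, seed_first, seed_last)

    # acceptable target base(s) per window offset j (pairs seed index k-1-j)
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    mism = np.zeros(windows.shape[0], dtype=np.int64)
    for j in range(k):
        sb = seed[k - 1 - j]
        accept = [_WC[sb]]
        if allow_wobble and sb in ("G", "U"):
            accept.append("U" if sb == "G" else "G")
        ok = np.zeros(windows.shape[0], dtype=bool)
        for ch in accept:
            ok |= windows[:, j] == ord(ch)
        mism += ~ok
    hits = np.flatnonzero(mism <= max_mismatch)

    sites: list[SeedSite] = []
    for h in hits:
        start = int(h) + 1
        end = start + k - 1
        mid = start + k // 2
        region = tr.region_at(mid) or "unannotated"
        boundary = tr.region_at(start) != tr.region_at(end)
        site = SeedSite(
            mirna_id=mirna.id,
            gene_id=tr.gene_id,
            start=start,
            end=end,
            region=region,
            mismatches=int(mism[h]),
            boundary=boundary,
        )
        if len(mirna.sequence) >= 16:
            site.supplementary_score = score_3prime_supplementary(mirna, tr, site)
        site.alignment = render_alignment(mirna, tr, site)
        sites.append(site)
    return sites


def _opposed_position(site: SeedSite, mirna_pos: int, loop_offset: int = 0) -> int:
    """Target position opposite miRNA nucleotide ``mirna_pos``.

    The duplex is anchored at the seed: miRNA nt 2 pairs the window's 3' end
    (site.end), nt 8 its 5' end (site.start); a loop allowance shifts the
    3'-side register further 5' on the target.
    """
    pos = site.start + 8 - mirna_pos
    if mirna_pos > 8:
        pos -= loop_offset
    return pos


def score_3prime_supplementary(
    mirna: MatureMiRNA,
    tr: TranscriptRegions,
    site: SeedSite,
    window: tuple[int, int] = (13, 16),
    loop_offset: int = 0,
    allow_wobble: bool = False,
) -> int:
    """Watson-Crick pair count between miRNA nt 13-16 and the opposed target bases."""
    lo, hi = window
    if hi > len(mirna.sequence):
        raise ValueError(
            f"supplementary window {lo}..{hi} beyond miRNA {mirna.id} length"
        )
    score = 0
    for k in range(lo, hi + 1):
        tpos = _opposed_position(site, k, loop_offset)
        if not 1 <= tpos <= len(tr.sequence):
            continue
        if _pairs(mirna.sequence[k - 1], tr.sequence[tpos - 1], allow_wobble):
            score += 1
    return score


def render_alignment(
    mirna: MatureMiRNA, tr: TranscriptRegions, site: SeedSite, loop_offset: int = 0
) -> str:
    """Fixed-width three-line alignment: target 5'->3', match stars, miRNA 3'->5'.

    Asterisks mark Watson-Crick complementary positions; the seed region of
    the microRNA is upper-case, the rest lower-case.  Deterministic.
    """
    L = len(mirna.sequence)
    # target span opposite miRNA nt L (left) .. nt 1 (right)
    left = _opposed_position(site, L, loop_offset)
    right = _opposed_position(site, 1, loop_offset)
    width = right - left + 1

    target_chars, star_chars, mir_chars = [], [], []
    for col in range(width):
        tpos = left + col
        tbase = tr.sequence[tpos - 1] if 1 <= tpos <= len(tr.sequence) else "."
        # which miRNA nt sits in this column (inverse of _opposed_position)
        cands = [k for k in range(1, L + 1) if _opposed_position(site, k, loop_offset) == tpos]
        if cands:
            k = cands[0]
            mbase = mirna.sequence[k - 1]
            mchar = mbase.upper() if 2 <= k <= 8 else mbase.lower()
            star = "*" if (tbase in "ACGU" and _WC[mbase] == tbase) else " "
        else:  # loop gap column
            mchar, star = "-", " "
        target_chars.append(tbase)
        star_chars.append(star)
        mir_chars.append(mchar)

    head = f"{site.gene_id} {left}..{right} ({site.region}, {site.mismatches} mm)"
    return "\n".join(
        [
            head,
            "target 5'-" + "".join(target_chars) + "-3'",
            "          " + "".join(star_chars),
            # leftmost column faces the miRNA 3' end, so this line reads 3'->5'
            "miRNA  3'-" + "".join(mir_chars) + "-5'",
        ]
    )


def annotate_site_position(
    site: SeedSite, tr: TranscriptRegions
) -> tuple[str, int | None]:
    """Region label and nucleotide gap between the site and the 3'UTR start.

    For sites 5' of the 3'UTR the distance is the number of nucleotides
    strictly between the site end and the 3'UTR start; inside the 3'UTR it
    is 0.  Without an annotated 3'UTR the distance is None.
    """
    span = tr.region_span("3UTR")
    region = tr.region_at(site.start + 3) or "unannotated"
    if span is None:
        return region, None
    utr_start, utr_end = span
    if site.start >= utr_start:
        return region, 0
    return region, utr_start - 1 - site.end


# ---------------------------------------------------------------------------
# IO


def read_mirna_fasta(path: str | Path) -> list[MatureMiRNA]:
    return [MatureMiRNA(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_transcripts(fasta: str | Path, regions_tsv: str | Path) -> list[TranscriptRegions]:
    """Transcripts from FASTA plus a region table (gene_id, label, start, end)."""
    regions = pd.read_csv(regions_tsv, sep="\t")
    required = {"gene_id", "label", "start", "end"}
    if not required <= set(regions.columns):
        raise ValueError(f"region table must have columns {sorted(required)}")
    out = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        sub = regions[regions["gene_id"] == rec.id].sort_values("start")
        spans = tuple(
            (row.label, int(row.start), int(row.end)) for row in sub.itertuples()
        )
        out.append(TranscriptRegions(rec.id, str(rec.seq), spans))
    return out


def write_sites_tsv(sites: list[SeedSite], path: str | Path) -> None:
    df = pd.DataFrame([asdict(s) for s in sites])
    if not df.empty:
        df = df.drop(columns=["alignment"])
    df.to_csv(path, sep="\t", index=False)


def write_alignments(sites: list[SeedSite], path: str | Path) -> None:
    Path(path).write_text("\n\n".join(s.alignment for s in sites) + "\n")
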