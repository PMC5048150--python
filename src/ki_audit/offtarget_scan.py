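"""Protospacer near-match scanning, cut-site and fragment prediction.

Cas9 binds a 20-nt protospacer immediately 5' of an NGG PAM and cleaves
~3 bp upstream of the PAM (between protospacer positions 17 and 18 for
the canonical offset).  The audit asks, for each unintended InDel,
whether the surrounding sequence resembles the guide closely enough to
be a plausible off-target cleavage site.  This module provides

* Hamming mismatch counting between guide and 20-nt site,
* bulge-tolerant alignment (at most one single-base gap, scored
  lexicographically: fewer bulges beats fewer mismatches),
* a PAM-anchored scanner over both strands returning
  :class:`OffTargetHit` records with predicted cut positions,
* cleavage-template fragment-size prediction for in-vitro digests,
* an IUPAC restriction-site scanner (e.g. TfiI GAWTC in the donor).

All coordinates are 1-based on the + strand of the scanned sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .variant_model import GuideDesign

__all__ = [
    "OffTargetHit",
    "hamming_mismatches",
    "bulge_alignment",
    "find_protospacers",
    "predict_cut_site",
    "predict_fragments",
    "find_restriction_sites",
    "revcomp",
]

_DNA = set("ACGT")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _check_dna(seq: str, what: str = "sequence") -> None:
    if set(seq.upper()) - _DNA:
        raise ValueError(f"{what} contains non-ACGT characters")


@dataclass(frozen=True)
class OffTargetHit:
    """A candidate protospacer adjacent to a matching PAM.

    ``protospacer_start`` is the lowest + strand coordinate of the
    protospacer window regardless of strand; ``predicted_cut`` is the +
    strand coordinate of the base immediately 5' (on the protospacer
    strand) of the blunt cut.
    """

    seq_id: str
    protospacer_start: int
    strand: str
    protospacer_seq: str
    pam_seq: str
    mismatches: int
    bulges: int
    predicted_cut: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not (0 <= self.mismatches <= 20 and 0 <= self.bulges <= 1):
            raise ValueError("mismatches must be 0-20 and bulges 0-1")


def hamming_mismatches(guide: str, site: str) -> int:
    """Number of mismatched positions between two equal-length DNA strings."""
    if len(guide) != len(site):
        raise ValueError(f"length mismatch: {len(guide)} vs {len(site)}")
    _check_dna(guide, "guide")
    _check_dna(site, "site")
    g, s = guide.upper(), site.upper()
    return sum(a != b for a, b in zip(g, s))


def bulge_alignment(guide: str, window: str) -> tuple[int, int, tuple[int, int]]:
    """Best guide/window alignment with at most one single-base gap.

    ``window`` may be 19-21 nt.  Returns ``(mismatches, bulges, span)``
    where ``span`` is the 1-based inclusive aligned range within the
    window.  Alignments are ranked lexicographically by (bulges,
    mismatches); for a 20-nt window the gap-free alignment is the only
    0-bulge candidate, so the result degenerates to
    :func:`hamming_mismatches`.
    """
    _check_dna(guide, "guide")
    _check_dna(window, "window")
    g, w = guide.upper(), window.upper()
    n, m = len(g), len(w)
    if not n - 1 <= m <= n + 1:
        raise ValueError(f"window length must be {n - 1}-{n + 1}, got {m}")

    candidates: list[tuple[int, int]] = []
    if m == n:
        candidates.append((0, sum(a != b for a, b in zip(g, w))))
    elif m == n - 1:
        # one guide base unpaired (RNA bulge): skip guide position i
        for i in range(n):
            gg = g[:i] + g[i + 1:]
            candidates.append((1, sum(a != b for a, b in zip(gg, w))))
    else:  # m == n + 1: one window base unpaired (DNA bulge)
        for i in range(m):
            ww = w[:i] + w[i + 1:]
            candidates.append((1, sum(a != b for a, b in zip(g, ww))))
    bulges, mismatches = min(candidates)
    return mismatches, bulges, (1, m)


def _iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for c in pattern.upper():
        bases = ambiguous_dna_values.get(c)
        if bases is None:
            raise ValueError(f"invalid IUPAC code {c!r}")
        parts.append(c if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))


def _pam_matches(pam_pattern: re.Pattern, triplet: str) -> bool:
    return pam_pattern.fullmatch(triplet) is not None


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _scan_strand(
    seq: str,
    guide: GuideDesign,
    max_mismatch: int,
    pam_re: re.Pattern,
) -> list[tuple[int, int]]:
    """Gap-free scan of one strand; (0-based window start, mismatches)."""
    n = len(guide.guide_seq)
    plen = len(guide.pam)
    if len(seq) < n + plen:
        return []
    arr = _encode(seq)
    windows = np.lib.stride_tricks.sliding_window_view(arr, n)
    g = _encode(guide.guide_seq)
    mm = (windows != g).sum(axis=1)
    out = []
    for start in np.nonzero(mm <= max_mismatch)[0]:
        pam_start = start + n
        if pam_start + plen > len(seq):
            continue
        if _pam_matches(pam_re, seq[pam_start:pam_start + plen].upper()):
            out.append((int(start), int(mm[start])))
    return out


def find_protospacers(
    seq: str,
    guide: GuideDesign | str,
    max_mismatch: int = 4,
    allow_bulge: bool = False,
    seq_id: str = "seq",
) -> list[OffTargetHit]:
    """Find guide near-matches 5' of a PAM on both strands.

    Reports every 20-nt window (and, with ``allow_bulge``, every 19/21-nt
    window; best alignment per PAM anchor) whose mismatch count is at
    most ``max_mismatch`` and whose adjacent triplet matches the PAM
    pattern.  Hits are sorted by (mismatches, bulges, position).
    """
    if isinstance(guide, str):
        guide = GuideDesign(guide_seq=guide)
    if not 0 <= max_mismatch <= 20:
        raise ValueError("max_mismatch must be in 0..20")
    _check_dna(seq, "scanned sequence")
    seq = seq.upper()
    pam_re = _iupac_regex(guide.pam)
    n = len(guide.guide_seq)
    plen = len(guide.pam)
    L = len(seq)
    if L < n + plen:
        raise ValueError("sequence shorter than protospacer + PAM")

    hits: dict[tuple[str, int], OffTargetHit] = {}

    def _add(strand: str, start0: int, wlen: int, mismatches: int, bulges: int, strand_seq: str) -> None:
        # start0: 0-based window start on the scanned strand orientation
        window = strand_seq[start0:start0 + wlen]
        pam = strand_seq[start0 + wlen:start0 + wlen + plen]
        if strand == "+":
            plus_start = start0 + 1
        else:
            plus_start = L - (start0 + wlen) + 1
        key = (strand, start0 + wlen)  # anchor on the PAM side (scanned-strand coords)
        hit = OffTargetHit(
            seq_id=seq_id,
            protospacer_start=plus_start,
            strand=strand,
            protospacer_seq=window,
            pam_seq=pam,
            mismatches=mismatches,
            bulges=bulges,
            predicted_cut=_cut_position(plus_start, wlen, strand, guide.cut_offset),
        )
        prev = hits.get(key)
        if prev is None or (hit.bulges, hit.mismatches) < (prev.bulges, prev.mismatches):
            hits[key] = hit

    for strand, strand_seq in (("+", seq), ("-", revcomp(seq))):
        for start0, mm in _scan_strand(strand_seq, guide, max_mismatch, pam_re):
            _add(strand, start0, n, mm, 0, strand_seq)
        if allow_bulge:
            for wlen in (n - 1, n + 1):
                for pam_start in range(wlen, len(strand_seq) - plen + 1):
                    if not _pam_matches(pam_re, strand_seq[pam_start:pam_start + plen]):
                        continue
                    start0 = pam_start - wlen
                    mm, bulges, _ = bulge_alignment(guide.guide_seq, strand_seq[start0:pam_start])
                    if mm <= max_mismatch and bulges <= 1:
                        _add(strand, start0, wlen, mm, bulges, strand_seq)

    return sorted(hits.values(), key=lambda h: (h.mismatches, h.bulges, h.protospacer_start))


def _cut_position(plus_start: int, wlen: int, strand: str, cut_offset: int) -> int:
    # base immediately 5' of the blunt cut, on the protospacer strand,
    # reported as a + strand coordinate
    if strand == "+":
        return plus_start + (wlen - cut_offset) - 1
    return plus_start + cut_offset


def predict_cut_site(hit: OffTargetHit, guide: GuideDesign) -> int:
    """Blunt-cut coordinate for a hit: ``cut_offset`` bp upstream of the PAM.

    Returns the + strand coordinate of the base immediately 5' of the cut
    on the protospacer strand (for offset 3 on a + strand hit spanning
    101-120, the cut falls after position 117).
    """
    wlen = len(hit.protospacer_seq)
    if guide.cut_offset >= wlen:
        raise ValueError("cut_offset must be smaller than the protospacer length")
    return _cut_position(hit.protospacer_start, wlen, hit.strand, guide.cut_offset)


def predict_fragments(template_length: int, cut_position: int) -> tuple[int, int]:
    """Fragment lengths from one blunt cut in a linear template.

    ``cut_position`` is the last base of the left fragment; the two
    lengths always sum to the template length.
    """
    if not 1 <= cut_position < template_length:
        raise ValueError(
            f"cut position {cut_position} outside template of {template_length} bp"
        )
    return cut_position, template_length - cut_position


def find_restriction_sites(seq: str, pattern: str) -> list[int]:
    """1-based start positions of an IUPAC pattern on the + strand.

    Overlapping matches are all reported.  Used for donor-design checks
    such as locating the TfiI (GAWTC) genotyping site.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    _check_dna(seq, "sequence")
    rex = _iupac_regex(pattern)
    lookahead = re.compile(f"(?=({rex.pattern}))")
    return [m.start() + 1 for m in lookahead.finditer(seq.upper())]
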