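"""Fine-mapping of classifier score peaks to exact TSS/CPA bases.

Classifier peaks localize promoters/terminators to tens of bases; the
exact start and cleavage bases are set by local micro-motifs: the
initiator (CA, within the general YR pyrimidine-purine consensus) for
TSSs, and the (G/C)AA cleavage motif for CPA sites.  The convention used
here places the TSS at the purine (the A of CA / the R of YR) and the CPA
site at the first A of SAA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifiers import ScoreTrack
from .sequence_io import Genome, GenomicInterval, reverse_complement

__all__ = ["Peak", "call_peaks", "locate_tss", "locate_cpa"]


@dataclass(frozen=True)
class Peak:
    """A maximal above-threshold run of a strand-specific score track."""

    interval: GenomicInterval
    summit: int  # genomic base of maximal score (leftmost tie-break)
    max_score: float

    def __post_init__(self):
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the peak interval")


def call_peaks(
    track: ScoreTrack,
    threshold: float = 0.5,
    min_separation: int = 150,
    strand: str | None = None,
) -> list[Peak]:
    """Maximal runs of scores >= threshold, merged when closer than
    ``min_separation``; the summit is the (leftmost) argmax."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    peaks: list[Peak] = []
    strands = [strand] if strand else ["+", "-"]
    for chrom in track.data:
        for s in strands:
            arr = track.data[chrom][s]
            above = arr >= threshold
            if not above.any():
                continue
            d = np.diff(above.astype(np.int8))
            starts = list(np.flatnonzero(d == 1) + 1)
            ends = list(np.flatnonzero(d == -1) + 1)
            if above[0]:
                starts.insert(0, 0)
            if above[-1]:
                ends.append(len(arr))
            merged = [[starts[0], ends[0]]]
            for a, b in zip(starts[1:], ends[1:]):
                if a - merged[-1][1] < min_separation:
                    merged[-1][1] = b
                else:
                    merged.append([a, b])
            for a, b in merged:
                summit = a + int(np.argmax(arr[a:b]))
                peaks.append(
                    Peak(
                        interval=GenomicInterval(chrom, a, b, s),
                        summit=summit,
                        max_score=float(arr[summit]),
                    )
                )
    return peaks


def _oriented_matches(seq: str, strand: str, pattern_sets, site_offset: int):
    """Offsets (in transcript orientation) of pattern matches, plus the
    transcript-coordinate of the registered site base within each match."""
    s = reverse_complement(seq) if strand == "-" else seq
    w = len(pattern_sets)
    hits = []
    for i in range(len(s) - w + 1):
        if all(s[i + j] in pattern_sets[j] for j in range(w)):
            hits.append(i + site_offset)
    return hits


def _pick_site(peak: Peak, genome: Genome, candidates_by_priority) -> int:
    """Choose the candidate base nearest the summit (5'-most tie-break),
    falling back through candidate lists and finally to the summit."""
    iv = peak.interval
    seq = genome[iv.chrom][iv.start : iv.end]
    n = len(seq)
    # summit in transcript coordinates
    summit_t = (peak.summit - iv.start) if iv.strand != "-" else (iv.end - 1 - peak.summit)
    for pattern_sets, site_offset in candidates_by_priority:
        hits = _oriented_matches(seq, iv.strand, pattern_sets, site_offset)
        if hits:
            # nearest to summit; ties break 5'-most (smaller transcript coord)
            best = min(hits, key=lambda t: (abs(t - summit_t), t))
            if iv.strand == "-":
                return iv.end - 1 - best
            return iv.start + best
    return peak.summit


_CA = [({"C"}, {"A"})]
_YR = [({"C", "T"}, {"A", "G"})]
_SAA = [({"C", "G"}, {"A"}, {"A"})]


def locate_tss(peak: Peak, genome: Genome, use_yr_fallback: bool = True) -> int:
    """Exact TSS base within a peak.

    Returns the purine position of the CA initiator occurrence nearest the
    summit; if no CA, falls back to any YR occurrence; if none, the summit.
    """
    candidates = [(_CA[0], 1)]
    if use_yr_fallback:
        candidates.append((_YR[0], 1))
    return _pick_site(peak, genome, candidates)


def locate_cpa(peak: Peak, genome: Genome) -> int:
    """Exact CPA base within a peak: the first A of the (G/C)AA cleavage
    motif occurrence nearest the summit; fallback is the summit."""
    return _pick_site(peak, genome, [(_SAA[0], 1)])
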