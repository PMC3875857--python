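"""Binned sequence features around candidate TSS/CPA anchors.

Each anchor (a single base plus strand) is described by a window of signed
offsets relative to the anchor, read 5'->3' of the putative transcript (so
minus-strand windows are reverse-complemented).  The window is tiled by
contiguous bins and one value is computed per (feature, bin):

* ``motif_max_score`` -- maximum PWM log-odds of a match lying fully inside
  the bin, scanning both strands of the bin (the nucleosome-depleting
  elements these features capture act orientation-independently);
* ``base_fraction`` -- fraction of bin bases in a base set (e.g. GC);
* ``at_ratio`` -- (#A - #T)/(#A + #T) of the bin, 0 if the bin has no A/T;
* ``polyA_tract`` / ``polyT_tract`` -- longest homopolymer run in the bin;
* ``dinucleotide_property_mean`` -- mean of a dinucleotide property table
  over the bin's dinucleotide steps (a proxy for DNA structural features).

The initiation scheme covers 600 bp around the TSS (-500..+100) in six
bins with interior boundaries -300/-150/-80/-50/0; the termination scheme
covers 150 bases around the CPA site (-75..+75) in three 50-base bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import MotifModel, pfm_to_pwm, reverse_complement_pwm
from .sequence_io import Genome, GenomicInterval, TranscriptAnnotation

__all__ = [
    "BinScheme",
    "FeatureSpec",
    "FeatureVector",
    "GenomeFeaturizer",
    "extract_features",
    "default_initiation_scheme",
    "default_termination_scheme",
    "default_initiation_specs",
    "default_termination_specs",
    "make_training_sets",
    "feature_matrix",
    "PROPELLER_TWIST",
]

FEATURE_KINDS = (
    "motif_max_score",
    "base_fraction",
    "at_ratio",
    "polyA_tract",
    "polyT_tract",
    "dinucleotide_property_mean",
)

# Propeller twist (degrees) per dinucleotide step, a standard DNA-structure
# scale; used by the structure-proxy feature kind.  Users may supply their
# own tables (dict of 16 dinucleotides -> value).
PROPELLER_TWIST = {
    "AA": -18.66, "AC": -13.10, "AG": -14.00, "AT": -15.01,
    "CA": -9.45, "CC": -8.11, "CG": -10.03, "CT": -14.00,
    "GA": -13.48, "GC": -11.08, "GG": -8.11, "GT": -13.10,
    "TA": -11.85, "TC": -13.48, "TG": -9.45, "TT": -18.66,
}


@dataclass(frozen=True)
class BinScheme:
    """Window [window_start, window_end) tiled by contiguous bins."""

    window_start: int
    window_end: int
    boundaries: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "boundaries", tuple(self.boundaries))
        cuts = (self.window_start,) + self.boundaries + (self.window_end,)
        if any(a >= b for a, b in zip(cuts, cuts[1:])):
            raise ValueError("boundaries must strictly increase within the window")

    @property
    def n_bins(self) -> int:
        return len(self.boundaries) + 1

    def bins(self) -> list[tuple[int, int]]:
        cuts = (self.window_start,) + self.boundaries + (self.window_end,)
        return list(zip(cuts, cuts[1:]))

    @property
    def width(self) -> int:
        return self.window_end - self.window_start


def default_initiation_scheme() -> BinScheme:
    """Six bins over 600 bp surrounding the TSS (-500..+100)."""
    return BinScheme(-500, 100, (-300, -150, -80, -50, 0))


def default_termination_scheme() -> BinScheme:
    """Three 50-base bins over 150 bases surrounding the CPA site."""
    return BinScheme(-75, 75, (-25, 25))


@dataclass(frozen=True)
class FeatureSpec:
    """One (feature kind, bin) with kind-specific parameters."""

    name: str
    kind: str
    bin: int
    params: tuple = ()

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "motif_max_score" and not self.params:
            raise ValueError("motif_max_score needs a motif name parameter")
        if self.kind == "base_fraction" and not self.params:
            raise ValueError("base_fraction needs a base-set parameter")


@dataclass
class FeatureVector:
    """Feature values for one anchor, aligned to a FeatureSpec list."""

    anchor: GenomicInterval  # single base + strand
    values: np.ndarray
    label: str = "unlabeled"  # positive / negative / unlabeled

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.anchor) != 1:
            raise ValueError("anchor must be a single base")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")


def default_initiation_specs(
    motif_names=("Reb1", "Abf1", "Rap1", "Rsc3", "TATA"),
) -> list[FeatureSpec]:
    """Reduced promoter feature vocabulary: GRF/TATA motifs, G/C content
    and poly(dA:dT) tracts in every bin, plus the A:T ratio of the first
    100 transcribed bases (the [0,+100) bin only)."""
    scheme = default_initiation_scheme()
    specs: list[FeatureSpec] = []
    for b in range(scheme.n_bins):
        for m in motif_names:
            specs.append(FeatureSpec(f"{m}_bin{b}", "motif_max_score", b, (m,)))
        specs.append(FeatureSpec(f"GC_bin{b}", "base_fraction", b, ("GC",)))
        specs.append(FeatureSpec(f"polyA_bin{b}", "polyA_tract", b))
        specs.append(FeatureSpec(f"polyT_bin{b}", "polyT_tract", b))
    specs.append(FeatureSpec("ATratio_bin5", "at_ratio", scheme.n_bins - 1))
    return specs


def default_termination_specs(motif_names=("Hrp1",)) -> list[FeatureSpec]:
    """Terminator vocabulary: Hrp1 efficiency-element motif, G/C content
    and poly(dA:dT) tracts in each of the three bins."""
    scheme = default_termination_scheme()
    specs: list[FeatureSpec] = []
    for b in range(scheme.n_bins):
        for m in motif_names:
            specs.append(FeatureSpec(f"{m}_bin{b}", "motif_max_score", b, (m,)))
        specs.append(FeatureSpec(f"GC_bin{b}", "base_fraction", b, ("GC",)))
        specs.append(FeatureSpec(f"polyA_bin{b}", "polyA_tract", b))
        specs.append(FeatureSpec(f"polyT_bin{b}", "polyT_tract", b))
    return specs


def _run_lengths(is_base: np.ndarray) -> np.ndarray:
    """r[i] = length of the homopolymer run ending at position i."""
    r = np.zeros(len(is_base), dtype=np.int32)
    run = 0
    # vectorized: positions of run starts
    idx = np.flatnonzero(is_base)
    if len(idx) == 0:
        return r
    starts = np.flatnonzero(np.diff(idx, prepend=idx[0] - 2) > 1)
    start_pos = idx[starts]
    # for each hit, run length = idx - start of its run + 1
    run_id = np.searchsorted(start_pos, idx, side="right") - 1
    r[idx] = (idx - start_pos[run_id] + 1).astype(np.int32)
    return r


class _ChromCache:
    """Per-chromosome precomputation shared by all anchors."""

    def __init__(self, genome: Genome, chrom: str, pwms: dict[str, np.ndarray]):
        enc = genome.encoded(chrom)
        self.length = len(enc)
        # cumulative base counts, shape (4, L+1); N contributes to none
        self.cum = np.zeros((4, self.length + 1), dtype=np.int64)
        for b in range(4):
            self.cum[b, 1:] = np.cumsum(enc == b)
        self.runA = _run_lengths(enc == 0)
        self.runT = _run_lengths(enc == 3)
        # both-strand motif score per match start position
        self.motif_scores: dict[str, np.ndarray] = {}
        self.motif_width: dict[str, int] = {}
        from .motifs import scan_scores_encoded

        for name, pwm in pwms.items():
            fwd = scan_scores_encoded(enc, pwm)
            rev = scan_scores_encoded(enc, reverse_complement_pwm(pwm))
            self.motif_scores[name] = np.maximum(fwd, rev)
            self.motif_width[name] = pwm.shape[0]
        self.enc = enc
        self._dinuc_vals: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def dinuc_values(self, table_key: int, table: dict[str, float]):
        """Per-step property value arrays, forward and reverse-complement."""
        if table_key not in self._dinuc_vals:
            tab_f = np.zeros((5, 5))
            tab_r = np.zeros((5, 5))
            from .sequence_io import reverse_complement

            bases = "ACGT"
            for i, a in enumerate(bases):
                for j, b in enumerate(bases):
                    tab_f[i, j] = table[a + b]
                    tab_r[i, j] = table[reverse_complement(a + b)]
            a, b = self.enc[:-1].astype(int), self.enc[1:].astype(int)
            self._dinuc_vals[table_key] = (tab_f[a, b], tab_r[a, b])
        return self._dinuc_vals[table_key]


_BASESET = {"A": (0,), "C": (1,), "G": (2,), "T": (3,), "GC": (1, 2),
            "AT": (0, 3), "AG": (0, 2), "CT": (1, 3)}
_COMP_SET = {0: 3, 1: 2, 2: 1, 3: 0}


class GenomeFeaturizer:
    """Vectorized feature extraction over many anchors of one genome.

    Precomputes per-chromosome motif score arrays, cumulative base counts
    and homopolymer run lengths, then evaluates all (feature, bin) values
    for arrays of anchor positions on either strand.
    """

    def __init__(
        self,
        genome: Genome,
        scheme: BinScheme,
        specs: list[FeatureSpec],
        motif_library: dict[str, MotifModel],
        property_tables: dict[str, dict[str, float]] | None = None,
    ):
        self.genome = genome
        self.scheme = scheme
        self.specs = list(specs)
        self.property_tables = dict(property_tables or {"propeller_twist": PROPELLER_TWIST})
        needed = {s.params[0] for s in specs if s.kind == "motif_max_score"}
        missing = needed - set(motif_library)
        if missing:
            raise KeyError(f"unknown motif name(s): {sorted(missing)}")
        self.pwms = {name: pfm_to_pwm(motif_library[name]) for name in needed}
        self._caches: dict[str, _ChromCache] = {}
        self._bins = scheme.bins()

    def _cache(self, chrom: str) -> _ChromCache:
        if chrom not in self._caches:
            self._caches[chrom] = _ChromCache(self.genome, chrom, self.pwms)
        return self._caches[chrom]

    def valid_anchor_range(self, chrom: str, strand: str) -> tuple[int, int]:
        """Half-open range of anchor positions whose window fits."""
        L = self.genome.length(chrom)
        ws, we = self.scheme.window_start, self.scheme.window_end
        if strand == "+":
            return max(0, -ws), min(L, L - we + 1)
        return max(0, we - 1), min(L, L + ws)

    def _check_anchors(self, chrom: str, positions: np.ndarray, strand: str):
        lo, hi = self.valid_anchor_range(chrom, strand)
        if len(positions) and (positions.min() < lo or positions.max() >= hi):
            raise ValueError(
                f"anchor window out of bounds on {chrom} {strand} "
                f"(valid anchors [{lo}, {hi}))"
            )

    def features_for_anchors(
        self, chrom: str, positions, strand: str
    ) -> np.ndarray:
        """Feature matrix (n_anchors x n_specs) for anchors on one strand."""
        P = np.asarray(positions, dtype=np.int64)
        self._check_anchors(chrom, P, strand)
        cache = self._cache(chrom)
        out = np.empty((len(P), len(self.specs)))
        for k, spec in enumerate(self.specs):
            o1, o2 = self._bins[spec.bin]
            if strand == "+":
                a = P + o1  # genomic span [a, a + w)
            else:
                a = P - o2 + 1
            w = o2 - o1
            out[:, k] = self._eval(spec, cache, a, w, strand)
        return out

    def _eval(self, spec, cache, a, w, strand):
        kind = spec.kind
        if kind == "motif_max_score":
            name = spec.params[0]
            mw = cache.motif_width[name]
            k = w - mw + 1
            if k <= 0:
                return np.full(len(a), cache.motif_scores[name].min(initial=0.0))
            idx = a[:, None] + np.arange(k)
            return cache.motif_scores[name][idx].max(axis=1)
        if kind == "base_fraction":
            bases = _BASESET[spec.params[0]]
            if strand == "-":
                bases = tuple(_COMP_SET[b] for b in bases)
            count = np.zeros(len(a), dtype=np.int64)
            for b in bases:
                count += cache.cum[b, a + w] - cache.cum[b, a]
            return count / w
        if kind == "at_ratio":
            nA = cache.cum[0, a + w] - cache.cum[0, a]
            nT = cache.cum[3, a + w] - cache.cum[3, a]
            if strand == "-":
                nA, nT = nT, nA
            denom = nA + nT
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(denom > 0, (nA - nT) / np.maximum(denom, 1), 0.0)
            return r
        if kind in ("polyA_tract", "polyT_tract"):
            want_A = kind == "polyA_tract"
            if strand == "-":
                want_A = not want_A
            runs = cache.runA if want_A else cache.runT
            idx = a[:, None] + np.arange(w)
            vals = np.minimum(runs[idx], np.arange(1, w + 1))
            return vals.max(axis=1).astype(float)
        if kind == "dinucleotide_property_mean":
            table_name = spec.params[0] if spec.params else "propeller_twist"
            table = self.property_tables[table_name]
            vf, vr = cache.dinuc_values(id(table), table)
            vals = vf if strand == "+" else vr
            # steps (i, i+1) for i in [a, a + w - 1)
            csum = np.concatenate([[0.0], np.cumsum(vals)])
            return (csum[a + w - 1] - csum[a]) / (w - 1)
        raise AssertionError(kind)

    def spec_names(self) -> list[str]:
        return [s.name for s in self.specs]


def extract_features(
    genome: Genome,
    anchor: GenomicInterval,
    scheme: BinScheme,
    specs: list[FeatureSpec],
    motif_library: dict[str, MotifModel],
    label: str = "unlabeled",
    featurizer: GenomeFeaturizer | None = None,
) -> FeatureVector:
    """Feature vector for a single anchor (base + strand).

    Raises ValueError when the window does not fit the chromosome and
    KeyError for unknown motif names.
    """
    if featurizer is None:
        featurizer = GenomeFeaturizer(genome, scheme, specs, motif_library)
    vals = featurizer.features_for_anchors(
        anchor.chrom, [anchor.start], anchor.strand
    )[0]
    return FeatureVector(anchor=anchor, values=vals, label=label)


# ---------------------------------------------------------------------------
# Training sets


def _tile_anchors(lo: int, hi: int, stride: int) -> np.ndarray:
    """Anchor positions tiling [lo, hi) with the given stride."""
    if hi <= lo:
        return np.array([], dtype=np.int64)
    return np.arange(lo, hi, stride, dtype=np.int64)


@dataclass
class AnchorSet:
    """Labeled anchors on one genome (inputs to featurization)."""

    anchors: list[GenomicInterval]
    label: str


def make_training_sets(
    genome: Genome,
    annotations: list[TranscriptAnnotation],
    initiation_scheme: BinScheme | None = None,
    termination_scheme: BinScheme | None = None,
    initiation_stride: int = 300,
    termination_stride: int = 75,
) -> tuple[AnchorSet, AnchorSet, AnchorSet, AnchorSet]:
    """Positive/negative anchors for the initiation and termination
    classifiers.

    Initiation positives sit at annotated TSS bases; negatives tile the
    genome in overlapping windows (half-window stride) whose windows do not
    overlap any positive's window.  Termination positives sit at CPA bases;
    negatives tile transcript bodies excluding the CPA window.
    """
    ischeme = initiation_scheme or default_initiation_scheme()
    tscheme = termination_scheme or default_termination_scheme()

    init_pos, term_pos = [], []
    for a in annotations:
        init_pos.append(GenomicInterval(a.chrom, a.tss_site, a.tss_site + 1, a.strand))
        term_pos.append(GenomicInterval(a.chrom, a.cpa_site, a.cpa_site + 1, a.strand))

    def window_span(scheme, pos, strand):
        if strand == "+":
            return pos + scheme.window_start, pos + scheme.window_end
        return pos - scheme.window_end + 1, pos - scheme.window_start + 1

    # exclusion spans of positive windows, per chrom (strand-agnostic:
    # a negative must not overlap any promoter window on either strand)
    excl: dict[str, list[tuple[int, int]]] = {}
    for iv in init_pos:
        excl.setdefault(iv.chrom, []).append(
            window_span(ischeme, iv.start, iv.strand)
        )

    init_neg = []
    for chrom in genome:
        L = genome.length(chrom)
        spans = excl.get(chrom, [])
        for strand in "+-":
            if strand == "+":
                lo, hi = -ischeme.window_start, L - ischeme.window_end + 1
            else:
                lo, hi = ischeme.window_end - 1, L + ischeme.window_start + 1
            for p in _tile_anchors(lo, hi, initiation_stride):
                ws, we = window_span(ischeme, int(p), strand)
                if all(we <= s or e <= ws for s, e in spans):
                    init_neg.append(GenomicInterval(chrom, int(p), int(p) + 1, strand))

    term_neg = []
    for a in annotations:
        iv = a.interval
        cw = window_span(tscheme, a.cpa_site, a.strand)
        # anchors within the transcript body whose window fits inside it
        if a.strand == "+":
            lo = iv.start - tscheme.window_start
            hi = iv.end - tscheme.window_end + 1
        else:
            lo = iv.start + tscheme.window_end - 1
            hi = iv.end + tscheme.window_start + 1
        for p in _tile_anchors(lo, hi, termination_stride):
            ws, we = window_span(tscheme, int(p), a.strand)
            if we <= cw[0] or cw[1] <= ws:
                term_neg.append(GenomicInterval(iv.chrom, int(p), int(p) + 1, a.strand))

    return (
        AnchorSet(init_pos, "positive"),
        AnchorSet(init_neg, "negative"),
        AnchorSet(term_pos, "positive"),
        AnchorSet(term_neg, "negative"),
    )


def feature_matrix(
    genome: Genome,
    anchor_sets: list[AnchorSet],
    scheme: BinScheme,
    specs: list[FeatureSpec],
    motif_library: dict[str, MotifModel],
) -> pd.DataFrame:
    """Featurize labeled anchors into a tidy table.

    Columns: chrom, pos, strand, label, then one column per FeatureSpec.
    """
    fz = GenomeFeaturizer(genome, scheme, specs, motif_library)
    frames = []
    for aset in anchor_sets:
        by_key: dict[tuple[str, str], list[int]] = {}
        for iv in aset.anchors:
            by_key.setdefault((iv.chrom, iv.strand), []).append(iv.start)
        for (chrom, strand), positions in by_key.items():
            pos = np.asarray(positions)
            X = fz.features_for_anchors(chrom, pos, strand)
            df = pd.DataFrame(X, columns=fz.spec_names())
            df.insert(0, "label", aset.label)
            df.insert(0, "strand", strand)
            df.insert(0, "pos", pos)
            df.insert(0, "chrom", chrom)
            frames.append(df)
    if not frames:
        cols = ["chrom", "pos", "strand", "label"] + [s.name for s in specs]
        return pd.DataFrame(columns=cols)
    return pd.concat(frames, ignore_index=True)
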