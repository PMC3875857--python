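"""Synthetic genomes, expression tracks, promoter libraries and sort-seq.

Everything the pipeline needs can be generated without downloads:

* random genomes at a stated base composition (default 38% G/C, matching
  the yeast genome) with implanted promoter and terminator grammars and
  full ground truth (transcript annotations plus an 8-state map);
* noisy per-base expression tracks over the true transcripts;
* the combinatorial promoter-library design procedure (random segments,
  embedded TFBSs, scoring of all combinations, disrupted controls);
* sort-seq bin-count simulation and the weighted-mean expression
  estimator;
* pseudo-random 3-kb fragment design with inserted consensus sites.

Promoter grammar (offsets 5'->3' relative to the TSS): one GRF binding
site and a poly-dA tract of length 10-20 in the [-150, -80) window, an
optional TATA box in [-80, -50), and a CA initiator with its A at the
TSS.  Competing CA dinucleotides within +/-40 bp of the initiator are
scrubbed so the implanted initiator is the locally dominant YR over the
initiation classifier's ~70-bp positional resolution, as at real
promoters where the initiator dominates the start-site neighbourhood.
Terminator grammar: 2-4 TATATA Hrp1 sites within 60 bp upstream of the
CPA site inside an AT-rich (~75% A+T) 150-bp window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .motifs import MotifModel, builtin_motifs, sample_site
from .sequence_io import (
    Genome,
    StateMap,
    TranscriptAnnotation,
    build_state_map,
    decode_sequence,
    encode_sequence,
    reverse_complement,
)

__all__ = [
    "YEAST_COMPOSITION",
    "SyntheticGenomeSpec",
    "GeneDesign",
    "LibraryDesign",
    "SegmentSpec",
    "SortSeqCounts",
    "generate_random_genome",
    "simulate_expression",
    "design_promoter_library",
    "make_library_scorer",
    "simulate_sortseq_counts",
    "estimate_sortseq_expression",
    "design_random_fragment",
]

#: A/C/G/T probabilities giving 38% G/C, the yeast genome's composition.
YEAST_COMPOSITION = np.array([0.31, 0.19, 0.19, 0.31])


@dataclass
class GeneDesign:
    """Placement and element inventory of one implanted gene."""

    chrom: str
    tss: int  # exact TSS base (genomic)
    cpa: int  # exact CPA base (genomic)
    strand: str
    grf: str = "Reb1"
    tract_length: int = 15
    has_tata: bool = True
    n_hrp1: int = 3


@dataclass
class SyntheticGenomeSpec:
    """Recipe for a random genome with implanted transcript grammars."""

    length: int = 60_000
    n_chromosomes: int = 1
    composition: np.ndarray = field(default_factory=lambda: YEAST_COMPOSITION.copy())
    n_genes: int | None = None  # per chromosome; None with explicit designs
    genes: list[GeneDesign] | None = None
    tata_probability: float = 0.7
    convergent_fraction: float = 0.4
    seed: int = 0

    def __post_init__(self):
        self.composition = np.asarray(self.composition, dtype=float)
        if abs(self.composition.sum() - 1.0) > 1e-6:
            raise ValueError("composition must sum to 1")
        if self.genes is None and self.n_genes is None:
            self.n_genes = max(1, self.length // 2000)


_PROMOTER_MARGIN = 170  # grammar extends to -160; keep a little slack
_TERMINATOR_WINDOW = 150


def _sample_layout(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> list[GeneDesign]:
    """Random non-overlapping gene placements on every chromosome.

    A fraction of genes (``convergent_fraction``) is laid out as convergent
    pairs whose CPA regions overlap by a few bases, producing the shared
    bidirectional terminator (Term) configuration seen between convergent
    yeast genes.
    """
    grf_names = ["Reb1", "Abf1", "Rap1", "Rsc3"]
    designs: list[GeneDesign] = []

    def _one(chrom, tss, cpa, strand):
        return GeneDesign(
            chrom=chrom,
            tss=tss,
            cpa=cpa,
            strand=strand,
            grf=grf_names[int(rng.integers(len(grf_names)))],
            tract_length=int(rng.integers(10, 21)),
            has_tata=bool(rng.random() < spec.tata_probability),
            n_hrp1=int(rng.integers(2, 5)),
        )

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        pos = 700  # leave room for the upstream half of the scoring window
        placed = 0
        while placed < spec.n_genes:
            body = int(rng.integers(500, 901))
            if pos + body + 700 > spec.length:
                break
            make_pair = (
                rng.random() < spec.convergent_fraction
                and placed + 1 < spec.n_genes
            )
            if make_pair:
                body2 = int(rng.integers(500, 901))
                delta = int(rng.integers(-8, 9))
                cpa2 = pos + body + delta
                tss2 = cpa2 + body2
                if tss2 + 700 > spec.length:
                    break
                designs.append(_one(chrom, pos, pos + body, "+"))
                designs.append(_one(chrom, tss2, cpa2, "-"))
                placed += 2
                pos = tss2 + int(rng.integers(650, 1000))
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "+":
                    tss, cpa = pos, pos + body
                else:
                    tss, cpa = pos + body, pos
                designs.append(_one(chrom, tss, cpa, strand))
                placed += 1
                pos += body + int(rng.integers(650, 1000))
    return designs


def _write_oriented(chrom_arr: np.ndarray, genomic_start: int, seq: str, strand: str):
    """Write ``seq`` (transcript orientation) into the genome array.

    For '+', ``genomic_start`` is the leftmost base; for '-', the sequence
    is reverse-complemented and ``genomic_start`` is still its leftmost
    genomic base after placement.
    """
    if strand == "-":
        seq = reverse_complement(seq)
    chrom_arr[genomic_start : genomic_start + len(seq)] = encode_sequence(seq)


def _tx2genomic(tss: int, strand: str, offset: int) -> int:
    """Genomic position of a transcript-oriented offset from the TSS."""
    return tss + offset if strand == "+" else tss - offset


def _implant_gene(
    chrom_arr: np.ndarray,
    g: GeneDesign,
    motif_lib: dict[str, MotifModel],
    rng: np.random.Generator,
    at_rich: np.ndarray,
):
    """Implant promoter and terminator elements for one gene."""
    strand = g.strand

    def write_at(offset: int, seq: str):
        # offset is transcript-oriented relative to the TSS and names the
        # 5'-most base of seq
        if strand == "+":
            _write_oriented(chrom_arr, g.tss + offset, seq, "+")
        else:
            _write_oriented(chrom_arr, g.tss - offset - len(seq) + 1, seq, "-")

    # GRF site at -145, poly-dA tract at -128, optional TATA at -70
    site = sample_site(motif_lib[g.grf], rng)
    write_at(-145, site)
    write_at(-128, "A" * g.tract_length)
    if g.has_tata:
        write_at(-70, "TATAAA")
    # CA initiator: A at offset 0
    write_at(-2, "TCAT")
    _scrub_initiator_neighborhood(chrom_arr, g)

    # terminator: AT-rich 150-bp window ending at the CPA site
    win = decode_sequence(
        np.searchsorted(np.cumsum(at_rich), rng.random(_TERMINATOR_WINDOW)).astype(
            np.uint8
        )
    )
    if strand == "+":
        _write_oriented(chrom_arr, g.cpa - _TERMINATOR_WINDOW + 1, win, "+")
    else:
        _write_oriented(chrom_arr, g.cpa, win, "-")
    # 2-4 Hrp1 TATATA sites within 60 bp upstream of the CPA, non-overlapping
    slots = np.arange(-60, -6, 7)
    chosen = rng.choice(len(slots), size=min(g.n_hrp1, len(slots)), replace=False)
    for k in sorted(chosen):
        off = int(slots[k])
        if strand == "+":
            _write_oriented(chrom_arr, g.cpa + off, "TATATA", "+")
        else:
            _write_oriented(chrom_arr, g.cpa - off - 6 + 1, "TATATA", "-")


def _scrub_initiator_neighborhood(chrom_arr: np.ndarray, g: GeneDesign, radius: int = 40):
    """Mutate the A of any competing CA within +/-radius of the initiator."""
    strand = g.strand
    for off in range(-radius, radius):
        if off in (-1,):
            continue  # the implanted initiator C at -1 / A at 0
        p_c = _tx2genomic(g.tss, strand, off)
        p_a = _tx2genomic(g.tss, strand, off + 1)
        if strand == "+":
            is_ca = chrom_arr[p_c] == 1 and chrom_arr[p_a] == 0
        else:
            # transcript C = genomic G, transcript A = genomic T
            is_ca = chrom_arr[p_c] == 2 and chrom_arr[p_a] == 3
        if is_ca and off + 1 != 0:
            chrom_arr[p_a] = 3 if strand == "+" else 0  # A -> T (transcript frame)


def generate_random_genome(
    spec: SyntheticGenomeSpec,
    motif_library: dict[str, MotifModel] | None = None,
) -> tuple[Genome, list[TranscriptAnnotation], StateMap]:
    """Generate a random genome with implanted genes and ground truth.

    Background bases are i.i.d. at ``spec.composition``; each gene gets the
    promoter/terminator grammar described in the module docstring.  Ground
    truth is returned both as transcript annotations (site regions widened
    to the standard 26/36-bp spreads) and as the derived 8-state map.
    """
    rng = np.random.default_rng(spec.seed)
    motif_lib = motif_library or builtin_motifs(background=spec.composition)
    chrom_arrays: dict[str, np.ndarray] = {}
    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cum = np.cumsum(spec.composition)
        chrom_arrays[chrom] = np.searchsorted(cum, rng.random(spec.length)).astype(
            np.uint8
        )
    designs = spec.genes if spec.genes is not None else _sample_layout(spec, rng)

    # check for overlapping implants (3'-end overlaps of convergent pairs
    # are the shared-terminator configuration and are allowed)
    spans: dict[str, list[tuple[int, int, GeneDesign]]] = {}
    for g in designs:
        lo, hi = sorted((g.tss, g.cpa))
        lo -= _PROMOTER_MARGIN
        hi += _PROMOTER_MARGIN
        for s, e, other in spans.get(g.chrom, []):
            if lo < e and s < hi:
                convergent = g.strand != other.strand and abs(g.cpa - other.cpa) <= 50
                if not convergent:
                    raise ValueError(f"overlapping implants on {g.chrom}")
        spans.setdefault(g.chrom, []).append((lo, hi, g))

    at_rich = np.array([0.375, 0.125, 0.125, 0.375])
    annotations: list[TranscriptAnnotation] = []
    for i, g in enumerate(designs):
        if g.chrom not in chrom_arrays:
            raise ValueError(f"unknown chromosome {g.chrom!r} in gene design")
        _implant_gene(chrom_arrays[g.chrom], g, motif_lib, rng, at_rich)
        annotations.append(
            TranscriptAnnotation.from_points(
                id=f"gene{i + 1}",
                chrom=g.chrom,
                strand=g.strand,
                tss=g.tss,
                cpa=g.cpa,
                chrom_length=len(chrom_arrays[g.chrom]),
            )
        )
    genome = Genome({c: decode_sequence(a) for c, a in chrom_arrays.items()})
    state_map = build_state_map(annotations, genome)
    return genome, annotations, state_map


def simulate_expression(
    annotations: list[TranscriptAnnotation],
    chrom_lengths: dict[str, int],
    rng: np.random.Generator,
    log_mean: float = 1.0,
    log_sigma: float = 1.0,
    noise_sigma: float = 0.2,
) -> dict[str, np.ndarray]:
    """Noisy per-base expression over the true transcripts.

    Each transcript draws a log-normal abundance; per-base expression is
    the sum of overlapping transcript abundances with multiplicative
    log-normal noise (``noise_sigma=0`` turns noise off); zero elsewhere.
    """
    track = {c: np.zeros(n) for c, n in chrom_lengths.items()}
    for a in annotations:
        abundance = float(rng.lognormal(log_mean, log_sigma))
        track[a.chrom][a.interval.start : a.interval.end] += abundance
    if noise_sigma > 0:
        for c, arr in track.items():
            nz = arr > 0
            arr[nz] *= rng.lognormal(0.0, noise_sigma, size=int(nz.sum()))
    return track


# ---------------------------------------------------------------------------
# Combinatorial promoter library


@dataclass
class SegmentSpec:
    """One positional segment set of the promoter library."""

    name: str  # e.g. "-150:-80"
    length: int
    n_candidates: int
    n_select: int
    motif_names: tuple[str, ...] = ()  # TFBSs relevant in this position


@dataclass
class LibrarySegment:
    name: str
    sequence: str
    motif: str | None = None  # embedded TFBS, if any
    motif_offset: int | None = None
    control_sequence: str | None = None  # TFBS-disrupted partner
    mean_score: float = float("nan")


@dataclass
class LibraryDesign:
    """Selected segments per position plus disrupted-control pairing."""

    segments: dict[str, list[LibrarySegment]]

    @property
    def n_combinations(self) -> int:
        n = 1
        for segs in self.segments.values():
            n *= len(segs)
        return n

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pos_name, segs in self.segments.items():
            for i, s in enumerate(segs):
                rows.append(
                    {
                        "position": pos_name,
                        "segment": i,
                        "sequence": s.sequence,
                        "motif": s.motif or "",
                        "motif_offset": -1 if s.motif_offset is None else s.motif_offset,
                        "control_sequence": s.control_sequence or "",
                        "mean_score": s.mean_score,
                    }
                )
        return pd.DataFrame(rows)


def _disrupt_motif(site: str, motif: MotifModel, n_positions: int = 3) -> str:
    """Mutate the motif's highest-information positions to its
    lowest-probability base."""
    ic = motif.information_content()
    order = np.argsort(ic)[::-1][:n_positions]
    bases = "ACGT"
    chars = list(site)
    for j in sorted(int(x) for x in order):
        worst = int(motif.pfm[j].argmin())
        if bases[worst] == chars[j]:
            worst = int(np.argsort(motif.pfm[j])[1])
        chars[j] = bases[worst]
    return "".join(chars)


def design_promoter_library(
    segment_specs: list[SegmentSpec],
    motif_library: dict[str, MotifModel],
    scorer,
    rng: np.random.Generator,
    composition: np.ndarray | None = None,
) -> LibraryDesign:
    """Design a combinatorial promoter library.

    Random candidate segments are generated at varying G/C content, TFBSs
    are embedded by sampling sites from their PFMs, every full-length
    combination is scored by ``scorer`` (a callable mapping a list of
    assembled promoter sequences, TSS at a fixed offset, to initiation
    scores — see :func:`make_library_scorer`), and the top-scoring segments
    in each position (by mean score over all combinations they appear in)
    are retained.  Each TFBS-bearing segment gets a control identical
    except for disruption of the site at its highest-information bases.
    """
    if len(segment_specs) < 1:
        raise ValueError("need at least one segment spec")
    comp = YEAST_COMPOSITION if composition is None else np.asarray(composition)

    candidates: list[list[LibrarySegment]] = []
    for spec in segment_specs:
        segs = []
        for i in range(spec.n_candidates):
            # vary G/C content across candidates
            gc = float(rng.uniform(0.2, 0.6))
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            seq = decode_sequence(
                np.searchsorted(np.cumsum(p), rng.random(spec.length)).astype(np.uint8)
            )
            motif_name = None
            offset = None
            control = None
            if spec.motif_names and rng.random() < 0.75:
                motif_name = spec.motif_names[int(rng.integers(len(spec.motif_names)))]
                motif = motif_library[motif_name]
                site = sample_site(motif, rng)
                offset = int(rng.integers(0, spec.length - motif.width + 1))
                seq = seq[:offset] + site + seq[offset + motif.width :]
                control = (
                    seq[:offset] + _disrupt_motif(site, motif) + seq[offset + motif.width :]
                )
            segs.append(
                LibrarySegment(
                    name=f"{spec.name}_{i}",
                    sequence=seq,
                    motif=motif_name,
                    motif_offset=offset,
                    control_sequence=control,
                )
            )
        candidates.append(segs)

    # score all combinations
    shapes = [len(c) for c in candidates]
    combos = np.stack(
        [g.ravel() for g in np.meshgrid(*[np.arange(n) for n in shapes], indexing="ij")]
    ).T
    seqs = [
        "".join(candidates[k][combo[k]].sequence for k in range(len(candidates)))
        for combo in combos
    ]
    scores = np.asarray(scorer(seqs), dtype=float)
    if len(scores) != len(seqs):
        raise ValueError("scorer must return one score per combination")

    selected: dict[str, list[LibrarySegment]] = {}
    for k, spec in enumerate(segment_specs):
        means = np.array(
            [scores[combos[:, k] == i].mean() for i in range(shapes[k])]
        )
        order = np.argsort(means)[::-1][: spec.n_select]
        if means[order[0]] <= 0:
            raise ValueError(f"no candidate exceeds the score floor in {spec.name}")
        chosen = []
        for i in order:
            seg = candidates[k][int(i)]
            seg.mean_score = float(means[int(i)])
            chosen.append(seg)
        selected[spec.name] = chosen
    return LibraryDesign(segments=selected)


def make_library_scorer(
    ensemble,
    scheme,
    specs,
    motif_library,
    context_length: int = 1400,
    seed: int = 12345,
    tss_offset_in_construct: int = 150,
):
    """Scorer for :func:`design_promoter_library`.

    Embeds each assembled construct (covering [-150, +80) around its TSS)
    at a fixed position in a neutral random context and returns the
    initiation-classifier score at the TSS anchor.
    """
    from .features import GenomeFeaturizer

    rng = np.random.default_rng(seed)
    cum = np.cumsum(YEAST_COMPOSITION)

    def scorer(seqs: list[str]) -> np.ndarray:
        # one long scaffold chromosome holding every construct
        spacing = context_length + max(len(s) for s in seqs)
        total = spacing * len(seqs) + context_length
        arr = np.searchsorted(cum, rng.random(total)).astype(np.uint8)
        anchors = []
        for i, s in enumerate(seqs):
            start = context_length // 2 + i * spacing
            arr[start : start + len(s)] = encode_sequence(s)
            anchors.append(start + tss_offset_in_construct)
        genome = Genome({"lib": decode_sequence(arr)})
        fz = GenomeFeaturizer(genome, scheme, specs, motif_library)
        X = fz.features_for_anchors("lib", np.asarray(anchors), "+")
        return ensemble.predict_matrix(X)

    return scorer


# ---------------------------------------------------------------------------
# Sort-seq


@dataclass
class SortSeqCounts:
    """Per-construct read counts across fluorescence bins."""

    counts: pd.DataFrame  # constructs x bins, non-negative
    bin_fluorescence: np.ndarray  # mean log-fluorescence per bin

    def __post_init__(self):
        self.bin_fluorescence = np.asarray(self.bin_fluorescence, dtype=float)
        if self.counts.shape[1] != len(self.bin_fluorescence):
            raise ValueError("one fluorescence value per bin required")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def simulate_sortseq_counts(
    expression: np.ndarray,
    rng: np.random.Generator,
    n_bins: int = 6,
    reads_per_construct: int = 200,
    sort_noise: float = 0.3,
    construct_ids: list[str] | None = None,
) -> SortSeqCounts:
    """Simulate sorting constructs into log-spaced fluorescence bins.

    Each construct's cells fluoresce log-normally around its expression
    level and are counted in whichever of the ``n_bins`` log-spaced bins
    they fall into.
    """
    expression = np.asarray(expression, dtype=float)
    lo, hi = np.log(expression.min() / 3 + 1e-9), np.log(expression.max() * 3)
    edges = np.linspace(lo, hi, n_bins + 1)
    centers = np.exp(0.5 * (edges[:-1] + edges[1:]))
    rows = []
    for x in expression:
        cells = np.log(x) + sort_noise * rng.standard_normal(reads_per_construct)
        which = np.clip(np.digitize(cells, edges) - 1, 0, n_bins - 1)
        rows.append(np.bincount(which, minlength=n_bins))
    ids = construct_ids or [f"construct{i}" for i in range(len(expression))]
    df = pd.DataFrame(rows, index=ids, columns=[f"bin{b + 1}" for b in range(n_bins)])
    return SortSeqCounts(counts=df, bin_fluorescence=centers)


def estimate_sortseq_expression(counts: SortSeqCounts) -> pd.Series:
    """Per-construct expression: bin-membership-weighted mean fluorescence.

    expression = sum_b (count_b / total) * mean_fluorescence_b.
    """
    mat = counts.counts.to_numpy(float)
    totals = mat.sum(axis=1)
    if (totals == 0).any():
        bad = counts.counts.index[totals == 0].tolist()
        raise ValueError(f"construct(s) with zero total count: {bad}")
    return pd.Series(
        (mat / totals[:, None]) @ counts.bin_fluorescence,
        index=counts.counts.index,
        name="expression",
    )


# ---------------------------------------------------------------------------
# Pseudo-random fragment design


def design_random_fragment(
    length: int,
    gc_target: float,
    site_counts: dict[str, int],
    rng: np.random.Generator,
    motif_library: dict[str, MotifModel] | None = None,
    max_tries: int = 1000,
) -> tuple[str, list[tuple[str, int, str]]]:
    """A random fragment with consensus binding sites inserted.

    Background bases are i.i.d. at the G/C target; for each named factor
    the requested number of consensus sites is inserted at uniform random
    non-overlapping positions on random strands.  Returns the sequence and
    an inventory of (factor, position, strand).
    """
    motif_lib = motif_library or builtin_motifs()
    p = np.array([(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2])
    arr = np.searchsorted(np.cumsum(p), rng.random(length)).astype(np.uint8)
    occupied: list[tuple[int, int]] = []
    inventory: list[tuple[str, int, str]] = []
    for name, count in site_counts.items():
        site = motif_lib[name].consensus()
        w = len(site)
        for _ in range(count):
            for _try in range(max_tries):
                pos = int(rng.integers(0, length - w + 1))
                if all(pos + w <= s or e <= pos for s, e in occupied):
                    break
            else:
                raise ValueError("infeasible site packing")
            strand = "+" if rng.random() < 0.5 else "-"
            seq = site if strand == "+" else reverse_complement(site)
            arr[pos : pos + w] = encode_sequence(seq)
            occupied.append((pos, pos + w))
            inventory.append((name, pos, strand))
    return decode_sequence(arr), inventory
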