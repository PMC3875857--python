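"""Genome and annotation I/O, coordinate conventions, and per-base state maps.

Coordinates are 0-based half-open throughout the package.  BED is read and
written 0-based half-open; GFF3 is read 1-based inclusive and converted on
input.  Strands are "+", "-", or "." (unstranded).

The 8-state alphabet used by the unified transcript model labels every base
of a genome as intergenic (IG), a transcription start site region, a
transcript body, or a cleavage/polyadenylation region on either strand, or a
bidirectional terminator (Term) shared by convergent transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "STATES",
    "STATE_INDEX",
    "Genome",
    "GenomicInterval",
    "TranscriptAnnotation",
    "StateMap",
    "load_genome",
    "write_genome",
    "reverse_complement",
    "encode_sequence",
    "decode_sequence",
    "build_state_map",
    "read_bed6",
    "write_bed6",
    "read_transcripts_gff3",
    "write_transcripts_gff3",
    "DEFAULT_TSS_WIDTH",
    "DEFAULT_CPA_WIDTH",
]

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# States: intergenic, then the forward-strand transcript cycle, the
# reverse-strand cycle, and the bidirectional terminator.
STATES = ("IG", "TSS+", "Gene+", "CPA+", "TSS-", "Gene-", "CPA-", "Term")
STATE_INDEX = {s: i for i, s in enumerate(STATES)}

# Multi-base site spans: TSS positions vary over ~26 bp and cleavage occurs
# over ~36 bases, so single-base annotations are widened to these defaults.
DEFAULT_TSS_WIDTH = 26
DEFAULT_CPA_WIDTH = 36

_BASE_TO_INT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _BASE_TO_INT[ord(_b)] = _i
_INT_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A,C,G,T,N as uint8 codes 0..4."""
    arr = _BASE_TO_INT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        raise ValueError("illegal characters in sequence")
    return arr


def decode_sequence(codes: np.ndarray) -> str:
    return _INT_TO_BASE[codes].tobytes().decode("ascii")


class Genome:
    """Named DNA sequences (uppercase, alphabet {A,C,G,T,N})."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("genome has no sequences")
        clean: dict[str, str] = {}
        for name, seq in sequences.items():
            if name in clean:
                raise ValueError(f"duplicate sequence name {name!r}")
            seq = seq.upper()
            if not seq:
                raise ValueError(f"empty sequence {name!r}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains illegal characters {sorted(bad)}"
                )
            clean[name] = seq
        self.sequences = clean
        self._encoded: dict[str, np.ndarray] = {}

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def length(self, name: str) -> int:
        return len(self.sequences[name])

    def encoded(self, name: str) -> np.ndarray:
        """Integer-encoded sequence, cached per chromosome."""
        if name not in self._encoded:
            self._encoded[name] = encode_sequence(self.sequences[name])
        return self._encoded[name]

    def composition(self) -> np.ndarray:
        """Genome-wide base probabilities (A,C,G,T), ignoring N."""
        counts = np.zeros(4, dtype=float)
        for name in self:
            enc = self.encoded(name)
            counts += np.bincount(enc[enc < 4], minlength=4)
        total = counts.sum()
        if total == 0:
            return np.full(4, 0.25)
        return counts / total

    def reverse_complemented(self) -> "Genome":
        return Genome({n: reverse_complement(s) for n, s in self.sequences.items()})


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open stranded interval on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def sequence(self, genome: Genome) -> str:
        """Strand-oriented sequence (reverse-complemented for '-')."""
        seq = genome[self.chrom][self.start : self.end]
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class TranscriptAnnotation:
    """A single-interval transcript with TSS and CPA site regions.

    ``tss_region`` and ``cpa_region`` are ranges (not single bases) at the
    transcript's 5' and 3' ends.  ``tss_site``/``cpa_site`` optionally record
    the exact base (defaulting to the region midpoint).
    """

    id: str
    interval: GenomicInterval
    tss_region: GenomicInterval
    cpa_region: GenomicInterval
    tss_site: int | None = None
    cpa_site: int | None = None

    def __post_init__(self):
        iv = self.interval
        for r in (self.tss_region, self.cpa_region):
            if r.chrom != iv.chrom or r.strand != iv.strand:
                raise ValueError(f"{self.id}: inconsistent chrom/strand in regions")
            if r.start < iv.start or r.end > iv.end:
                raise ValueError(f"{self.id}: region outside transcript interval")
        if iv.strand == "+":
            if self.tss_region.start != iv.start or self.cpa_region.end != iv.end:
                raise ValueError(f"{self.id}: TSS/CPA regions must flank the transcript")
        elif iv.strand == "-":
            if self.tss_region.end != iv.end or self.cpa_region.start != iv.start:
                raise ValueError(f"{self.id}: TSS/CPA regions must flank the transcript")
        else:
            raise ValueError(f"{self.id}: transcript must be stranded")
        if self.tss_site is None:
            object.__setattr__(
                self, "tss_site", (self.tss_region.start + self.tss_region.end) // 2
            )
        if self.cpa_site is None:
            object.__setattr__(
                self, "cpa_site", (self.cpa_region.start + self.cpa_region.end) // 2
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @classmethod
    def from_points(
        cls,
        id: str,
        chrom: str,
        strand: str,
        tss: int,
        cpa: int,
        tss_width: int = DEFAULT_TSS_WIDTH,
        cpa_width: int = DEFAULT_CPA_WIDTH,
        chrom_length: int | None = None,
    ) -> "TranscriptAnnotation":
        """Build an annotation from exact TSS/CPA bases, widening each site
        to a centered region of the default spread."""
        th, ch = tss_width // 2, cpa_width // 2
        tss_lo, tss_hi = tss - th, tss - th + tss_width
        cpa_lo, cpa_hi = cpa - ch, cpa - ch + cpa_width
        if strand == "+":
            if not tss < cpa:
                raise ValueError(f"{id}: TSS must precede CPA on +")
            start, end = tss_lo, cpa_hi
        elif strand == "-":
            if not cpa < tss:
                raise ValueError(f"{id}: CPA must precede TSS genomically on -")
            start, end = cpa_lo, tss_hi
        else:
            raise ValueError("strand must be + or -")
        if start < 0 or (chrom_length is not None and end > chrom_length):
            raise ValueError(f"{id}: annotation out of chromosome bounds")
        return cls(
            id=id,
            interval=GenomicInterval(chrom, start, end, strand),
            tss_region=GenomicInterval(chrom, tss_lo, tss_hi, strand),
            cpa_region=GenomicInterval(chrom, cpa_lo, cpa_hi, strand),
            tss_site=tss,
            cpa_site=cpa,
        )


@dataclass
class StateMap:
    """Per-base 8-state labels per chromosome, plus an estimation mask.

    ``labels[chrom]`` is an int8 array of indices into :data:`STATES`.
    ``mask[chrom]`` marks bases excluded from HMM parameter estimation
    (e.g. overlapping sense/antisense transcript bodies); masked bases keep
    the IG label for decoding comparisons.
    """

    labels: dict[str, np.ndarray]
    mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, arr in self.labels.items():
            if arr.ndim != 1:
                raise ValueError("labels must be 1-D per chromosome")
            if arr.min(initial=0) < 0 or arr.max(initial=0) >= len(STATES):
                raise ValueError("labels outside the 8-state alphabet")
            if chrom not in self.mask:
                self.mask[chrom] = np.zeros(len(arr), dtype=bool)

    def state_names(self, chrom: str) -> list[str]:
        return [STATES[i] for i in self.labels[chrom]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, arr in self.labels.items():
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": np.arange(len(arr)),
                        "state": [STATES[i] for i in arr],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StateMap":
        df = pd.read_csv(path, sep="\t")
        labels = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values("pos")
            labels[str(chrom)] = np.array(
                [STATE_INDEX[s] for s in sub["state"]], dtype=np.int8
            )
        return cls(labels=labels)


def load_genome(path) -> Genome:
    """Load a FASTA file into a :class:`Genome` (uppercased, validated)."""
    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate record name {rec.id!r}")
        records[rec.id] = str(rec.seq)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome(records)


def write_genome(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def build_state_map(
    annotations: list[TranscriptAnnotation],
    genome: Genome,
    tss_width: int | None = None,
    cpa_width: int | None = None,
) -> StateMap:
    """Convert transcript annotations into a per-base 8-state map.

    TSS/CPA regions map to TSS±/CPA± states, the span between them to
    Gene±, overlapping CPA+ and CPA− regions of convergent transcripts to
    Term, and everything else to IG.  Bases where Gene+ and Gene− (or other
    incompatible cross-strand labels) coincide are masked: the model has no
    states for simultaneous sense/antisense transcription.

    ``tss_width``/``cpa_width`` optionally re-center the site states around
    the exact sites with the given widths (e.g. widened to the classifiers'
    intrinsic resolution when the map is used for HMM training).
    """
    per_strand: dict[str, dict[str, np.ndarray]] = {}
    for strand in "+-":
        per_strand[strand] = {
            chrom: np.zeros(genome.length(chrom), dtype=np.int8) for chrom in genome
        }
    offsets = {"+": 0, "-": 3}  # TSS+/Gene+/CPA+ = 1,2,3; TSS-/Gene-/CPA- = 4,5,6
    for ann in annotations:
        iv = ann.interval
        if iv.chrom not in genome:
            raise ValueError(f"{ann.id}: unknown chromosome {iv.chrom!r}")
        if iv.end > genome.length(iv.chrom):
            raise ValueError(f"{ann.id}: annotation beyond chromosome end")
        layer = per_strand[iv.strand][iv.chrom]
        off = offsets[iv.strand]
        L = genome.length(iv.chrom)
        tss_lo, tss_hi = ann.tss_region.start, ann.tss_region.end
        cpa_lo, cpa_hi = ann.cpa_region.start, ann.cpa_region.end
        if tss_width is not None:
            tss_lo = max(0, ann.tss_site - tss_width // 2)
            tss_hi = min(L, tss_lo + tss_width)
        if cpa_width is not None:
            cpa_lo = max(0, ann.cpa_site - cpa_width // 2)
            cpa_hi = min(L, cpa_lo + cpa_width)
        lo = min(iv.start, tss_lo, cpa_lo)
        hi = max(iv.end, tss_hi, cpa_hi)
        layer[lo:hi] = 2 + off  # Gene body first ...
        layer[tss_lo:tss_hi] = 1 + off  # ... site regions win
        layer[cpa_lo:cpa_hi] = 3 + off

    labels: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for chrom in genome:
        plus = per_strand["+"][chrom]
        minus = per_strand["-"][chrom]
        out = np.where(plus > 0, plus, minus).astype(np.int8)
        m = np.zeros(len(out), dtype=bool)
        both = (plus > 0) & (minus > 0)
        if both.any():
            term = both & (plus == STATE_INDEX["CPA+"]) & (minus == STATE_INDEX["CPA-"])
            out[term] = STATE_INDEX["Term"]
            clash = both & ~term
            out[clash] = STATE_INDEX["IG"]
            m[clash] = True
        labels[chrom] = out
        mask[chrom] = m
    return StateMap(labels=labels, mask=mask)


# ---------------------------------------------------------------------------
# Annotation file formats


def read_bed6(path) -> list[GenomicInterval]:
    """Read a BED6 file into stranded intervals (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    return [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end), str(r.strand))
        for r in df.itertuples()
    ]


def write_bed6(intervals, path, names=None, scores=None) -> None:
    rows = []
    for i, iv in enumerate(intervals):
        name = names[i] if names is not None else f"feature{i}"
        score = scores[i] if scores is not None else 0
        rows.append((iv.chrom, iv.start, iv.end, name, score, iv.strand))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def write_transcripts_gff3(annotations: list[TranscriptAnnotation], path) -> None:
    """Write transcripts as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            attrs = (
                f"ID={a.id};tss_region={a.tss_region.start + 1}-{a.tss_region.end};"
                f"cpa_region={a.cpa_region.start + 1}-{a.cpa_region.end};"
                f"tss_site={a.tss_site + 1};cpa_site={a.cpa_site + 1}"
            )
            fh.write(
                "\t".join(
                    [
                        a.chrom,
                        "txdefine",
                        "transcript",
                        str(a.interval.start + 1),
                        str(a.interval.end),
                        ".",
                        a.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_transcripts_gff3(path) -> list[TranscriptAnnotation]:
    """Read transcripts written by :func:`write_transcripts_gff3`.

    GFF3 coordinates are 1-based inclusive and are converted to the internal
    0-based half-open convention on input.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            chrom, _, ftype, start, end, _, strand, _, attr_str = f[:9]
            if ftype != "transcript":
                continue
            attrs = dict(kv.split("=", 1) for kv in attr_str.split(";") if "=" in kv)
            start0, end0 = int(start) - 1, int(end)

            def _region(key):
                lo, hi = attrs[key].split("-")
                return GenomicInterval(chrom, int(lo) - 1, int(hi), strand)

            out.append(
                TranscriptAnnotation(
                    id=attrs.get("ID", "tx"),
                    interval=GenomicInterval(chrom, start0, end0, strand),
                    tss_region=_region("tss_region"),
                    cpa_region=_region("cpa_region"),
                    tss_site=int(attrs["tss_site"]) - 1 if "tss_site" in attrs else None,
                    cpa_site=int(attrs["cpa_site"]) - 1 if "cpa_site" in attrs else None,
                )
            )
    return out
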