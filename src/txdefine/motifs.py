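"""Motif models, log-odds scanning, site sampling, and consensus matching.

A :class:`MotifModel` is a position frequency matrix (PFM) with a background
composition and pseudocount, convertible to a log2-odds position weight
matrix (PWM).  Consensus patterns use the IUPAC nucleotide alphabet; the
optimal Hrp1 efficiency element is fixed as the six-base pattern TATATA.

The module ships small illustrative PFMs for the factors that dominate
yeast promoter and terminator identity (Reb1, Abf1, Rap1, Rsc3, the TATA
box bound by Spt15/TBP, and Hrp1).  They are stand-ins with the right
widths and information content for simulation and testing; curated
database matrices can be loaded from plain-text PFM or MEME minimal files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import encode_sequence, reverse_complement

__all__ = [
    "MotifModel",
    "IUPAC",
    "pfm_to_pwm",
    "scan_max_score",
    "scan_scores",
    "sample_site",
    "count_matches",
    "find_matches",
    "expected_match_density",
    "read_pfm_file",
    "write_pfm_file",
    "read_meme_minimal",
    "builtin_motifs",
    "consensus",
    "OPTIMAL_HRP1_SITE",
]

BASES = "ACGT"
UNIFORM = np.full(4, 0.25)

# DNA base sets for each IUPAC nucleotide code.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Six-base optimal Hrp1 binding site (its own reverse complement).
OPTIMAL_HRP1_SITE = "TATATA"


@dataclass
class MotifModel:
    """Position frequency matrix with background and pseudocount."""

    name: str
    pfm: np.ndarray  # width x 4, rows sum to 1 (columns A,C,G,T)
    pseudocount: float = 0.001
    background: np.ndarray = field(default_factory=lambda: UNIFORM.copy())

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[1] != 4 or self.pfm.shape[0] < 1:
            raise ValueError("pfm must be width x 4 with width >= 1")
        if np.any(self.pfm < 0):
            raise ValueError("pfm frequencies must be non-negative")
        rowsums = self.pfm.sum(axis=1)
        if np.any(rowsums <= 0):
            raise ValueError("pfm rows must have positive mass")
        self.pfm = self.pfm / rowsums[:, None]
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.pfm.shape[0]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (vs background)."""
        p = self.pfm + 1e-12
        return (p * np.log2(p / self.background)).sum(axis=1)


def consensus(motif: MotifModel) -> str:
    return motif.consensus()


def pfm_to_pwm(motif: MotifModel) -> np.ndarray:
    """log2-odds scoring matrix: log2((f + pseudocount, renormalized) / bg).

    With a positive pseudocount every entry is finite.
    """
    if np.any(motif.background <= 0):
        raise ValueError("background probabilities must be positive")
    f = motif.pfm + motif.pseudocount
    f = f / f.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore"):
        return np.log2(f / motif.background)


def _pwm5(pwm: np.ndarray) -> np.ndarray:
    """PWM extended with a strongly penalized 5th column for N bases."""
    w = pwm.shape[0]
    ext = np.full((w, 5), -1e6 / max(w, 1))
    ext[:, :4] = pwm
    return ext


def scan_scores(seq: str, pwm: np.ndarray) -> np.ndarray:
    """Forward-strand log-odds score at every offset (length L-W+1)."""
    enc = encode_sequence(seq)
    return scan_scores_encoded(enc, pwm)


def scan_scores_encoded(enc: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    w = pwm.shape[0]
    n = len(enc) - w + 1
    if n < 1:
        raise ValueError("sequence shorter than motif")
    ext = _pwm5(pwm)
    out = np.zeros(n)
    for j in range(w):
        out += ext[j, enc[j : j + n]]
    return out


def reverse_complement_pwm(pwm: np.ndarray) -> np.ndarray:
    """PWM scoring a motif occurrence on the reverse strand."""
    return pwm[::-1, ::-1]


def scan_max_score(seq: str, pwm: np.ndarray, both_strands: bool = False):
    """Best log-odds match in a sequence.

    Returns ``(score, position, strand)``; ties break leftmost, then to the
    + strand.  ``position`` is the 0-based offset of the match on the
    forward strand (for '-' hits, the leftmost base of the covered span).
    """
    fwd = scan_scores(seq, pwm)
    best = float(fwd.max())
    pos = int(fwd.argmax())
    strand = "+"
    if both_strands:
        rev = scan_scores(seq, reverse_complement_pwm(pwm))
        rbest = float(rev.max())
        if rbest > best:
            best, pos, strand = rbest, int(rev.argmax()), "-"
        elif rbest == best and int(rev.argmax()) < pos:
            pos, strand = int(rev.argmax()), "-"
    return best, pos, strand


def sample_site(motif: MotifModel, rng: np.random.Generator) -> str:
    """Draw a site by sampling each position from the PFM column weights."""
    cols = [rng.choice(4, p=row) for row in motif.pfm]
    return "".join(BASES[c] for c in cols)


def _iupac_matcher(pattern: str) -> list[set]:
    try:
        return [set(IUPAC[c]) for c in pattern.upper()]
    except KeyError as e:
        raise ValueError(f"invalid IUPAC character {e.args[0]!r}") from None


def find_matches(
    seq: str,
    pattern: str,
    overlapping: bool = True,
    both_strands: bool = False,
) -> list[tuple[int, str]]:
    """Offsets (and strands) at which an IUPAC pattern matches.

    Non-overlapping mode greedily consumes matches left to right (within the
    merged, position-sorted candidate list when both strands are scanned).
    """
    sets = _iupac_matcher(pattern)
    w = len(sets)
    hits: list[tuple[int, str]] = []
    n = len(seq)
    for i in range(n - w + 1):
        if all(seq[i + j] in sets[j] for j in range(w)):
            hits.append((i, "+"))
    if both_strands:
        rc = reverse_complement(pattern)
        rsets = _iupac_matcher(rc)
        for i in range(n - w + 1):
            if all(seq[i + j] in rsets[j] for j in range(w)):
                if (i, "+") not in hits or rc != pattern:
                    hits.append((i, "-"))
        hits.sort(key=lambda h: (h[0], h[1]))
    if not overlapping:
        kept = []
        next_free = -1
        for pos, strand in hits:
            if pos >= next_free:
                kept.append((pos, strand))
                next_free = pos + w
        hits = kept
    return hits


def count_matches(
    seq: str,
    pattern: str,
    overlapping: bool = True,
    both_strands: bool = False,
) -> int:
    """Number of IUPAC-pattern match offsets in a sequence."""
    return len(find_matches(seq, pattern, overlapping, both_strands))


def expected_match_density(pattern: str, composition) -> float:
    """Expected matches per kilobase per strand in i.i.d. random sequence.

    Overlap-ignoring approximation: the product over positions of the
    allowed-base probability, times 1000 scan positions per kb.
    """
    composition = np.asarray(composition, dtype=float)
    if abs(composition.sum() - 1.0) > 1e-6:
        raise ValueError("composition must sum to 1")
    p = 1.0
    for allowed in _iupac_matcher(pattern):
        p *= sum(composition[BASES.index(b)] for b in allowed)
    return 1000.0 * p


# ---------------------------------------------------------------------------
# File formats


def read_pfm_file(path, pseudocount: float = 0.001, background=None) -> list[MotifModel]:
    """Read the plain-text PFM format: ``>name`` lines followed by width
    rows of 4 whitespace-separated frequencies (columns A,C,G,T)."""
    motifs = []
    name, rows = None, []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    motifs.append(_make_motif(name, rows, pseudocount, background))
                name, rows = line[1:].strip(), []
            else:
                rows.append([float(x) for x in line.split()])
    if name is not None:
        motifs.append(_make_motif(name, rows, pseudocount, background))
    return motifs


def _make_motif(name, rows, pseudocount, background):
    bg = UNIFORM if background is None else np.asarray(background)
    return MotifModel(name=name, pfm=np.array(rows), pseudocount=pseudocount, background=bg)


def write_pfm_file(motifs: list[MotifModel], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for row in m.pfm:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def read_meme_minimal(path, pseudocount: float = 0.001) -> list[MotifModel]:
    """Read MEME minimal motif format (letter-probability matrices)."""
    motifs = []
    background = UNIFORM.copy()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.array(
                [float(parts[parts.index(b) + 1]) for b in "ACGT"]
            )
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability" not in lines[j]:
                j += 1
            rows = []
            j += 1
            while j < len(lines):
                parts = lines[j].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                j += 1
            motifs.append(
                MotifModel(name=name, pfm=np.array(rows), pseudocount=pseudocount,
                           background=background.copy())
            )
            i = j
            continue
        i += 1
    return motifs


# ---------------------------------------------------------------------------
# Built-in illustrative motif library


def _pfm_from_consensus(spec: str, strong: float = 0.85) -> np.ndarray:
    """PFM from an IUPAC string: allowed bases share ``strong`` mass."""
    rows = []
    for c in spec.upper():
        allowed = IUPAC[c]
        row = np.full(4, (1 - strong) / (4 - len(allowed)) if len(allowed) < 4 else 0.25)
        for b in allowed:
            row[BASES.index(b)] = strong / len(allowed)
        rows.append(row / row.sum())
    return np.array(rows)


def builtin_motifs(background=None, pseudocount: float = 0.001) -> dict[str, MotifModel]:
    """Small illustrative PFMs for the promoter/terminator-defining factors.

    Synthetic stand-ins (consensus-derived, not database matrices): Reb1,
    Abf1, Rap1, Rsc3 are the general regulatory factors, TATA is the
    Spt15/TBP-bound TATA box, and Hrp1 is the AU-rich efficiency element.
    """
    bg = UNIFORM if background is None else np.asarray(background, dtype=float)
    specs = {
        "Reb1": "TTACCCG",
        "Abf1": "TCANNNNNNACG",
        "Rap1": "ACACCCATACAT",
        "Rsc3": "CGCGC",
        "TATA": "TATAWAWR",
        "Hrp1": "TATATA",
    }
    return {
        name: MotifModel(
            name=name,
            pfm=_pfm_from_consensus(spec),
            pseudocount=pseudocount,
            background=bg.copy(),
        )
        for name, spec in specs.items()
    }
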