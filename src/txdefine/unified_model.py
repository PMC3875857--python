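"""The 8-state strand-symmetric hidden Markov model over classifier scores.

The model scans a chromosome in one direction and describes transcription
on both strands simultaneously with states {IG, TSS+, Gene+, CPA+, TSS-,
Gene-, CPA-, Term}.  Its observations are the four per-base classifier
score tracks (initiation and termination, each on both strands), emitted
as independent Gaussians per state and track: 8x4 means and variances,
plus an 8x8 transition matrix of which only 24 entries are nonzero.

Strand symmetry: an involution sigma swaps +/- states (fixing IG and
Term) and swaps the +/- observation tracks.  Equivalent states share
means and variances, and the joint transition flows pi(a) T[a, b] are
tied to their reflections pi(sigma(b)) T[sigma(b), sigma(a)] — the
model's law is invariant under reverse complement, so decoding a
chromosome and its reverse complement yields mirror-image predictions
while states keep their own dwell times.  With this tying the model has
56 free nonzero parameters: 24 transitions + 16 means + 16 variances.

Decoding uses scaled forward-backward, so the output is the posterior
marginal probability of each state at every base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .sequence_io import STATES, STATE_INDEX, StateMap, TranscriptAnnotation, GenomicInterval
from .classifiers import ScoreTrack

__all__ = [
    "OBS_TRACKS",
    "SIGMA_STATE",
    "SIGMA_OBS",
    "UMStructure",
    "UMParameters",
    "PosteriorTrack",
    "build_structure",
    "count_free_parameters",
    "estimate_parameters",
    "symmetrize",
    "tie_gene_to_intergenic",
    "posterior_decode",
    "forward_backward",
    "tune_means",
    "predict_transcripts",
    "stack_tracks",
    "sample_path",
    "stationary_distribution",
    "mean_orbits",
]

#: Observation track order: initiation then termination scores per strand.
OBS_TRACKS = ("init+", "term+", "init-", "term-")

# sigma: strand-swap involution on states and observations
SIGMA_STATE = np.array(
    [
        STATE_INDEX["IG"],
        STATE_INDEX["TSS-"],
        STATE_INDEX["Gene-"],
        STATE_INDEX["CPA-"],
        STATE_INDEX["TSS+"],
        STATE_INDEX["Gene+"],
        STATE_INDEX["CPA+"],
        STATE_INDEX["Term"],
    ]
)
SIGMA_OBS = np.array([2, 3, 0, 1])

N_STATES = len(STATES)
N_OBS = len(OBS_TRACKS)


@dataclass(frozen=True)
class UMStructure:
    """State alphabet, allowed transitions, and the symmetry involution."""

    allowed_transitions: frozenset[tuple[int, int]]
    sigma_state: tuple[int, ...] = tuple(SIGMA_STATE)
    sigma_obs: tuple[int, ...] = tuple(SIGMA_OBS)

    def __post_init__(self):
        sig = self.sigma_state
        for a, b in self.allowed_transitions:
            if (sig[b], sig[a]) not in self.allowed_transitions:
                raise ValueError(
                    f"allowed set not sigma-closed: {STATES[a]}->{STATES[b]}"
                )

    @property
    def n_allowed(self) -> int:
        return len(self.allowed_transitions)

    @property
    def n_zero(self) -> int:
        return N_STATES * N_STATES - self.n_allowed

    def mask(self) -> np.ndarray:
        m = np.zeros((N_STATES, N_STATES), dtype=bool)
        for a, b in self.allowed_transitions:
            m[a, b] = True
        return m


def build_structure() -> UMStructure:
    """The canonical structure: 8 self-loops, the two strand cycles, the
    bidirectional-terminator path, and the divergent/tandem/convergent
    shortcut transitions — 24 allowed transitions (40 of the 64 zero)."""
    s = STATE_INDEX
    pairs = set()
    for i in range(N_STATES):
        pairs.add((i, i))
    core = [
        ("IG", "TSS+"), ("TSS+", "Gene+"), ("Gene+", "CPA+"), ("CPA+", "IG"),
        ("IG", "CPA-"), ("CPA-", "Gene-"), ("Gene-", "TSS-"), ("TSS-", "IG"),
        ("Gene+", "Term"), ("Term", "Gene-"),
    ]
    shortcuts = [
        ("TSS-", "TSS+"),   # divergent promoters
        ("CPA+", "TSS+"),   # tandem genes, forward strand
        ("TSS-", "CPA-"),   # tandem genes, reverse strand
        ("CPA+", "CPA-"),   # convergent genes without a shared terminator
        ("CPA+", "Term"), ("Term", "CPA-"),  # terminator entered/exited via CPA
    ]
    for a, b in core + shortcuts:
        pairs.add((s[a], s[b]))
    return UMStructure(allowed_transitions=frozenset(pairs))


def mean_orbits(structure: UMStructure | None = None) -> list[list[tuple[int, int]]]:
    """sigma-orbits of (state, observation) emission cells.

    Paired cells {(s, o), (sigma s, sigma o)} are one free parameter; cells
    fixed by sigma (IG and Term with... none, since sigma swaps tracks) are
    grouped likewise.  16 orbits for the canonical model.
    """
    sig_s = SIGMA_STATE if structure is None else np.array(structure.sigma_state)
    sig_o = SIGMA_OBS if structure is None else np.array(structure.sigma_obs)
    seen = set()
    orbits = []
    for s in range(N_STATES):
        for o in range(N_OBS):
            if (s, o) in seen:
                continue
            img = (int(sig_s[s]), int(sig_o[o]))
            orbit = [(s, o)] if img == (s, o) else [(s, o), img]
            seen.update(orbit)
            orbits.append(orbit)
    return orbits


def count_free_parameters(structure: UMStructure) -> int:
    """Nonzero transitions + sigma-tied free means + sigma-tied free
    variances (56 for the canonical structure)."""
    n_emit = len(mean_orbits(structure))
    return structure.n_allowed + 2 * n_emit


@dataclass
class UMParameters:
    """Tied Gaussian emission and transition parameters of the model."""

    means: np.ndarray       # 8 x 4
    variances: np.ndarray   # 8 x 4, positive
    transitions: np.ndarray  # 8 x 8 row-stochastic, zero off the allowed set
    initial: np.ndarray      # length 8
    structure: UMStructure = field(default_factory=build_structure)

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.variances = np.asarray(self.variances, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.means.shape != (N_STATES, N_OBS):
            raise ValueError("means must be 8 x 4")
        if self.variances.shape != (N_STATES, N_OBS) or np.any(self.variances <= 0):
            raise ValueError("variances must be 8 x 4 and positive")
        if self.transitions.shape != (N_STATES, N_STATES):
            raise ValueError("transitions must be 8 x 8")
        if np.any(self.transitions < 0):
            raise ValueError("transition probabilities must be non-negative")
        if not np.allclose(self.transitions.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("transition rows must sum to 1")
        if np.any(self.transitions[~self.structure.mask()] != 0):
            raise ValueError("nonzero transition outside the allowed set")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-8):
            raise ValueError("initial distribution must sum to 1")

    def is_symmetric(self, atol: float = 1e-9) -> bool:
        """True when the model's law is invariant under reverse complement.

        Emission means/variances satisfy the sigma orbit ties; the joint
        transition flows F[a, b] = initial[a] T[a, b] satisfy the
        reflection tie F[a, b] = F[sigma(b), sigma(a)] with a sigma-
        invariant, stationary initial distribution.
        """
        sig_s, sig_o = np.array(self.structure.sigma_state), np.array(self.structure.sigma_obs)
        m_ok = np.allclose(self.means, self.means[np.ix_(sig_s, sig_o)], atol=atol)
        v_ok = np.allclose(self.variances, self.variances[np.ix_(sig_s, sig_o)], atol=atol)
        F = self.initial[:, None] * self.transitions
        f_ok = np.allclose(F, F[np.ix_(sig_s, sig_s)].T, atol=atol)
        i_ok = np.allclose(self.initial, self.initial[sig_s], atol=atol) and np.allclose(
            self.initial @ self.transitions, self.initial, atol=atol
        )
        return bool(m_ok and v_ok and f_ok and i_ok)

    def expected_dwell_times(self) -> dict[str, float]:
        """Expected bases spent per visit in each state, 1/(1 - self)."""
        return {
            STATES[i]: float(1.0 / max(1.0 - self.transitions[i, i], 1e-300))
            for i in range(N_STATES)
        }

    def copy(self) -> "UMParameters":
        return UMParameters(
            means=self.means.copy(),
            variances=self.variances.copy(),
            transitions=self.transitions.copy(),
            initial=self.initial.copy(),
            structure=self.structure,
        )

    # -- human-readable serialization ------------------------------------
    def to_json(self, path=None) -> str:
        payload = {
            "states": list(STATES),
            "observations": list(OBS_TRACKS),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "transitions": self.transitions.tolist(),
            "initial": self.initial.tolist(),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "UMParameters":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            means=np.array(payload["means"]),
            variances=np.array(payload["variances"]),
            transitions=np.array(payload["transitions"]),
            initial=np.array(payload["initial"]),
        )


@dataclass
class PosteriorTrack:
    """Per-base state posterior marginals per chromosome (rows sum to 1)."""

    probs: dict[str, np.ndarray]  # chrom -> (L, 8)
    loglik: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, arr in self.probs.items():
            if arr.ndim != 2 or arr.shape[1] != N_STATES:
                raise ValueError("posterior arrays must be (L, 8)")
            if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("posterior rows must sum to 1")

    def transcript_probability(self, chrom: str) -> np.ndarray:
        """P(transcribed) per base = 1 - P(IG)."""
        return 1.0 - self.probs[chrom][:, STATE_INDEX["IG"]]

    def strand_transcript_probability(self, chrom: str, strand: str) -> np.ndarray:
        p = self.probs[chrom]
        if strand == "+":
            idx = [STATE_INDEX[s] for s in ("TSS+", "Gene+", "CPA+", "Term")]
        else:
            idx = [STATE_INDEX[s] for s in ("TSS-", "Gene-", "CPA-", "Term")]
        return p[:, idx].sum(axis=1)

    def to_tsv(self, path) -> None:
        import pandas as pd

        frames = []
        for chrom, arr in self.probs.items():
            df = pd.DataFrame(arr, columns=list(STATES))
            df.insert(0, "pos", np.arange(len(arr)))
            df.insert(0, "chrom", chrom)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def stationary_distribution(transitions: np.ndarray) -> np.ndarray:
    """Left eigenvector of the transition matrix for eigenvalue 1."""
    vals, vecs = np.linalg.eig(transitions.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def _symmetrize_transitions(T: np.ndarray, sig_s: np.ndarray):
    """Strand-symmetrize a transition matrix on the level of joint flows.

    The flow matrix F[a, b] = pi(a) T[a, b] (pi stationary) is averaged
    with its reflection F[sigma(b), sigma(a)] — the flows counted when the
    chromosome is read as its reverse complement — and a Sinkhorn-style
    rescaling of row a / column sigma(a) (which preserves the reflection
    tie exactly) drives the flow row sums to sigma-invariance.  The result
    is a row-stochastic T whose stationary distribution is sigma-invariant
    and whose flows are exactly reflection-symmetric, so per-state dwell
    times are preserved rather than forced equal across state kinds.
    """

    def reflect(M):
        return M[np.ix_(sig_s, sig_s)].T

    w = stationary_distribution(T)
    F = w[:, None] * T
    F = 0.5 * (F + reflect(F))
    r = np.ones(len(T))
    for _ in range(500):
        G = (r[:, None] * F) * r[sig_s][None, :]
        rs = G.sum(axis=1)
        gap = np.abs(rs - rs[sig_s]).max()
        if gap < 1e-15 * rs.max():
            break
        r = r * ((rs[sig_s] + 1e-300) / (rs + 1e-300)) ** 0.25
    G = (r[:, None] * F) * r[sig_s][None, :]
    G = 0.5 * (G + reflect(G))
    w_out = G.sum(axis=1)
    T_out = G / w_out[:, None]
    return T_out, w_out / w_out.sum()


def symmetrize(params: UMParameters) -> UMParameters:
    """Project parameters onto the strand-symmetric set.

    Emission means/variances are replaced by their sigma-orbit averages.
    Transitions are symmetrized on joint flows (see
    :func:`_symmetrize_transitions`) and the initial distribution becomes
    the resulting sigma-invariant stationary distribution.  Idempotent.
    """
    sig_s = np.array(params.structure.sigma_state)
    sig_o = np.array(params.structure.sigma_obs)
    means = 0.5 * (params.means + params.means[np.ix_(sig_s, sig_o)])
    variances = 0.5 * (params.variances + params.variances[np.ix_(sig_s, sig_o)])
    T, initial = _symmetrize_transitions(params.transitions, sig_s)
    return UMParameters(
        means=means,
        variances=variances,
        transitions=T,
        initial=initial,
        structure=params.structure,
    )


def stack_tracks(init_track: ScoreTrack, term_track: ScoreTrack) -> dict[str, np.ndarray]:
    """Stack the four observation tracks as (4, L) arrays per chromosome,
    ordered (init+, term+, init-, term-)."""
    out = {}
    for chrom in init_track.data:
        out[chrom] = np.vstack(
            [
                init_track.data[chrom]["+"],
                term_track.data[chrom]["+"],
                init_track.data[chrom]["-"],
                term_track.data[chrom]["-"],
            ]
        )
    return out


def estimate_parameters(
    state_map: StateMap,
    tracks: dict[str, np.ndarray],
    structure: UMStructure | None = None,
    variance_floor: float = 1e-4,
    symmetric: bool = True,
) -> UMParameters:
    """Moment/count estimation of the model parameters from a labeled map.

    Means and variances are the empirical per-state moments of each
    observation track; transitions are normalized adjacent-base transition
    counts restricted to the allowed set (transitions observed outside it
    are warned about and dropped).  Masked bases are excluded.  The result
    is symmetrized unless ``symmetric=False``.
    """
    import warnings

    structure = structure or build_structure()
    obs_by_state: list[list[np.ndarray]] = [[] for _ in range(N_STATES)]
    counts = np.zeros((N_STATES, N_STATES))
    for chrom, labels in state_map.labels.items():
        if chrom not in tracks:
            raise ValueError(f"no observation tracks for chromosome {chrom!r}")
        obs = tracks[chrom]
        if obs.shape != (N_OBS, len(labels)):
            raise ValueError(f"tracks for {chrom!r} must be (4, L)")
        mask = state_map.mask.get(chrom, np.zeros(len(labels), dtype=bool))
        keep = ~mask
        lab = labels[keep]
        kept_obs = obs[:, keep]
        for s in range(N_STATES):
            sel = lab == s
            if sel.any():
                obs_by_state[s].append(kept_obs[:, sel])
        # adjacent-base transitions between consecutive unmasked bases
        a, b = labels[:-1], labels[1:]
        ok = keep[:-1] & keep[1:]
        np.add.at(counts, (a[ok], b[ok]), 1)

    means = np.zeros((N_STATES, N_OBS))
    variances = np.zeros((N_STATES, N_OBS))
    for s in range(N_STATES):
        if not obs_by_state[s]:
            raise ValueError(f"state {STATES[s]} unobserved in the state map")
        arr = np.concatenate(obs_by_state[s], axis=1)
        means[s] = arr.mean(axis=1)
        variances[s] = np.maximum(arr.var(axis=1), variance_floor)

    allowed = structure.mask()
    bad = counts.copy()
    bad[allowed] = 0
    if bad.sum() > 0:
        pairs = [
            f"{STATES[i]}->{STATES[j]} (x{int(bad[i, j])})"
            for i, j in zip(*np.nonzero(bad))
        ]
        warnings.warn(
            "dropping transitions outside the allowed set: " + ", ".join(pairs),
            stacklevel=2,
        )
        counts[~allowed] = 0
    rowsums = counts.sum(axis=1, keepdims=True)
    if np.any(rowsums == 0):
        missing = [STATES[i] for i in np.flatnonzero(rowsums[:, 0] == 0)]
        raise ValueError(f"no outgoing transitions observed for state(s) {missing}")
    T = counts / rowsums

    params = UMParameters(
        means=means,
        variances=variances,
        transitions=T,
        initial=stationary_distribution(T),
        structure=structure,
    )
    if symmetric:
        params = symmetrize(params)
    return params


def _log_emissions(params: UMParameters, obs: np.ndarray) -> np.ndarray:
    """(L, 8) log-likelihoods of the 4-track observations per state."""
    if np.any(params.variances <= 0):
        raise ValueError("zero-variance state")
    L = obs.shape[1]
    ll = np.zeros((L, N_STATES))
    x = obs.T  # (L, 4)
    for s in range(N_STATES):
        mu, var = params.means[s], params.variances[s]
        ll[:, s] = -0.5 * (
            np.sum((x - mu) ** 2 / var + np.log(2 * np.pi * var), axis=1)
        )
    return ll


def tie_gene_to_intergenic(params: UMParameters) -> UMParameters:
    """Share emission parameters between the Gene states and IG.

    The classifier scores carry no per-base information that distinguishes
    a transcript body from intergenic background — both are featureless
    between boundary elements — but finite training data leaves small
    spurious differences in the estimated moments (e.g. antisense
    terminator firing inside gene bodies inflates the Gene variances).
    Left in place, those differences accumulate over hundreds of bases and
    fragment or truncate transcript calls.  Tying Gene± emissions to IG's
    leaves segmentation to the TSS/CPA/Term boundary evidence and the
    transition structure, playing the same corrective role as tuning the
    observation means against expression data.
    """
    p = params.copy()
    ig = STATE_INDEX["IG"]
    for s in (STATE_INDEX["Gene+"], STATE_INDEX["Gene-"]):
        p.means[s] = p.means[ig]
        p.variances[s] = p.variances[ig]
    return symmetrize(p)


def forward_backward(
    params: UMParameters, obs: np.ndarray, emission_weight: float = 1.0
):
    """Scaled forward-backward with strand-symmetric boundaries.

    ``obs`` is (4, L).  Returns ``(posterior (L, 8), loglik)``.  Scaling at
    every step makes underflow impossible by construction.

    With strand-symmetric parameters (reflection-tied flows and the
    sigma-invariant stationary initial distribution) decoding is exactly
    invariant under reverse complement of the input: the posterior of the
    reverse-complemented observations is the position-reversed,
    sigma-mapped posterior of the original.

    ``emission_weight`` scales the per-base emission log-likelihoods.  The
    score tracks are strongly autocorrelated (the scoring windows span
    hundreds of bases), so treating every base as an independent draw
    overstates the evidence; a weight of 1/resolution (one effective
    observation per classifier resolution length) corrects for this when
    decoding real score tracks.  The default 1.0 is the textbook
    per-base-independent model.
    """
    if not 0 < emission_weight <= 1:
        raise ValueError("emission_weight must lie in (0, 1]")
    if not np.all(np.isfinite(obs)):
        raise ValueError("observations must be finite")
    log_e = _log_emissions(params, obs) * emission_weight
    # per-base stabilization of emissions before exponentiating
    shift = log_e.max(axis=1, keepdims=True)
    e = np.exp(log_e - shift)
    L = e.shape[0]
    T = params.transitions
    alpha = np.zeros((L, N_STATES))
    c = np.zeros(L)
    a = params.initial * e[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, L):
        a = (alpha[t - 1] @ T) * e[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.zeros((L, N_STATES))
    beta[-1] = 1.0
    for t in range(L - 2, -1, -1):
        b = T @ (beta[t + 1] * e[t + 1])
        beta[t] = b / c[t + 1]
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.sum(np.log(c)) + shift.sum())
    return post, loglik


def posterior_decode(
    params: UMParameters,
    tracks: dict[str, np.ndarray],
    emission_weight: float = 1.0,
) -> PosteriorTrack:
    """Posterior marginals of the 8 states at every base of every
    chromosome; requires sigma-symmetric parameters."""
    probs, logliks = {}, {}
    for chrom, obs in tracks.items():
        post, ll = forward_backward(params, obs, emission_weight=emission_weight)
        probs[chrom] = post
        logliks[chrom] = ll
    return PosteriorTrack(probs=probs, loglik=logliks)


def tune_means(
    params: UMParameters,
    tracks: dict[str, np.ndarray],
    expression: dict[str, np.ndarray],
    max_evaluations: int = 500,
    seed: int = 0,
) -> UMParameters:
    """Tune the 16 sigma-tied observation means to maximize the Pearson
    correlation between the model's per-base transcript probability
    (1 - P(IG)) and log expression.

    Variances and transitions stay fixed; Nelder-Mead derivative-free
    search; the returned parameters are symmetric and never score below
    the starting point.
    """
    for chrom in tracks:
        if chrom not in expression:
            raise ValueError(f"no expression for chromosome {chrom!r}")
        if np.ptp(expression[chrom]) == 0 and len(expression) == 1:
            raise ValueError("constant expression track: correlation undefined")
    logx = np.concatenate([np.log1p(expression[c]) for c in tracks])
    if np.ptp(logx) == 0:
        raise ValueError("constant expression track: correlation undefined")
    orbits = mean_orbits(params.structure)

    def assemble(vec: np.ndarray) -> UMParameters:
        p = params.copy()
        for v, orbit in zip(vec, orbits):
            for s, o in orbit:
                p.means[s, o] = v
        return p

    def objective(vec: np.ndarray) -> float:
        p = assemble(vec)
        ptx = np.concatenate(
            [
                posterior_decode(p, {c: tracks[c]}).transcript_probability(c)
                for c in tracks
            ]
        )
        if np.ptp(ptx) == 0:
            return 0.0
        return float(stats.pearsonr(ptx, logx)[0])

    x0 = np.array([params.means[orbit[0]] for orbit in orbits])
    f0 = objective(x0)
    res = optimize.minimize(
        lambda v: -objective(v),
        x0,
        method="Nelder-Mead",
        options={"maxfev": max_evaluations, "xatol": 1e-3, "fatol": 1e-4},
    )
    if -res.fun <= f0:
        return symmetrize(params)
    return symmetrize(assemble(res.x))


def predict_transcripts(
    posterior: PosteriorTrack,
    threshold: float = 0.5,
    min_length: int = 1,
    min_confidence: float = 0.0,
) -> list[TranscriptAnnotation]:
    """Call transcripts from posterior marginals.

    Per strand, maximal runs where the strand transcript probability
    (TSS + Gene + CPA for that strand, plus Term) is >= threshold become
    transcripts; TSS/CPA regions are the runs where the corresponding state
    is the posterior argmax inside the call (Term counts toward the CPA
    region of both strands), defaulting to the transcript's terminal base.
    Calls shorter than ``min_length`` bases, or whose mean strand
    probability is below ``min_confidence``, are discarded.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    out: list[TranscriptAnnotation] = []
    k = 0
    for chrom, post in posterior.probs.items():
        argmax = post.argmax(axis=1)
        for strand in "+-":
            p_tx = posterior.strand_transcript_probability(chrom, strand)
            above = p_tx >= threshold
            if not above.any():
                continue
            d = np.diff(above.astype(np.int8))
            starts = list(np.flatnonzero(d == 1) + 1)
            ends = list(np.flatnonzero(d == -1) + 1)
            if above[0]:
                starts.insert(0, 0)
            if above[-1]:
                ends.append(len(above))
            tss_state = STATE_INDEX["TSS+" if strand == "+" else "TSS-"]
            cpa_state = STATE_INDEX["CPA+" if strand == "+" else "CPA-"]
            term_state = STATE_INDEX["Term"]
            for a, b in zip(starts, ends):
                if b - a < min_length:
                    continue
                if p_tx[a:b].mean() < min_confidence:
                    continue
                lab = argmax[a:b]
                n = b - a
                tss_r = _terminal_run(lab, tss_state, None, from_start=(strand == "+"))
                cpa_r = _terminal_run(
                    lab, cpa_state, term_state, from_start=(strand == "-")
                )
                # site regions must flank the call: extend to its ends
                if strand == "+":
                    tss_r = (0, tss_r[1]) if tss_r else (0, 1)
                    cpa_r = (cpa_r[0], n) if cpa_r else (n - 1, n)
                else:
                    tss_r = (tss_r[0], n) if tss_r else (n - 1, n)
                    cpa_r = (0, cpa_r[1]) if cpa_r else (0, 1)
                k += 1
                iv = GenomicInterval(chrom, a, b, strand)
                out.append(
                    TranscriptAnnotation(
                        id=f"txp{k}",
                        interval=iv,
                        tss_region=GenomicInterval(chrom, a + tss_r[0], a + tss_r[1], strand),
                        cpa_region=GenomicInterval(chrom, a + cpa_r[0], a + cpa_r[1], strand),
                    )
                )
    return out


def _terminal_run(labels: np.ndarray, state: int, alt_state, from_start: bool):
    """First (or last) contiguous run of a state label within a call."""
    match = labels == state
    if alt_state is not None:
        match |= labels == alt_state
    idx = np.flatnonzero(match)
    if len(idx) == 0:
        return None
    breaks = np.flatnonzero(np.diff(idx) > 1)
    if from_start:
        end = idx[breaks[0]] if len(breaks) else idx[-1]
        return int(idx[0]), int(end) + 1
    start = idx[breaks[-1] + 1] if len(breaks) else idx[0]
    return int(start), int(idx[-1]) + 1


def sample_path(
    params: UMParameters, length: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a state path and Gaussian observations from the model.

    Returns ``(states (L,), obs (4, L))``; used for parameter-recovery
    simulations.
    """
    cum = np.cumsum(params.transitions, axis=1)
    u = rng.random(length)
    states = np.empty(length, dtype=np.int8)
    s = int(np.searchsorted(np.cumsum(params.initial), u[0], side="right"))
    states[0] = s
    for t in range(1, length):
        s = int(np.searchsorted(cum[s], u[t], side="right"))
        states[t] = min(s, N_STATES - 1)
    mu = params.means[states]  # (L, 4)
    sd = np.sqrt(params.variances[states])
    obs = (mu + sd * rng.standard_normal((length, N_OBS))).T
    return states, obs
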