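"""PWM binding-affinity profiles and running-sum motif/loading association.

Two stages connect promoter sequence to the eigen-analysis:

1. ``scan_pwm_affinity`` turns a position weight matrix into a per-gene
   *binding strength*: the best log-odds score over every window on both
   strands of the gene's upstream sequence is converted to a per-window
   significance under an i.i.d. background model (exact discretized score
   distribution), combined over the L scanned windows as 1 - (1 - p)^L,
   and transformed to -log10.  Strength is monotone decreasing in the
   combined significance.

2. ``base_association`` measures the association between a binding-affinity
   profile and a sorted per-gene statistic (e.g. a gene eigenvector) with
   the maximum of a mean-centered running sum along the sorted gene list;
   significance comes from an add-one permutation null over affinity
   shuffles.  This is a transparent variant of binding-association
   enrichment scores used for cis/trans-regulation inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import default_rng

_BASE_ORDER = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASE_ORDER)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

SCORE_GRANULARITY = 1e-3   # bits; discretization of the null score grid
MIN_LOG_ODDS = -30.0       # floor for zero-probability cells (bits)


@dataclass
class PWM:
    """Position frequency matrix over A/C/G/T with pseudocount and background."""

    name: str
    counts: np.ndarray                       # (4, L) nonnegative counts
    pseudocount: float = 0.01
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.counts.shape[0] != 4 or self.counts.shape[1] < 2:
            raise ValueError("counts must be 4 x L with L >= 2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be nonnegative")
        if abs(self.background.sum() - 1.0) > 1e-8 or (self.background <= 0).any():
            raise ValueError("background must be a positive composition summing to 1")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def probabilities(self) -> np.ndarray:
        """Column frequencies after pseudocount normalization (columns sum to 1)."""
        padded = self.counts + self.pseudocount * self.background[:, None]
        return padded / padded.sum(axis=0, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """log2(p / background); zero-probability cells floored for finiteness."""
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probabilities / self.background[:, None])
        return np.maximum(lo, MIN_LOG_ODDS)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.probabilities.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(
            name=self.name,
            counts=self.counts[::-1, ::-1].copy(),
            pseudocount=self.pseudocount,
            background=self.background[::-1].copy(),
        )

    @classmethod
    def from_consensus(cls, name: str, consensus: str, weight: float = 97.0,
                       off: float = 1.0, **kwargs) -> "PWM":
        counts = np.full((4, len(consensus)), off)
        for j, base in enumerate(consensus.upper()):
            counts[_BASE_INDEX[base], j] = weight
        return cls(name=name, counts=counts, **kwargs)


@dataclass
class AffinityProfile:
    """Per-gene binding strengths (>= 0) for one motif."""

    strengths: pd.Series
    motif_id: str
    flagged_genes: list = field(default_factory=list)   # sequence shorter than motif

    def __post_init__(self) -> None:
        if (self.strengths < 0).any():
            raise ValueError("binding strengths must be nonnegative")


def _null_tail(pwm: PWM, granularity: float = SCORE_GRANULARITY):
    """Exact tail P(null window score >= s) on a discretized score grid.

    The null window is i.i.d. background; per-column score distributions
    (4 atoms each) are convolved by shifting, on a grid of ``granularity``
    bits.  Returns (offset_bins, tail array) where index = score/granularity
    - offset.
    """
    lom = np.rint(pwm.log_odds / granularity).astype(np.int64)   # (4, L) in bins
    bg = pwm.background
    dist = np.array([1.0])
    offset = 0
    for j in range(pwm.length):
        col = lom[:, j]
        lo, hi = int(col.min()), int(col.max())
        new = np.zeros(len(dist) + (hi - lo))
        for b in range(4):
            sh = int(col[b]) - lo
            new[sh: sh + len(dist)] += bg[b] * dist
        dist = new
        offset += lo
    tail = np.cumsum(dist[::-1])[::-1]
    return offset, tail


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)   # 4 = N / unknown
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    bad = ~np.isin(arr, [ord(c) for c in "ACGTN"])
    if bad.any():
        raise ValueError(f"invalid alphabet character {chr(arr[bad][0])!r}")
    return out


def _window_scores(codes: np.ndarray, lom5: np.ndarray) -> np.ndarray:
    """Scores of every window of one encoded sequence (N rows score 0)."""
    L = lom5.shape[1]
    n_win = len(codes) - L + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    return lom5[windows, np.arange(L)].sum(axis=1)[:n_win]


def scan_pwm_affinity(promoters: dict[str, str], pwm: PWM) -> AffinityProfile:
    """Binding-strength profile of one motif over a promoter collection.

    Per gene: best log-odds window score over both strands; per-window
    significance p = P(null >= best) from the exact discretized null;
    combined significance 1 - (1 - p)^L over the L windows scanned (both
    strands); strength = -log10(combined).  Sequences shorter than the
    motif get strength 0 and are flagged.
    """
    if not promoters:
        raise ValueError("no promoter sequences supplied")
    lom = pwm.log_odds
    lom5 = np.vstack([lom, np.zeros((1, pwm.length))])      # N row scores 0
    rc = pwm.reverse_complement().log_odds
    rc5 = np.vstack([rc, np.zeros((1, pwm.length))])
    offset, tail = _null_tail(pwm)

    strengths = {}
    flagged = []
    for gene, seq in promoters.items():
        if len(seq) < pwm.length:
            strengths[gene] = 0.0
            flagged.append(gene)
            continue
        codes = _encode(seq)
        fwd = _window_scores(codes, lom5)
        rev = _window_scores(codes, rc5)    # = forward scan of the reverse strand
        best = float(max(fwd.max(), rev.max()))
        n_windows = len(fwd) + len(rev)
        bin_idx = int(np.rint(best / SCORE_GRANULARITY)) - offset
        if bin_idx < 0:
            p = 1.0
        else:
            bin_idx = min(bin_idx, len(tail) - 1)
            p = float(max(tail[bin_idx], np.nextafter(0, 1)))
        combined = 1.0 - (1.0 - min(p, 1.0)) ** n_windows
        combined = max(combined, 1e-300)
        strengths[gene] = max(0.0, -np.log10(combined))
    return AffinityProfile(
        strengths=pd.Series(strengths, name=pwm.name), motif_id=pwm.name,
        flagged_genes=flagged,
    )


@dataclass
class BaseAssociation:
    motif_id: str
    score: float
    p_value: float
    end: str                 # 'head' (top of the sorted list) or 'tail'
    peak_position: int       # 1-based index of the running-sum extremum


def base_association(
    loadings: pd.Series,
    affinity: AffinityProfile,
    n_perm: int = 999,
    seed: int = 0,
) -> BaseAssociation:
    """Maximum mean-centered running-sum association with a permutation null.

    Genes are sorted by ``loadings`` descending; with w the affinities in
    that order and w_bar the universe mean, R(i) = sum_{j<=i} (w_j - w_bar)
    and the score is max_i |R(i)|, its position recording whether affinity
    concentrates at the head or tail of the list.  p is the add-one
    permutation p-value over uniform shuffles of the affinity profile.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    missing = loadings.index.difference(affinity.strengths.index)
    if len(missing):
        raise KeyError(f"affinity missing for genes: {list(missing[:5])}")
    w_all = affinity.strengths.loc[loadings.index].to_numpy(dtype=float)
    order = np.argsort(-loadings.to_numpy(), kind="stable")
    w = w_all[order]
    g = len(w)
    centered = w - w.mean()
    if np.allclose(centered, 0.0):
        return BaseAssociation(affinity.motif_id, 0.0, 1.0, "head", 0)
    running = np.cumsum(centered)
    absrun = np.abs(running)
    peak = int(np.argmax(absrun))
    score = float(absrun[peak])
    end = "head" if (peak + 1) <= g / 2 else "tail"

    rng = default_rng(seed)
    exceed = 0
    block = 200    # permutations per vectorized block (memory control)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        idx = np.argsort(rng.random((b, g)), axis=1)
        perm = centered[idx]
        perm_scores = np.abs(np.cumsum(perm, axis=1)).max(axis=1)
        exceed += int((perm_scores >= score).sum())
        done += b
    p = (1 + exceed) / (n_perm + 1)
    return BaseAssociation(affinity.motif_id, score, float(p), end, peak + 1)
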