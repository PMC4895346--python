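"""Position weight matrices: log-odds conversion, P-value thresholds, scanning.

A motif is represented in two stages: a :class:`PositionFrequencyMatrix`
(nonnegative base counts or probabilities per motif position, JASPAR style)
and a :class:`PWM` of log2 odds weights against a background base
composition.  Scores of genomic windows are sums of per-position weights;
a score threshold for a given P-value is obtained by exact convolution of
the per-position score distributions under the background model.

Coordinates are 0-based throughout.  A site is reported as a single center
position: the motif midpoint for odd motif lengths, and the position
immediately upstream of the midpoint for even lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Human-genome base composition used as default background (A, C, G, T).
HUMAN_BACKGROUND = (0.29, 0.21, 0.21, 0.29)


class InvalidMatrixError(ValueError):
    """Raised for a frequency matrix with a zero-sum row."""


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position base frequencies (rows = positions, columns = A,C,G,T)."""

    values: np.ndarray
    name: str = "motif"

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 4 or values.shape[0] < 1:
            raise InvalidMatrixError("PFM must be an N x 4 matrix with N >= 1")
        if (values < 0).any():
            raise InvalidMatrixError("PFM entries must be nonnegative")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized base probabilities."""
        sums = self.values.sum(axis=1, keepdims=True)
        if (sums <= 0).any():
            raise InvalidMatrixError("PFM row sums must be positive")
        return self.values / sums


@dataclass(frozen=True)
class PWM:
    """Log2-odds weight matrix with its background base composition."""

    weights: np.ndarray
    background: np.ndarray
    name: str = "motif"

    def __post_init__(self):
        weights = np.asarray(self.weights, dtype=float)
        background = np.asarray(self.background, dtype=float)
        if abs(background.sum() - 1.0) > 1e-9:
            raise ValueError("background must sum to 1")
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "background", background)

    def __len__(self) -> int:
        return self.weights.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.weights.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.weights.min(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.weights.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        """PWM scoring the reverse-complement motif on the forward strand."""
        return PWM(self.weights[::-1, ::-1].copy(), self.background[::-1].copy(),
                   name=self.name)


@dataclass
class SiteList:
    """Ordered binding-site records with single-base centers.

    Backed by a DataFrame with columns chrom, center, strand, score, id.
    """

    frame: pd.DataFrame = field(default_factory=lambda: SiteList.empty_frame())

    COLUMNS = ("chrom", "center", "strand", "score", "id")

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "center": pd.Series(dtype=int),
                             "strand": pd.Series(dtype=str),
                             "score": pd.Series(dtype=float),
                             "id": pd.Series(dtype=str)})

    def __post_init__(self):
        frame = pd.DataFrame(self.frame).reset_index(drop=True)
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"site list missing columns: {sorted(missing)}")
        if frame["id"].duplicated().any():
            raise ValueError("site ids must be unique within a list")
        self.frame = frame[list(self.COLUMNS)]

    @classmethod
    def from_records(cls, records) -> "SiteList":
        frame = pd.DataFrame(records, columns=list(cls.COLUMNS))
        return cls(frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __iter__(self):
        return self.frame.itertuples(index=False)

    @property
    def centers(self) -> np.ndarray:
        return self.frame["center"].to_numpy()

    def subset(self, mask) -> "SiteList":
        return SiteList(self.frame[np.asarray(mask)].reset_index(drop=True))


def log_odds_from_probabilities(pfm: PositionFrequencyMatrix,
                                background=HUMAN_BACKGROUND,
                                pseudocount: float = 0.01) -> PWM:
    """Convert a base probability matrix to a log2-odds PWM.

    Each row of the PFM is renormalized to 1, then

        w[i, b] = log2((p[i, b] + pseudocount * bg[b]) / ((1 + pseudocount) * bg[b]))

    The pseudocount is spread proportionally to the background so that a
    row equal to the background maps to all-zero weights for any
    pseudocount, and zero-probability bases get a finite penalty.
    """
    background = np.asarray(background, dtype=float)
    if (background <= 0).any():
        raise ValueError("background frequencies must be strictly positive")
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    probs = pfm.probabilities
    adjusted = (probs + pseudocount * background) / (1.0 + pseudocount)
    with np.errstate(divide="ignore"):
        weights = np.log2(adjusted / background)
    return PWM(weights, background / background.sum(), name=pfm.name)


def score_distribution(pwm: PWM, grid: float = 0.01):
    """Exact distribution of window scores under the background model.

    Weights are rounded to multiples of ``grid`` and the per-position score
    distributions are convolved position by position.  Returns
    ``(scores, probabilities)`` with scores ascending on the grid.
    """
    keys = np.rint(pwm.weights / grid).astype(np.int64)
    # start with the empty-product distribution: score 0 with probability 1
    cur = np.ones(1)
    cur_lo = 0
    for i in range(len(pwm)):
        kmin, kmax = int(keys[i].min()), int(keys[i].max())
        nxt = np.zeros(len(cur) + (kmax - kmin))
        for b in range(4):
            k = int(keys[i, b])
            nxt[k - kmin:k - kmin + len(cur)] += pwm.background[b] * cur
        cur = nxt
        cur_lo += kmin
    scores = (np.arange(len(cur)) + cur_lo) * grid
    return scores, cur


def score_threshold_from_pvalue(pwm: PWM, pvalue: float = 1e-4,
                                grid: float = 0.01) -> float:
    """Smallest score ``t`` with ``P(score >= t) <= pvalue`` under background.

    Computed by exact convolution of per-position score distributions on a
    rounding grid of ``grid`` log2 units; the returned threshold is accurate
    to the grid resolution (at most ``len(pwm) * grid / 2`` from the exact
    value).
    """
    if not (0.0 < pvalue <= 1.0):
        raise ValueError("pvalue must lie in (0, 1]")
    scores, probs = score_distribution(pwm, grid=grid)
    tail = np.cumsum(probs[::-1])[::-1]
    # leftmost grid score whose upper tail is within the requested P-value
    ok = tail <= pvalue + 1e-12
    if not ok.any():
        return float(scores[-1] + grid)
    return float(scores[np.argmax(ok)])


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A,C,G,T -> 0..3; other letters -> 4."""
    table = np.full(256, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        table[ord(base)] = idx
        table[ord(base.lower())] = idx
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_scores(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Scores of every full-length window; windows containing N are -inf."""
    n = weights.shape[0]
    nwin = len(codes) - n + 1
    if nwin <= 0:
        return np.empty(0)
    padded = np.vstack([weights.T, np.full((1, n), -np.inf)])  # row 4 = N
    scores = np.zeros(nwin)
    for j in range(n):
        scores += padded[codes[j:j + nwin], j]
    return scores


def motif_center_offset(n: int, strand: str = "+") -> int:
    """Offset of the reported center from the window start.

    Odd lengths use the midpoint.  For even lengths the position
    immediately upstream of the midpoint is used, which on the minus strand
    corresponds to the downstream position in forward coordinates.
    """
    if n % 2 == 1 or strand == "+":
        return (n - 1) // 2
    return n // 2


def scan_sequence(seq: str, pwm: PWM, threshold: float,
                  chrom: str = "chr", id_prefix: str | None = None) -> SiteList:
    """All positions on both strands scoring at least ``threshold``.

    Windows containing N are skipped.  Reverse-strand windows are scored
    against the reverse-complement PWM and their centers mapped back to
    forward coordinates.  Records are ordered by center, plus strand first.
    """
    codes = encode_sequence(seq)
    n = len(pwm)
    prefix = id_prefix or pwm.name
    hits = []
    for strand, weights in (("+", pwm.weights),
                            ("-", pwm.reverse_complement().weights)):
        scores = _window_scores(codes, weights)
        starts = np.nonzero(scores >= threshold)[0]
        off = motif_center_offset(n, strand)
        for start in starts:
            hits.append((chrom, int(start) + off, strand,
                         float(scores[start]), None))
    hits.sort(key=lambda h: (h[1], h[2]))
    records = [(c, p, s, sc, f"{prefix}_{i}")
               for i, (c, p, s, sc, _) in enumerate(hits)]
    return SiteList.from_records(records)


def best_match_in_window(seq: str, pwm: PWM, center: int,
                         halfwidth: int = 100):
    """Best PWM match among windows starting within ``center +/- halfwidth``.

    Returns ``(score, offset, strand)`` where ``offset`` is the distance of
    the match center from ``center``.  Ties are broken by smaller
    ``|offset|``, then by the plus strand.  Returns ``(nan, 0, '.')`` when
    no full-length N-free window fits.
    """
    codes = encode_sequence(seq)
    n = len(pwm)
    lo = max(0, center - halfwidth)
    hi = min(len(seq) - n, center + halfwidth)
    if hi < lo:
        return float("nan"), 0, "."
    segment = codes[lo:hi + n]
    best = None
    for strand, weights in (("+", pwm.weights),
                            ("-", pwm.reverse_complement().weights)):
        scores = _window_scores(segment, weights)
        off = motif_center_offset(n, strand)
        for i, score in enumerate(scores):
            if not np.isfinite(score):
                continue
            offset = lo + i + off - center
            key = (-score, abs(offset), 0 if strand == "+" else 1)
            if best is None or key < best[0]:
                best = (key, float(score), int(offset), strand)
    if best is None:
        return float("nan"), 0, "."
    return best[1], best[2], best[3]


def filter_sites_by_tag_support(sites: SiteList, tracks,
                                min_count: int = 3,
                                halfwidth: int = 100) -> SiteList:
    """Drop sites lacking ChIP-seq tag support in every track.

    A site is kept iff at least one track has ``min_count`` or more tags
    (deduplicated) within ``+/- halfwidth`` of its center.
    """
    from .tracks import count_tags

    if not tracks:
        raise ValueError("at least one tag track is required")
    keep = np.zeros(len(sites), dtype=bool)
    for track in tracks:
        counts = count_tags(track, sites, halfwidth=halfwidth, dedup=True)
        keep |= counts >= min_count
    return sites.subset(keep)
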