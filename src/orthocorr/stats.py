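"""Correspondence significance methods.

Five independent ways to ask whether the mouse fold-change pattern over
ortholog pairs agrees with the human pattern more than chance allows:

1. concordance proportions against a hypergeometric null band;
2. overlap-at-rank-N curves for ranked transcript lists;
3. a 3x3 differential-expression contingency table with adjusted residuals;
4. foreground/background detection-rate curves and the area between them;
5. an unweighted running enrichment score with a random-set permutation
   null;

plus a Monte-Carlo test for the number of genes significant in *all*
models simultaneously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .io import OrthologMap

logger = logging.getLogger(__name__)

LABELS = ("up", "down", "ns")


# ---------------------------------------------------------------------------
# concordance proportions and hypergeometric bands
# ---------------------------------------------------------------------------


def concordance_percentage(n1: int, n2: int) -> Tuple[float, float]:
    """(percent increased, percent decreased) at one-decimal precision.

    26 increased of 28 -> (92.9, 7.1).
    """
    n1, n2 = int(n1), int(n2)
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    n = n1 + n2
    if n == 0:
        raise ValueError("n1 + n2 must be at least 1")
    return (round(100.0 * n1 / n, 1), round(100.0 * n2 / n, 1))


def hypergeom_band(M: int, K: int, n: int, level: float = 0.95) -> Tuple[int, int]:
    """Equal-tail central interval of Hypergeometric(M, K, n).

    ``lo`` is the smallest x with CDF(x) > alpha/2 and ``hi`` the smallest x
    with CDF(x) >= 1 - alpha/2 (inner rounding), so each tail outside the
    band has probability at most alpha/2 and coverage is >= level.
    """
    if not (0 <= K <= M and 0 <= n <= M):
        raise ValueError(f"invalid hypergeometric parameters M={M}, K={K}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if n == 0 or K == 0:
        return (0, 0)
    if K == M:
        return (n, n)
    alpha = 1.0 - level
    dist = sps.hypergeom(M, K, n)
    lo = int(dist.ppf(alpha / 2.0))
    if dist.cdf(lo) <= alpha / 2.0:
        lo += 1
    hi = int(dist.ppf(1.0 - alpha / 2.0))
    lo = max(lo, max(0, n - (M - K)))
    hi = min(hi, min(n, K))
    return (lo, hi)


@dataclass
class ConcordanceSummary:
    """Sign concordance of one mapped transcript set against its null band.

    ``n1 + n2 = n``: every mapped mouse transcript is counted as increased
    (log2fc >= 0) or decreased (log2fc < 0); there is no "unchanged" class.
    The band is the central ``level`` interval of the count of increased
    transcripts under random draws from the mapped population.
    """

    set_label: str
    n: int
    n1: int
    n2: int
    pct_increased: float
    pct_decreased: float
    band: Tuple[int, int]
    p: float
    direction: str = "up"

    def to_dict(self) -> Dict[str, object]:
        return {
            "set_label": self.set_label,
            "n": self.n,
            "n1": self.n1,
            "n2": self.n2,
            "pct_increased": self.pct_increased,
            "pct_decreased": self.pct_decreased,
            "band_lo": self.band[0],
            "band_hi": self.band[1],
            "p": self.p,
            "direction": self.direction,
        }


def proportion_concordance_test(
    human_set: Iterable[str],
    omap: OrthologMap,
    mouse: pd.DataFrame,
    cfg: Optional[AnalysisConfig] = None,
    set_label: str = "",
    direction: str = "up",
) -> ConcordanceSummary:
    """Test whether mouse orthologs of a human DE set skew in one direction.

    The human set (typically the strict up- or down-selection) is mapped to
    its n mouse ortholog transcripts; n1 of them have mouse log2fc >= 0 and
    n2 have log2fc < 0.  The null treats the n transcripts as a uniform
    draw from the mapped mouse population (M transcripts, K of them
    increased): band = central 95% of Hypergeometric(M, K, n) on n1; p is
    the upper tail P(X >= n1) for ``direction="up"`` sets and P(n - X >= n2)
    for ``direction="down"`` sets.
    """
    cfg = cfg or AnalysisConfig()
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    population = omap.pairs["mouse_transcript"].unique()
    pop_lfc = mouse["log2fc"].reindex(population).dropna()
    M = len(pop_lfc)
    K = int((pop_lfc >= 0).sum())

    mapped = omap.mouse_orthologs(human_set)
    lfc = mouse["log2fc"].reindex(mapped).dropna()
    n = len(lfc)
    if n == 0:
        raise ValueError("human set maps to no mouse transcripts with fold changes")
    n1 = int((lfc >= 0).sum())
    n2 = n - n1
    pct_up, pct_down = concordance_percentage(n1, n2)
    band = hypergeom_band(M, K, n, cfg.band_level)
    dist = sps.hypergeom(M, K, n)
    if direction == "up":
        p = float(dist.sf(n1 - 1))
    else:
        p = float(dist.cdf(n1))
    return ConcordanceSummary(
        set_label=set_label,
        n=n,
        n1=n1,
        n2=n2,
        pct_increased=pct_up,
        pct_decreased=pct_down,
        band=band,
        p=min(max(p, 0.0), 1.0),
        direction=direction,
    )


# ---------------------------------------------------------------------------
# ranked-list overlap curves
# ---------------------------------------------------------------------------


@dataclass
class OverlapCurve:
    """Overlap-at-rank-N between species' ranked lists, with its null band."""

    ranks: np.ndarray
    overlap: np.ndarray
    mapped_size: np.ndarray  # a(N)
    band_lo: np.ndarray
    band_hi: np.ndarray
    direction: str
    population: int  # M_m: mapped mouse transcripts ranked

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.ranks,
                "overlap": self.overlap,
                "a": self.mapped_size,
                "lo": self.band_lo,
                "hi": self.band_hi,
            }
        )

    def exceedance_fraction(self) -> float:
        """Fraction of evaluated ranks where the overlap exceeds the band."""
        return float(np.mean(self.overlap > self.band_hi))


def ranked_overlap_curve(
    human: pd.DataFrame,
    mouse: pd.DataFrame,
    omap: OrthologMap,
    direction: str = "up",
    cfg: Optional[AnalysisConfig] = None,
    grid: Optional[Sequence[int]] = None,
) -> OverlapCurve:
    """Overlap between the mouse top-N and orthologs of the human top-N.

    Both species are ranked by signed log2 fold change (descending for
    ``up``, ascending for ``down``).  The mouse ranking is taken within the
    ortholog-mapped mouse universe (M_m transcripts) so that, at each rank
    N, the overlap between the a(N) mouse orthologs of the human top-N and
    the mouse top-N is a draw of N from M_m under the null, with band the
    central 95% of Hypergeometric(M_m, a(N), N).
    """
    cfg = cfg or AnalysisConfig()
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    ascending = direction == "down"

    mapped_mouse = pd.Index(omap.pairs["mouse_transcript"].unique())
    mouse_lfc = mouse["log2fc"].reindex(mapped_mouse).dropna()
    mouse_order = mouse_lfc.sort_values(ascending=ascending, kind="stable")
    M_m = len(mouse_order)
    mouse_rank = pd.Series(np.arange(1, M_m + 1), index=mouse_order.index)

    human_in_map = pd.Index(omap.pairs["human_transcript"].unique())
    human_lfc = human["log2fc"].reindex(human["log2fc"].index.intersection(human_in_map))
    human_order = human_lfc.sort_values(ascending=ascending, kind="stable")
    human_rank = pd.Series(np.arange(1, len(human_order) + 1), index=human_order.index)

    rank_max = cfg.rank_max
    if rank_max > min(M_m, len(human_order)):
        raise ValueError(
            f"rank_max={rank_max} exceeds rankable universe "
            f"(mouse {M_m}, human {len(human_order)})"
        )

    # per mouse transcript: smallest human rank among its partners (entry
    # rank into A(N)), counting each mouse transcript once however many
    # human top-N transcripts map to it
    pairs = omap.pairs[["human_transcript", "mouse_transcript"]]
    hr = human_rank.reindex(pairs["human_transcript"]).to_numpy()
    entry = (
        pd.DataFrame({"mouse": pairs["mouse_transcript"].to_numpy(), "hr": hr})
        .dropna()
        .groupby("mouse")["hr"]
        .min()
    )
    entry = entry.reindex(mouse_rank.index).dropna()
    a_entry = np.sort(entry.to_numpy())  # a(N) = #{entry <= N}
    both_entry = np.sort(
        np.maximum(entry.to_numpy(), mouse_rank.reindex(entry.index).to_numpy())
    )  # overlap(N) = #{max(entry, mouse rank) <= N}

    if grid is None:
        ranks = np.arange(1, rank_max + 1)
    else:
        ranks = np.asarray(sorted(set(int(g) for g in grid)))
        if ranks.min() < 1 or ranks.max() > rank_max:
            raise ValueError("grid ranks must lie in [1, rank_max]")
    a_N = np.searchsorted(a_entry, ranks, side="right")
    overlap = np.searchsorted(both_entry, ranks, side="right")

    alpha = 1.0 - cfg.band_level
    dist = sps.hypergeom(M_m, a_N, ranks)
    lo = dist.ppf(alpha / 2.0).astype(int)
    cdf_lo = dist.cdf(lo)
    lo = np.where(cdf_lo <= alpha / 2.0, lo + 1, lo)
    hi = dist.ppf(1.0 - alpha / 2.0).astype(int)
    lo = np.maximum(lo, np.maximum(0, ranks - (M_m - a_N)))
    hi = np.minimum(hi, np.minimum(ranks, a_N))
    return OverlapCurve(
        ranks=ranks,
        overlap=overlap,
        mapped_size=a_N,
        band_lo=lo,
        band_hi=hi,
        direction=direction,
        population=M_m,
    )


# ---------------------------------------------------------------------------
# 3x3 contingency and adjusted residuals
# ---------------------------------------------------------------------------


@dataclass
class ContingencyResult:
    """3x3 counts of (human label, mouse label) over ortholog pairs."""

    counts: pd.DataFrame  # index human labels, columns mouse labels

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(index=LABELS, columns=LABELS, fill_value=0)

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def expected(self) -> pd.DataFrame:
        O = self.counts.to_numpy(dtype=float)
        R = O.sum(axis=1, keepdims=True)
        C = O.sum(axis=0, keepdims=True)
        return pd.DataFrame(R @ C / O.sum(), index=self.counts.index, columns=self.counts.columns)

    def to_dict(self) -> Dict[str, Dict[str, int]]:
        return {h: {m: int(self.counts.loc[h, m]) for m in LABELS} for h in LABELS}


def classify_pairs(
    human_labels: pd.Series, mouse_labels: pd.Series, omap: OrthologMap
) -> ContingencyResult:
    """Assign every ortholog pair to one of nine DE categories and count."""
    pairs = omap.pairs
    h = human_labels.reindex(pairs["human_transcript"]).to_numpy()
    m = mouse_labels.reindex(pairs["mouse_transcript"]).to_numpy()
    missing = pd.isna(h) | pd.isna(m)
    if missing.any():
        example = pairs.loc[missing.nonzero()[0][0]]
        raise ValueError(
            f"pair with missing label, e.g. ({example['human_transcript']}, "
            f"{example['mouse_transcript']})"
        )
    counts = pd.crosstab(pd.Categorical(h, LABELS), pd.Categorical(m, LABELS), dropna=False)
    counts.index = pd.Index(LABELS, name="human")
    counts.columns = pd.Index(LABELS, name="mouse")
    return ContingencyResult(counts=counts)


def adjusted_residuals(
    c: ContingencyResult, cutoff: float = 3.0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized cell deviations, ~N(0,1) per cell under independence.

    r_ij = (O_ij - E_ij) / sqrt(E_ij (1 - R_i/T)(1 - C_j/T)).  Returns the
    residual matrix and a boolean matrix flagging |r| > cutoff.
    """
    O = c.counts.to_numpy(dtype=float)
    T = O.sum()
    R = O.sum(axis=1)
    C = O.sum(axis=0)
    if np.any(R == 0) or np.any(C == 0):
        raise ValueError("zero row or column margin; residuals undefined")
    E = np.outer(R, C) / T
    denom = np.sqrt(E * (1.0 - R[:, None] / T) * (1.0 - C[None, :] / T))
    resid = (O - E) / denom
    resid_df = pd.DataFrame(resid, index=c.counts.index, columns=c.counts.columns)
    return resid_df, resid_df.abs() > cutoff


# ---------------------------------------------------------------------------
# detection-rate curves
# ---------------------------------------------------------------------------


@dataclass
class DetectionRateResult:
    """Cumulative detection of foreground vs background along a human ranking."""

    ranks: np.ndarray
    foreground_curve: np.ndarray
    background_curve: np.ndarray
    area: float
    n_foreground: int
    n_background: int


def detection_rate_curves(
    human: pd.DataFrame,
    mouse: pd.DataFrame,
    omap: OrthologMap,
    direction: str = "up",
    cfg: Optional[AnalysisConfig] = None,
) -> DetectionRateResult:
    """Area between foreground and background detection curves.

    Foreground: human transcripts orthologous to the ``foreground_size``
    mouse transcripts most strongly altered in the stated direction at
    p < mouse_alpha.  Background: human transcripts orthologous to mouse
    transcripts not altered (p > background_p).  Human transcripts are
    scanned in fold-change order (descending for ``up``); each curve is the
    cumulative fraction of its set encountered; the area is the mean of
    (foreground - background) over all ranks, positive when foreground
    genes concentrate near the top.
    """
    cfg = cfg or AnalysisConfig()
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    ascending = direction == "down"
    mouse_sorted = mouse.sort_values("log2fc", ascending=ascending, kind="stable")
    sig = mouse_sorted[mouse_sorted["p"] < cfg.mouse_alpha]
    fg_mouse = sig.head(cfg.foreground_size).index
    bg_mouse = mouse.index[mouse["p"] > cfg.background_p]

    fg_human = set(omap.human_orthologs(fg_mouse)) & set(human.index)
    bg_human = set(omap.human_orthologs(bg_mouse)) & set(human.index)
    if len(fg_human) < 10:
        raise ValueError(
            f"foreground maps to only {len(fg_human)} human transcripts (<10)"
        )

    order = human["log2fc"].sort_values(ascending=ascending, kind="stable").index
    in_fg = order.isin(fg_human)
    in_bg = order.isin(bg_human)
    fg_curve = np.cumsum(in_fg) / len(fg_human)
    bg_curve = np.cumsum(in_bg) / max(len(bg_human), 1)
    area = float(np.mean(fg_curve - bg_curve))
    return DetectionRateResult(
        ranks=np.arange(1, len(order) + 1),
        foreground_curve=fg_curve,
        background_curve=bg_curve,
        area=area,
        n_foreground=len(fg_human),
        n_background=len(bg_human),
    )


# ---------------------------------------------------------------------------
# running enrichment score (unweighted GSEA)
# ---------------------------------------------------------------------------


@dataclass
class GseaResult:
    """Running enrichment score of a gene set along a ranking.

    The running sum gains 1/|S| at each set member ("hit") and loses
    1/(M - |S|) at each non-member; it starts and ends at 0.  ES is the
    running value of greatest absolute magnitude (ties resolve positive).
    """

    ranking_size: int
    set_size: int
    es: float
    es_position: int
    running: Optional[np.ndarray] = None
    null_es: Optional[np.ndarray] = None
    p: Optional[float] = None
    band: Optional[float] = None
    seed: Optional[int] = None


def _es_from_positions(positions: np.ndarray, M: int, s: int) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized ES for rows of sorted 0-based hit positions.

    The running extrema occur only at hits (local maxima candidates) or just
    before hits (local minima candidates); with i hits among the first
    p_i + 1 entries, the value at the i-th hit is i/s - (p_i + 1 - i)/(M - s)
    and the value just before it is (i - 1)/s - (p_i - (i - 1))/(M - s).
    Returns (es, argmax position) per row.
    """
    if positions.ndim == 1:
        positions = positions[None, :]
    B = positions.shape[0]
    i = np.arange(1, s + 1, dtype=float)
    hit = i / s - (positions + 1 - i) / (M - s)
    pre = (i - 1.0) / s - (positions - (i - 1.0)) / (M - s)
    max_pos = hit.max(axis=1)
    min_neg = np.minimum(pre.min(axis=1), 0.0)
    take_pos = max_pos >= -min_neg - 1e-12  # ties resolve positive
    es = np.where(take_pos, max_pos, min_neg)
    pos_idx = positions[np.arange(B), hit.argmax(axis=1)]
    neg_idx = positions[np.arange(B), pre.argmin(axis=1)] - 1
    es_at = np.where(take_pos, pos_idx, neg_idx).astype(int)
    return es, es_at


def gsea_running_score(ranking: Sequence[str], S: Iterable[str]) -> GseaResult:
    """Unweighted running enrichment score of set S along a gene ranking."""
    ranking = list(ranking)
    M = len(ranking)
    S = set(S)
    if not S:
        raise ValueError("gene set S is empty")
    unknown = S - set(ranking)
    if unknown:
        raise ValueError(f"set members absent from ranking: {sorted(unknown)[:5]}")
    s = len(S)
    if s == M:
        raise ValueError("S equals the whole ranking; score undefined")
    is_hit = np.fromiter((g in S for g in ranking), dtype=bool, count=M)
    steps = np.where(is_hit, 1.0 / s, -1.0 / (M - s))
    running = np.cumsum(steps)
    positions = np.sort(np.nonzero(is_hit)[0])
    es_arr, es_at = _es_from_positions(positions, M, s)
    return GseaResult(
        ranking_size=M,
        set_size=s,
        es=float(es_arr[0]),
        es_position=int(es_at[0]),
        running=running,
    )


def gsea_null(
    result: GseaResult,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> GseaResult:
    """Permutation null for an enrichment score: random same-size gene sets.

    Draws ``n_perm`` uniform random sets of ``set_size`` positions from the
    ranking and computes their ES.  The two-sided p-value is
    (1 + #{|null ES| >= |ES|}) / (n_perm + 1); the band is the 95th
    percentile of the null ES for positive scores (5th for negative), i.e.
    the edge of the lower 95% of the null.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if rng is None:
        rng = np.random.default_rng(seed)
    M, s = result.ranking_size, result.set_size
    null = np.empty(n_perm)
    chunk = max(1, min(n_perm, int(5e6 / max(M, 1))))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        u = rng.random((b, M))
        pos = np.sort(np.argpartition(u, s - 1, axis=1)[:, :s], axis=1)
        null[done : done + b] = _es_from_positions(pos, M, s)[0]
        done += b
    p = (1.0 + np.sum(np.abs(null) >= abs(result.es))) / (n_perm + 1.0)
    band = float(np.quantile(null, 0.95 if result.es >= 0 else 0.05))
    return GseaResult(
        ranking_size=M,
        set_size=s,
        es=result.es,
        es_position=result.es_position,
        running=result.running,
        null_es=null,
        p=float(p),
        band=band,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# consensus genes across models
# ---------------------------------------------------------------------------


@dataclass
class ConsensusResult:
    """Genes significant in the same direction in all models, with Monte-Carlo p."""

    genes: List[str]
    observed: int
    null_sample: np.ndarray
    p: float
    direction: str
    seed: Optional[int] = None


def consensus_gene_test(
    per_model_labels: Mapping[str, pd.Series],
    mappable: Iterable[str],
    direction: str = "up",
    n_sim: int = 10000,
    seed: Optional[int] = None,
    universe: Optional[Sequence[str]] = None,
) -> ConsensusResult:
    """Monte-Carlo significance for the cross-model consensus gene count.

    ``per_model_labels`` maps model name -> {up, down, ns} labels over a
    shared gene universe.  Observed = genes labeled ``direction`` in every
    model that are also *mappable* (have an ortholog).  The null draws,
    independently per model, a uniform random subset matching that model's
    significant-gene count, intersects across models, and thins by the
    mappable proportion.  The intersection chain is simulated exactly with
    nested hypergeometric draws (the overlap of a fresh uniform subset with
    any fixed set is hypergeometric, and the running intersection stays
    conditionally uniform), which is equivalent to drawing the subsets
    outright.
    """
    if len(per_model_labels) < 2:
        raise ValueError("need >=2 models")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    labels = list(per_model_labels.values())
    if universe is None:
        universe = labels[0].index
    universe = pd.Index(universe)
    G = len(universe)
    mappable_set = set(mappable)

    sig_sets = []
    for name, lab in per_model_labels.items():
        lab = lab.reindex(universe)
        genes = set(lab.index[lab == direction])
        if len(genes) > G:
            raise ValueError(f"model {name}: significant count exceeds universe")
        sig_sets.append(genes)
    consensus = set.intersection(*sig_sets) & mappable_set
    observed = len(consensus)
    m_k = [len(s) for s in sig_sets]
    phi = len(mappable_set & set(universe)) / G

    rng = np.random.default_rng(seed)
    inter = np.full(n_sim, m_k[0], dtype=np.int64)
    for m in m_k[1:]:
        nonzero = inter > 0
        drawn = np.zeros(n_sim, dtype=np.int64)
        if m > 0 and nonzero.any():
            drawn[nonzero] = sps.hypergeom.rvs(
                G, inter[nonzero], m, random_state=rng
            )
        inter = drawn
    thinned = rng.binomial(inter, phi)
    p = (1.0 + np.sum(thinned >= observed)) / (n_sim + 1.0)
    return ConsensusResult(
        genes=sorted(consensus),
        observed=observed,
        null_sample=thinned,
        p=float(p),
        direction=direction,
        seed=seed,
    )
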