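"""Term-level correspondence.

Over-representation of DE transcripts among annotation terms (one-sided
hypergeometric, optionally conditional on a parent/child term hierarchy),
per-term cross-species fold-change t-tests, concordant/discordant ortholog
pair subsets, and signature-set mean fold-change scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import GeneSet, GeneSetCollection, OrthologMap

logger = logging.getLogger(__name__)


@dataclass
class EnrichedTerm:
    """One term's over-representation result among a DE selection."""

    term_id: str
    name: str
    k: int  # DE members
    K: int  # background members
    n_de: int
    n_background: int
    p: float
    conditional: bool = False

    def to_dict(self) -> Dict[str, object]:
        return {
            "term_id": self.term_id,
            "name": self.name,
            "k": self.k,
            "K": self.K,
            "n_de": self.n_de,
            "n_background": self.n_background,
            "p": self.p,
            "conditional": self.conditional,
        }


def _topological_leaves_first(
    term_ids: Sequence[str], relation: Mapping[str, Iterable[str]]
) -> List[str]:
    """Order terms so every child precedes its parents.

    ``relation`` maps parent -> children.  Terms without hierarchy
    information keep their input order.
    """
    children = {t: set(relation.get(t, ())) & set(term_ids) for t in term_ids}
    ordered: List[str] = []
    seen: Set[str] = set()

    def visit(t: str, stack: Set[str]) -> None:
        if t in seen:
            return
        if t in stack:
            raise ValueError(f"cycle in term relation at {t!r}")
        stack.add(t)
        for c in sorted(children[t]):
            visit(c, stack)
        stack.discard(t)
        seen.add(t)
        ordered.append(t)

    for t in term_ids:
        visit(t, set())
    return ordered


def overrepresentation_test(
    de_set: Iterable[str],
    annotation: GeneSetCollection,
    background: Iterable[str],
    conditional: bool = False,
    relation: Optional[Mapping[str, Iterable[str]]] = None,
    min_size: int = 10,
    alpha: float = 0.05,
) -> List[EnrichedTerm]:
    """One-sided hypergeometric over-representation of *de_set* per term.

    Term members outside *background* are dropped (warned).  With
    ``conditional=True`` and a parent->children *relation*, terms are tested
    leaves-first and the members of already-significant (p < alpha)
    descendants are removed from each parent before testing, so parents are
    only credited with signal their significant children do not explain.
    Terms with fewer than *min_size* DE members are filtered from the
    output.  Results are sorted by p.
    """
    background = set(map(str, background))
    if not background:
        raise ValueError("background is empty")
    de = set(map(str, de_set)) & background
    if len(de) < len(set(map(str, de_set))):
        logger.warning(
            "overrepresentation: %d DE ids outside background dropped",
            len(set(map(str, de_set))) - len(de),
        )
    N = len(background)
    n = len(de)

    if conditional and relation is None:
        logger.warning("conditional=True but no relation supplied; running unconditional")
        conditional = False

    term_ids = annotation.ids()
    order = (
        _topological_leaves_first(term_ids, relation) if conditional else list(term_ids)
    )
    removed: Dict[str, Set[str]] = {t: set() for t in term_ids}
    significant_members: Dict[str, Set[str]] = {}
    parents_of: Dict[str, List[str]] = {t: [] for t in term_ids}
    if conditional:
        for parent, kids in relation.items():
            for c in kids:
                if c in parents_of:
                    parents_of[c].append(parent)

    results: List[EnrichedTerm] = []
    for term_id in order:
        gs = annotation[term_id]
        members = (set(gs.members) & background) - removed[term_id]
        K = len(members)
        k = len(members & de)
        if K == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(k - 1, N, K, n))
        if conditional and p < alpha:
            # propagate this term's members up to all ancestors
            frontier = list(parents_of.get(term_id, []))
            while frontier:
                a = frontier.pop()
                if a in removed and not members <= removed[a]:
                    removed[a] |= members
                    frontier.extend(parents_of.get(a, []))
        results.append(
            EnrichedTerm(
                term_id=term_id,
                name=gs.name,
                k=k,
                K=K,
                n_de=n,
                n_background=N,
                p=min(max(p, 0.0), 1.0),
                conditional=conditional,
            )
        )
    kept = [r for r in results if r.k >= min_size]
    kept.sort(key=lambda r: (r.p, r.term_id))
    return kept


@dataclass
class TermCorrespondence:
    """Cross-species fold-change behaviour of one term's mouse orthologs.

    ``n_human``/``n_mouse`` are the bracketed [x/y] counts; the t-test is a
    one-sample two-tailed t of the mouse log2 fold changes against zero.
    ``call`` is ``concordant_up``/``concordant_down`` when the mean agrees
    in sign with the human selection and p < 0.05, ``discordant`` when it
    disagrees significantly, else ``ns``; ``marginal`` flags 0.05 <= p < 0.10.
    """

    term_id: str
    n_human: int
    n_mouse: int
    mean_mouse_log2fc: float
    t_stat: float
    p: float
    call: str
    marginal: bool = False
    degenerate: bool = False

    def to_dict(self) -> Dict[str, object]:
        return {
            "term_id": self.term_id,
            "n_human": self.n_human,
            "n_mouse": self.n_mouse,
            "mean_mouse_log2fc": self.mean_mouse_log2fc,
            "t_stat": self.t_stat,
            "p": self.p,
            "call": self.call,
            "marginal": self.marginal,
        }


def term_correspondence(
    term_id: str,
    human_members: Iterable[str],
    omap: OrthologMap,
    mouse: pd.DataFrame,
    human_direction: str = "up",
) -> TermCorrespondence:
    """Average mouse fold change over a term's ortholog transcripts, with t-test.

    Mouse transcripts reached via several human members are counted once.
    With fewer than 2 mapped transcripts (or zero variance) the mean is
    reported and the test flagged degenerate.
    """
    human_members = list(dict.fromkeys(map(str, human_members)))
    n_human = len(human_members)
    mapped = omap.mouse_orthologs(human_members)
    lfc = mouse["log2fc"].reindex(mapped).dropna()
    n_mouse = len(lfc)
    if n_mouse == 0:
        raise ValueError(f"term {term_id!r}: no mapped mouse transcripts")
    mean = float(lfc.mean())
    if n_mouse < 2 or float(lfc.std(ddof=1)) == 0.0:
        return TermCorrespondence(
            term_id=term_id,
            n_human=n_human,
            n_mouse=n_mouse,
            mean_mouse_log2fc=mean,
            t_stat=np.nan,
            p=np.nan,
            call="ns",
            degenerate=True,
        )
    t, p = sps.ttest_1samp(lfc.to_numpy(), 0.0)
    p = float(p)
    concordant = (mean >= 0) == (human_direction == "up")
    if p < 0.05:
        call = ("concordant_up" if mean >= 0 else "concordant_down") if concordant else "discordant"
    else:
        call = "ns"
    return TermCorrespondence(
        term_id=term_id,
        n_human=n_human,
        n_mouse=n_mouse,
        mean_mouse_log2fc=mean,
        t_stat=float(t),
        p=p,
        call=call,
        marginal=0.05 <= p < 0.10,
    )


def concordant_discordant_subsets(
    human_labels: pd.Series, mouse_labels: pd.Series, omap: OrthologMap
) -> Dict[str, pd.DataFrame]:
    """Split labeled ortholog pairs into up-up / down-down / up-down / down-up.

    Pairs where either side is ``ns`` (or unlabeled) belong to no subset.
    The four subsets are disjoint and each is directly usable as a DE
    selection for over-representation testing.
    """
    pairs = omap.pairs[["human_transcript", "mouse_transcript"]].copy()
    pairs["human_label"] = human_labels.reindex(pairs["human_transcript"]).to_numpy()
    pairs["mouse_label"] = mouse_labels.reindex(pairs["mouse_transcript"]).to_numpy()
    out: Dict[str, pd.DataFrame] = {}
    for key, (hl, ml) in {
        "up_up": ("up", "up"),
        "down_down": ("down", "down"),
        "up_down": ("up", "down"),
        "down_up": ("down", "up"),
    }.items():
        sel = pairs[(pairs["human_label"] == hl) & (pairs["mouse_label"] == ml)]
        out[key] = sel.reset_index(drop=True)
    return out


@dataclass
class SignatureScore:
    """Mean fold change of a transcript set with a one-sample t-test."""

    set_id: str
    n_members: int
    n_present: int
    mean_log2fc: float
    t_stat: float
    p: float
    degenerate: bool = False

    def to_dict(self) -> Dict[str, object]:
        return {
            "set_id": self.set_id,
            "n_members": self.n_members,
            "n_present": self.n_present,
            "mean_log2fc": self.mean_log2fc,
            "t_stat": self.t_stat,
            "p": self.p,
        }


def signature_set_score(gene_set: GeneSet, table: pd.DataFrame) -> SignatureScore:
    """Average log2 fold change of a gene set's members present in a DE table.

    Two-tailed one-sample t of the member fold changes against zero; with
    fewer than 2 members present (or zero variance) the score is flagged
    degenerate and no test is reported.
    """
    lfc = table["log2fc"].reindex(gene_set.members).dropna()
    n_present = len(lfc)
    if n_present == 0:
        raise ValueError(f"set {gene_set.set_id!r}: no members present in table")
    mean = float(lfc.mean())
    if n_present < 2 or float(lfc.std(ddof=1)) == 0.0:
        return SignatureScore(
            set_id=gene_set.set_id,
            n_members=len(gene_set.members),
            n_present=n_present,
            mean_log2fc=mean,
            t_stat=np.nan,
            p=np.nan,
            degenerate=True,
        )
    t, p = sps.ttest_1samp(lfc.to_numpy(), 0.0)
    return SignatureScore(
        set_id=gene_set.set_id,
        n_members=len(gene_set.members),
        n_present=n_present,
        mean_log2fc=mean,
        t_stat=float(t),
        p=float(p),
    )


def read_term_relation(path) -> Dict[str, List[str]]:
    """Read a two-column tab-delimited parent/child term relation file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"], dtype=str)
    rel: Dict[str, List[str]] = {}
    for parent, child in df.itertuples(index=False):
        rel.setdefault(parent, []).append(child)
    return rel
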