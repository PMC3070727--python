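"""Microarray-based immunophenotyping.

Infers which cell populations (mostly leukocyte subsets) infiltrate a
lesion from bulk expression data: each population contributes a set of
"signature transcripts" highly expressed in that population relative to
normal skin; if the population invades the lesion, its signature
transcripts should be disproportionately elevated in lesional versus
normal skin.  Signatures derived on the mouse platform can be projected
into the human transcript space through the ortholog map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import AnalysisConfig
from .de import benjamini_hochberg
from .io import OrthologMap, PathLike

logger = logging.getLogger(__name__)

MIN_SIGNATURE = 5


@dataclass
class CellReference:
    """Log2 expression of cell populations plus the normal-skin baseline.

    ``expression`` is transcripts x populations; ``skin_baseline`` is the
    per-transcript log2 expression in normal skin on the same platform.
    """

    expression: pd.DataFrame
    skin_baseline: pd.Series

    def __post_init__(self) -> None:
        self.skin_baseline = self.skin_baseline.reindex(self.expression.index)
        if self.skin_baseline.isna().any():
            raise ValueError("skin_baseline missing for some transcripts")
        if not np.isfinite(self.expression.to_numpy(dtype=float)).all():
            raise ValueError("cell reference expression must be finite")

    @property
    def populations(self) -> List[str]:
        return list(self.expression.columns)


@dataclass
class SignatureSet:
    """Transcripts highly expressed in one population relative to skin."""

    population: str
    members: List[str]
    theta: float
    cap: int
    species: str = "mouse"


def derive_signatures(
    ref: CellReference, theta: float = 2.0, cap: int = 250
) -> List[SignatureSet]:
    """Signature transcripts per population: log2 excess over skin >= theta.

    Candidates are ranked by (population - baseline) and truncated to
    *cap*; populations yielding fewer than 5 members are excluded with a
    warning.  theta=2 corresponds to a 4-fold excess.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    out: List[SignatureSet] = []
    diffs = ref.expression.sub(ref.skin_baseline, axis=0)
    for pop in ref.populations:
        d = diffs[pop]
        cand = d[d >= theta].sort_values(ascending=False, kind="stable")
        members = list(cand.index[:cap])
        if len(members) < MIN_SIGNATURE:
            logger.warning(
                "population %s: only %d signature transcripts (<%d), excluded",
                pop,
                len(members),
                MIN_SIGNATURE,
            )
            continue
        out.append(SignatureSet(population=pop, members=members, theta=theta, cap=cap))
    return out


def inflammation_profile(
    sigs: Sequence[SignatureSet],
    table: pd.DataFrame,
    cfg: Optional[AnalysisConfig] = None,
    species: str = "mouse",
) -> pd.DataFrame:
    """Per-population lesion inflammation evidence from a DE table.

    For each population's signature: n1 = members with log2fc >= 0 in the
    lesion, n2 = members with log2fc < 0 (n1 + n2 = n), ratio = n1/n2 (inf
    when n2 = 0).  Significance is a one-sided binomial test of n1
    successes in n trials against p0 = the genome-wide fraction of
    transcripts with log2fc >= 0 (controls for global expression shifts),
    BH-corrected across populations; a population is flagged when
    q < 0.05.  Members absent from the table are dropped (logged);
    populations with n < 5 after dropping are excluded.
    """
    cfg = cfg or AnalysisConfig()
    all_lfc = table["log2fc"].to_numpy(dtype=float)
    p0 = float(np.mean(all_lfc >= 0))
    rows = []
    for sig in sigs:
        lfc = table["log2fc"].reindex(sig.members).dropna()
        dropped = len(sig.members) - len(lfc)
        if dropped:
            logger.info("population %s: %d signature members absent", sig.population, dropped)
        n = len(lfc)
        if n < MIN_SIGNATURE:
            logger.warning("population %s: n=%d (<%d), excluded", sig.population, n, MIN_SIGNATURE)
            continue
        n1 = int((lfc >= 0).sum())
        n2 = n - n1
        ratio = float("inf") if n2 == 0 else n1 / n2
        p = float(sps.binomtest(n1, n, p0, alternative="greater").pvalue)
        rows.append(
            {
                "population": sig.population,
                "n": n,
                "n1": n1,
                "n2": n2,
                "ratio": ratio,
                "p": p,
            }
        )
    if not rows:
        raise ValueError("no population with enough signature transcripts")
    prof = pd.DataFrame(rows).set_index("population")
    prof["q"] = benjamini_hochberg(prof["p"].to_numpy())
    prof["significant"] = prof["q"] < 0.05
    prof.attrs["species"] = species
    prof.attrs["p0"] = p0
    return prof


def project_signatures_to_human(
    sigs: Sequence[SignatureSet], omap: OrthologMap
) -> List[SignatureSet]:
    """Map mouse signatures to the union of their human ortholog transcripts.

    A mouse transcript with several human orthologs contributes all of
    them, so a projected signature may exceed the original size.
    Populations whose projected size is < 5 are excluded.
    """
    out: List[SignatureSet] = []
    for sig in sigs:
        human_members = list(omap.human_orthologs(sig.members))
        if len(human_members) < MIN_SIGNATURE:
            logger.warning(
                "population %s: projected signature has %d members (<%d), excluded",
                sig.population,
                len(human_members),
                MIN_SIGNATURE,
            )
            continue
        out.append(
            SignatureSet(
                population=sig.population,
                members=human_members,
                theta=sig.theta,
                cap=sig.cap,
                species="human",
            )
        )
    return out


def read_cell_reference(path: PathLike) -> CellReference:
    """Read a tab-delimited cell reference with a required skin_baseline column."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if "skin_baseline" not in df.columns:
        raise ValueError(f"{path}: missing required 'skin_baseline' column")
    baseline = df["skin_baseline"].astype(float)
    expr = df.drop(columns=["skin_baseline"]).astype(float)
    return CellReference(expression=expr, skin_baseline=baseline)


def write_cell_reference(ref: CellReference, path: PathLike) -> None:
    out = ref.expression.copy()
    out["skin_baseline"] = ref.skin_baseline
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")
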