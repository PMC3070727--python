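"""Differential-expression engine.

Per transcript, the effect is the log2 fold change (case mean minus control
mean) tested with a pooled-variance two-sample t statistic.  Optionally the
per-transcript variances are shrunk toward a common prior by empirical
Bayes: with prior degrees of freedom d0 and prior variance s0^2, the
moderated variance is

    s~g^2 = (d0 * s0^2 + dg * sg^2) / (d0 + dg),

and the statistic is referred to a t distribution on d0 + dg degrees of
freedom.  (d0, s0^2) are estimated by matching the first two moments of
log sg^2 to a scaled-F model via digamma/trigamma inversion, the classical
closed-form approach for microarray-scale experiments where per-transcript
variances at n = 2-3 per group are individually unreliable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .io import ExpressionMatrix, PathLike

logger = logging.getLogger(__name__)

DE_COLUMNS = ["gene", "log2fc", "stat", "p", "q", "direction"]


@dataclass
class ModerationParams:
    """Empirical-Bayes variance-shrinkage hyperparameters.

    ``d0`` may be ``numpy.inf`` (complete shrinkage: every transcript uses
    the prior variance ``s0_sq``).  With ``enabled=False`` the ordinary
    pooled t is used and the hyperparameters are ignored.
    """

    d0: float = np.inf
    s0_sq: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.enabled:
            if not self.d0 > 0:
                raise ValueError("d0 must be positive (may be inf)")
            if not self.s0_sq > 0:
                raise ValueError("s0_sq must be positive")


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x for y > 0 by Newton iteration.

    Uses the standard monotone parametrization; converges in a handful of
    iterations for any x > 0.
    """
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x  # starting value, exact as x -> 0
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y + dif
        if np.all(np.abs(dif) / y < 1e-10):
            break
    return y


def estimate_moderation(s2: np.ndarray, df: float) -> ModerationParams:
    """Estimate (d0, s0^2) from observed per-transcript variances.

    Matches mean and variance of z = log s2 under the scaled-F model
    s2 ~ s0^2 * F(df, d0):

        E[z]   = log s0^2 + psi(df/2) - log(df/2) - psi(d0/2) + log(d0/2)
        Var[z] = psi'(df/2) + psi'(d0/2)

    If the observed Var[z] does not exceed psi'(df/2), the excess
    variability is zero and d0 = inf (all transcripts share s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise ValueError("need >=2 positive variances to estimate moderation")
    z = np.log(s2)
    e = z.mean()
    v = z.var(ddof=1)
    evar = v - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        log_s0 = (
            e
            - float(special.digamma(df / 2.0))
            + np.log(df / 2.0)
            + float(special.digamma(d0 / 2.0))
            - np.log(d0 / 2.0)
        )
    else:
        d0 = np.inf
        log_s0 = e - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    return ModerationParams(d0=d0, s0_sq=float(np.exp(log_s0)), enabled=True)


def differential_expression(
    m: ExpressionMatrix,
    moderation: Optional[ModerationParams] = None,
) -> pd.DataFrame:
    """Per-transcript case-vs-control summary.

    Returns a DataFrame indexed by transcript id with columns ``gene,
    log2fc, stat, p, q, direction``.  ``direction`` is ``up`` when
    log2fc >= 0 (exact zeros count as up; measure-zero on continuous data)
    and ``down`` otherwise.  If *moderation* is ``None`` the hyperparameters
    are estimated from the data; pass ``ModerationParams(enabled=False)``
    for the ordinary pooled t.
    """
    n1, n2 = m.n_case, m.n_control
    if n1 < 2 or n2 < 2:
        raise ValueError("variance-based testing needs >=2 samples per group")
    case = m.values[m.case_samples].to_numpy(dtype=float)
    ctrl = m.values[m.control_samples].to_numpy(dtype=float)
    mean1 = case.mean(axis=1)
    mean2 = ctrl.mean(axis=1)
    lfc = mean1 - mean2
    v1 = case.var(axis=1, ddof=1)
    v2 = ctrl.var(axis=1, ddof=1)
    dg = n1 + n2 - 2
    s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dg

    if moderation is None:
        moderation = estimate_moderation(s2, dg)
    if moderation.enabled:
        d0, s0 = moderation.d0, moderation.s0_sq
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0 + dg * s2) / (d0 + dg)
            df_total = d0 + dg
    else:
        s2_tilde = s2
        df_total = dg

    if np.all(s2_tilde == 0):
        raise ValueError(
            "all transcripts have zero within-group variance; enable moderation "
            "or add a pseudo-variance floor"
        )

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.sign(lfc) * np.inf)
    t = np.where((se == 0) & (lfc == 0), 0.0, t)
    n_degenerate = int((se == 0).sum())
    if n_degenerate:
        logger.warning("%d transcripts with zero residual variance", n_degenerate)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = benjamini_hochberg(p)

    genes = (
        m.gene_symbols.reindex(m.transcript_ids)
        if m.gene_symbols is not None
        else pd.Series(index=m.transcript_ids, dtype=object)
    )
    out = pd.DataFrame(
        {
            "gene": genes.to_numpy(),
            "log2fc": lfc,
            "stat": t,
            "p": p,
            "q": q,
            "direction": np.where(lfc >= 0, "up", "down"),
        },
        index=m.transcript_ids,
    )
    out.index.name = "transcript_id"
    return out


def benjamini_hochberg(p) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values), input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


_ROLES = ("human_broad", "human_strict", "mouse")


def classify_de(
    table: pd.DataFrame,
    role: str,
    cfg: Optional[AnalysisConfig] = None,
) -> pd.Series:
    """Three-way {up, down, ns} labels under a named selection rule.

    ``human_broad``: q < human_fdr and |log2fc| > human_lfc_broad.
    ``human_strict``: q < human_fdr and |log2fc| > human_lfc_strict.
    ``mouse``: p < mouse_alpha (no fold-change cutoff).
    """
    cfg = cfg or AnalysisConfig()
    if role not in _ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {_ROLES}")
    lfc = table["log2fc"].to_numpy(dtype=float)
    if role == "mouse":
        sig = table["p"].to_numpy(dtype=float) < cfg.mouse_alpha
    else:
        cut = cfg.human_lfc_broad if role == "human_broad" else cfg.human_lfc_strict
        sig = (table["q"].to_numpy(dtype=float) < cfg.human_fdr) & (np.abs(lfc) > cut)
    labels = np.where(~sig, "ns", np.where(lfc >= 0, "up", "down"))
    out = pd.Series(labels, index=table.index, name="label")
    counts = out.value_counts()
    logger.info(
        "classify_de[%s]: up=%d down=%d ns=%d",
        role,
        counts.get("up", 0),
        counts.get("down", 0),
        counts.get("ns", 0),
    )
    return out


def collapse_expression_by_gene(m: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse transcripts to gene level by the per-sample maximum.

    One row per gene symbol; transcripts lacking a symbol are dropped (count
    logged).  The resulting index is the gene symbol.
    """
    if m.gene_symbols is None:
        raise ValueError("gene_symbols must be populated for gene-level collapse")
    symbols = m.gene_symbols.reindex(m.transcript_ids)
    has_symbol = symbols.notna() & (symbols.astype(str).str.len() > 0)
    n_dropped = int((~has_symbol).sum())
    if n_dropped:
        logger.info("collapse: dropped %d transcripts without gene symbol", n_dropped)
    vals = m.values.loc[has_symbol.to_numpy()]
    collapsed = vals.groupby(symbols[has_symbol].to_numpy()).max()
    collapsed.index.name = "transcript_id"
    genes = pd.Series(collapsed.index, index=collapsed.index)
    return ExpressionMatrix(
        species=m.species, values=collapsed, design=m.design, gene_symbols=genes
    )


def write_de_table(table: pd.DataFrame, path: PathLike) -> None:
    out = table.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")


def read_de_table(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    missing = [c for c in DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: DE table missing columns {missing}")
    return table
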