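"""Synthetic two-species dataset generator with planted correspondence.

Emulates the study design the pipeline targets: a large human case/control
cohort (58 lesional vs 64 normal samples) profiled on a ~55k-transcript
platform, and small mouse experiments (2-3 lesional vs 2-3 control
samples), joined by a many-to-many ortholog map covering ~61% of human
transcripts.  Expression is additive Gaussian on the log2 scale:

    value = baseline + effect * 1[case] + N(0, noise_sd).

Differential expression is planted per ortholog family (the connected
1:1 / 1:2 / 2:1 units of the map, singletons for unmapped transcripts):
each family is DE with probability ``pi_de`` and its human transcripts
share one signed effect (magnitude |N(effect_mean, effect_sd)|) — the
transcripts of a gene move together.  Each mouse member of a DE family is
concordant with probability ``rho``; a concordant transcript's effect is
``rho * e_h + sqrt(1 - rho^2) * z`` with z drawn from the same signed
effect law, so rho is a single dial from independence (0) to exact
sharing (1).  The generator also plants enriched annotation terms among DE
transcripts, builds a cell-population reference with disjoint signatures,
and spikes chosen population signatures into the mouse lesion samples.
Everything is written in the file dialects the readers consume, alongside
a TruthBundle recording what was planted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .immuno import CellReference, write_cell_reference
from .io import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    OrthologMap,
    PathLike,
    write_expression_matrix,
    write_gmt,
    write_ortholog_map,
)

logger = logging.getLogger(__name__)

DEFAULT_POPULATIONS = (
    "t_cell",
    "b_cell",
    "nk_cell",
    "dendritic_cell",
    "macrophage",
    "monocyte",
    "granulocyte",
    "treg",
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults reflect the emulated study design."""

    n_human_transcripts: int = 6000
    n_mouse_transcripts: int = 5500
    n_human_case: int = 58
    n_human_control: int = 64
    n_mouse_case: int = 3
    n_mouse_control: int = 3
    ortholog_coverage: float = 0.61
    fanout_1to1: float = 0.8
    fanout_1to2: float = 0.1
    fanout_2to1: float = 0.1
    pi_de: float = 0.15
    p_up: float = 0.45
    rho: float = 0.6
    effect_mean: float = 1.0
    effect_sd: float = 0.5
    pi_de_mouse_extra: float = 0.05
    noise_sd_human: float = 1.0
    noise_sd_mouse: float = 0.5
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    frac_multi_transcript_genes: float = 0.12
    n_terms: int = 40
    term_size_min: int = 10
    term_size_max: int = 120
    frac_enriched_terms: float = 0.3
    enrichment_odds: float = 8.0
    populations: Tuple[str, ...] = DEFAULT_POPULATIONS
    signature_size: int = 100
    signature_delta: float = 3.0
    reference_noise_sd: float = 0.25
    spikes: Mapping[str, float] = field(default_factory=lambda: {"macrophage": 1.0})
    spike_human_coupled: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        probs = {
            "ortholog_coverage": self.ortholog_coverage,
            "pi_de": self.pi_de,
            "p_up": self.p_up,
            "rho": self.rho,
            "pi_de_mouse_extra": self.pi_de_mouse_extra,
            "frac_enriched_terms": self.frac_enriched_terms,
            "frac_multi_transcript_genes": self.frac_multi_transcript_genes,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        fan = self.fanout_1to1 + self.fanout_1to2 + self.fanout_2to1
        if abs(fan - 1.0) > 1e-9:
            raise ValueError("fanout probabilities must sum to 1")
        if self.pi_de * self.n_human_transcripts > self.n_human_transcripts:
            raise ValueError("infeasible pi_de")
        for name in (
            "n_human_transcripts",
            "n_mouse_transcripts",
            "n_human_case",
            "n_human_control",
            "n_mouse_case",
            "n_mouse_control",
            "n_terms",
            "signature_size",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.spikes) - set(self.populations)
        if unknown:
            raise ValueError(f"spiked populations not in panel: {sorted(unknown)}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["populations"] = list(self.populations)
        d["spikes"] = dict(self.spikes)
        return d


@dataclass
class TruthBundle:
    """What the generator planted, for test bookkeeping."""

    human_effects: pd.Series  # signed log2 effect per human transcript (0 = null)
    mouse_effects: pd.Series
    concordant_pairs: pd.DataFrame  # human_transcript, mouse_transcript, concordant flag
    enriched_terms: List[str]
    spiked_populations: Dict[str, float]
    fanout_counts: Dict[str, int]
    seed: int

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "human_effects": {k: float(v) for k, v in self.human_effects.items() if v != 0},
            "mouse_effects": {k: float(v) for k, v in self.mouse_effects.items() if v != 0},
            "concordant_pairs": self.concordant_pairs.to_dict(orient="list"),
            "enriched_terms": self.enriched_terms,
            "spiked_populations": self.spiked_populations,
            "fanout_counts": self.fanout_counts,
        }


@dataclass
class SyntheticDataset:
    """In-memory bundle of one generated two-species experiment."""

    config: SyntheticConfig
    human: ExpressionMatrix
    mouse: ExpressionMatrix
    orthologs: OrthologMap
    terms: GeneSetCollection
    cell_reference: CellReference
    truth: TruthBundle

    def write(self, outdir: PathLike) -> Dict[str, str]:
        """Write every component in the pipeline's file dialects; returns the index."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = {
            "human_expression": "human_expression.tsv",
            "human_design": "human_design.tsv",
            "mouse_expression": "mouse_expression.tsv",
            "mouse_design": "mouse_design.tsv",
            "human_symbols": "human_symbols.tsv",
            "mouse_symbols": "mouse_symbols.tsv",
            "orthologs": "orthologs.csv",
            "terms": "terms.gmt",
            "cell_reference": "cell_reference.tsv",
            "truth": "truth.json",
        }
        write_expression_matrix(
            self.human, outdir / files["human_expression"], outdir / files["human_design"]
        )
        write_expression_matrix(
            self.mouse, outdir / files["mouse_expression"], outdir / files["mouse_design"]
        )
        self.human.gene_symbols.to_csv(outdir / files["human_symbols"], sep="\t", header=False)
        self.mouse.gene_symbols.to_csv(outdir / files["mouse_symbols"], sep="\t", header=False)
        write_ortholog_map(self.orthologs, outdir / files["orthologs"])
        write_gmt(self.terms, outdir / files["terms"])
        write_cell_reference(self.cell_reference, outdir / files["cell_reference"])
        with open(outdir / files["truth"], "w", encoding="utf-8") as fh:
            json.dump(self.truth.to_json_dict(), fh, indent=1, sort_keys=True)
        return {k: str(outdir / v) for k, v in files.items()}


def _signed_effects(rng: np.random.Generator, size: int, cfg: SyntheticConfig) -> np.ndarray:
    mag = np.abs(rng.normal(cfg.effect_mean, cfg.effect_sd, size=size))
    sign = np.where(rng.random(size) < cfg.p_up, 1.0, -1.0)
    return mag * sign


def _assign_symbols(
    rng: np.random.Generator, ids: Sequence[str], prefix: str, frac_multi: float
) -> pd.Series:
    """Gene symbols with a fraction of genes carrying two transcripts."""
    n = len(ids)
    n_multi = int(round(frac_multi * n / 2.0))
    symbols = np.empty(n, dtype=object)
    gene_no = 0
    i = 0
    order = rng.permutation(n)
    while i < n:
        take = 2 if (gene_no < n_multi and i + 1 < n) else 1
        sym = f"{prefix}{gene_no:05d}"
        for j in range(take):
            symbols[order[i + j]] = sym
        i += take
        gene_no += 1
    return pd.Series(symbols, index=pd.Index(ids))


def _build_ortholog_map(
    rng: np.random.Generator,
    human_ids: Sequence[str],
    mouse_ids: Sequence[str],
    human_symbols: pd.Series,
    mouse_symbols: pd.Series,
    cfg: SyntheticConfig,
) -> Tuple[OrthologMap, Dict[str, int], List[Tuple[List[str], List[str]]]]:
    """Sequentially assemble 1:1 / 1:2 / 2:1 ortholog families.

    Returns the map, the fanout-unit counts, and the family list (each a
    (human members, mouse members) tuple); families are disjoint by
    construction.
    """
    n_mapped = int(round(cfg.ortholog_coverage * len(human_ids)))
    humans = list(rng.permutation(np.asarray(human_ids))[:n_mapped])
    mouse_pool = list(rng.permutation(np.asarray(mouse_ids)))
    rows: List[Tuple[str, str]] = []
    families: List[Tuple[List[str], List[str]]] = []
    counts = {"1to1": 0, "1to2": 0, "2to1": 0}
    hi = 0
    mi = 0
    while hi < len(humans) and mi < len(mouse_pool):
        u = rng.random()
        if u < cfg.fanout_1to1 or hi == len(humans) - 1:
            rows.append((humans[hi], mouse_pool[mi]))
            families.append(([humans[hi]], [mouse_pool[mi]]))
            counts["1to1"] += 1
            hi += 1
            mi += 1
        elif u < cfg.fanout_1to1 + cfg.fanout_1to2:
            if mi + 1 >= len(mouse_pool):
                rows.append((humans[hi], mouse_pool[mi]))
                families.append(([humans[hi]], [mouse_pool[mi]]))
                counts["1to1"] += 1
                hi += 1
                mi += 1
                continue
            rows.append((humans[hi], mouse_pool[mi]))
            rows.append((humans[hi], mouse_pool[mi + 1]))
            families.append(([humans[hi]], [mouse_pool[mi], mouse_pool[mi + 1]]))
            counts["1to2"] += 1
            hi += 1
            mi += 2
        else:
            rows.append((humans[hi], mouse_pool[mi]))
            rows.append((humans[hi + 1], mouse_pool[mi]))
            families.append(([humans[hi], humans[hi + 1]], [mouse_pool[mi]]))
            counts["2to1"] += 1
            hi += 2
            mi += 1
    pairs = pd.DataFrame(rows, columns=["human_transcript", "mouse_transcript"])
    pairs["human_gene"] = human_symbols.reindex(pairs["human_transcript"]).to_numpy()
    pairs["mouse_gene"] = mouse_symbols.reindex(pairs["mouse_transcript"]).to_numpy()
    return OrthologMap(pairs=pairs), counts, families


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate one fully specified two-species dataset (deterministic in seed)."""
    rng = np.random.default_rng(cfg.seed)

    human_ids = [f"HT{i:06d}" for i in range(cfg.n_human_transcripts)]
    mouse_ids = [f"MT{i:06d}" for i in range(cfg.n_mouse_transcripts)]
    human_symbols = _assign_symbols(rng, human_ids, "HG", cfg.frac_multi_transcript_genes)
    mouse_symbols = _assign_symbols(rng, mouse_ids, "MG", cfg.frac_multi_transcript_genes)

    omap, fanout_counts, families = _build_ortholog_map(
        rng, human_ids, mouse_ids, human_symbols, mouse_symbols, cfg
    )

    # plant differential expression per ortholog family: every human
    # transcript of a DE family shares one signed effect (transcripts of
    # one gene move together), so at rho=1 every pair is concordant
    mapped_humans = {h for fam in families for h in fam[0]}
    unmapped = [h for h in human_ids if h not in mapped_humans]
    units: List[Tuple[List[str], List[str]]] = families + [([h], []) for h in unmapped]
    n_units = len(units)
    de_mask = rng.random(n_units) < cfg.pi_de
    unit_eff = np.where(de_mask, _signed_effects(rng, n_units, cfg), 0.0)

    human_effects = pd.Series(0.0, index=pd.Index(human_ids))
    mouse_effects = pd.Series(0.0, index=pd.Index(mouse_ids))
    conc_rows: List[Tuple[str, str, bool]] = []
    sqrt_resid = np.sqrt(max(1.0 - cfg.rho**2, 0.0))
    for (h_members, m_members), is_de, e_h in zip(units, de_mask, unit_eff):
        if not is_de:
            continue
        for h in h_members:
            human_effects.loc[h] = e_h
        for m in m_members:
            concordant = bool(rng.random() < cfg.rho)
            if concordant:
                # direction inherited; magnitude law preserved via a
                # sign-aligned residual
                z = float(np.sign(e_h) * abs(rng.normal(cfg.effect_mean, cfg.effect_sd)))
                mouse_effects.loc[m] = cfg.rho * e_h + sqrt_resid * z
            conc_rows.append((h_members[0], m, concordant))
    concordant_pairs = pd.DataFrame(
        conc_rows, columns=["human_transcript", "mouse_transcript", "concordant"]
    )

    # independent mouse-only differential expression
    untouched = mouse_effects.index[mouse_effects == 0.0]
    n_extra = int(round(cfg.pi_de_mouse_extra * cfg.n_mouse_transcripts))
    n_extra = min(n_extra, len(untouched))
    if n_extra:
        extra_ids = rng.choice(untouched.to_numpy(), size=n_extra, replace=False)
        mouse_effects.loc[extra_ids] = _signed_effects(rng, n_extra, cfg)

    # expression matrices
    def build_matrix(
        ids: Sequence[str],
        effects: pd.Series,
        n_case: int,
        n_control: int,
        noise_sd: float,
        species: str,
        symbols: pd.Series,
    ) -> ExpressionMatrix:
        n = len(ids)
        baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=n)
        n_samples = n_case + n_control
        noise = rng.normal(0.0, noise_sd, size=(n, n_samples))
        group = np.array([1.0] * n_case + [0.0] * n_control)
        vals = baseline[:, None] + np.outer(effects.to_numpy(), group) + noise
        cols = [f"{species}_case_{i}" for i in range(n_case)] + [
            f"{species}_ctrl_{i}" for i in range(n_control)
        ]
        design = pd.Series(["case"] * n_case + ["control"] * n_control, index=cols)
        return ExpressionMatrix(
            species=species,
            values=pd.DataFrame(vals, index=pd.Index(ids), columns=cols),
            design=design,
            gene_symbols=symbols,
        )

    human = build_matrix(
        human_ids,
        human_effects,
        cfg.n_human_case,
        cfg.n_human_control,
        cfg.noise_sd_human,
        "human",
        human_symbols,
    )
    mouse = build_matrix(
        mouse_ids,
        mouse_effects,
        cfg.n_mouse_case,
        cfg.n_mouse_control,
        cfg.noise_sd_mouse,
        "mouse",
        mouse_symbols,
    )

    # annotation terms over human transcripts, some enriched among DE ones
    terms = GeneSetCollection()
    enriched_terms: List[str] = []
    is_de = human_effects.to_numpy() != 0.0
    de_ids = np.asarray(human_ids)[is_de]
    null_ids = np.asarray(human_ids)[~is_de]
    n_enriched = int(round(cfg.frac_enriched_terms * cfg.n_terms))
    for t in range(cfg.n_terms):
        size = int(rng.integers(cfg.term_size_min, cfg.term_size_max + 1))
        enriched = t < n_enriched
        if enriched:
            # weighted sampling: DE transcripts enter at enrichment_odds : 1
            w = np.concatenate(
                [np.full(len(de_ids), cfg.enrichment_odds), np.ones(len(null_ids))]
            )
            ids_all = np.concatenate([de_ids, null_ids])
            members = rng.choice(ids_all, size=size, replace=False, p=w / w.sum())
        else:
            members = rng.choice(np.asarray(human_ids), size=size, replace=False)
        set_id = f"TERM{t:03d}"
        terms.add(
            GeneSet(
                set_id=set_id,
                name=("planted enriched term" if enriched else "null term"),
                members=list(members),
                namespace="transcript",
                source="synthetic",
            )
        )
        if enriched:
            enriched_terms.append(set_id)

    # cell reference with disjoint signatures on the mouse platform
    skin_baseline = pd.Series(
        rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_mouse_transcripts),
        index=pd.Index(mouse_ids),
    )
    needed = cfg.signature_size * len(cfg.populations)
    if needed > cfg.n_mouse_transcripts:
        raise ValueError("signature panel larger than mouse universe")
    sig_pool = rng.permutation(np.asarray(mouse_ids))[:needed]
    ref_expr = pd.DataFrame(
        rng.normal(0.0, cfg.reference_noise_sd, size=(cfg.n_mouse_transcripts, len(cfg.populations))),
        index=pd.Index(mouse_ids),
        columns=list(cfg.populations),
    ).add(skin_baseline, axis=0)
    signature_members: Dict[str, List[str]] = {}
    for i, pop in enumerate(cfg.populations):
        members = list(sig_pool[i * cfg.signature_size : (i + 1) * cfg.signature_size])
        signature_members[pop] = members
        ref_expr.loc[members, pop] += cfg.signature_delta
    cell_reference = CellReference(expression=ref_expr, skin_baseline=skin_baseline)

    # spike chosen population signatures into mouse lesion samples; with
    # spike_human_coupled the human orthologs of the signature transcripts
    # are elevated in human cases too (a shared infiltrate in both species)
    for pop, magnitude in cfg.spikes.items():
        members = signature_members[pop]
        mouse.values.loc[members, mouse.case_samples] += magnitude
        if cfg.spike_human_coupled:
            human_members = omap.human_orthologs(members)
            human.values.loc[human_members, human.case_samples] += magnitude

    truth = TruthBundle(
        human_effects=human_effects,
        mouse_effects=mouse_effects,
        concordant_pairs=concordant_pairs,
        enriched_terms=enriched_terms,
        spiked_populations=dict(cfg.spikes),
        fanout_counts=fanout_counts,
        seed=cfg.seed,
    )
    return SyntheticDataset(
        config=cfg,
        human=human,
        mouse=mouse,
        orthologs=omap,
        terms=terms,
        cell_reference=cell_reference,
        truth=truth,
    )


def generate_null_labels(
    n_pairs: int,
    margins_human: Sequence[float],
    margins_mouse: Sequence[float],
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """I.i.d. (human, mouse) label pairs from the product of two marginals.

    Margins are (P(up), P(down), P(ns)) per species; labels are
    independent between species, supporting null calibration of the
    contingency analysis.
    """
    mh = np.asarray(margins_human, dtype=float)
    mm = np.asarray(margins_mouse, dtype=float)
    for name, m in (("margins_human", mh), ("margins_mouse", mm)):
        if m.shape != (3,) or np.any(m < 0) or abs(m.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} must be 3 non-negative values summing to 1")
    rng = np.random.default_rng(seed)
    labels = np.array(["up", "down", "ns"])
    h = rng.choice(labels, size=n_pairs, p=mh)
    m = rng.choice(labels, size=n_pairs, p=mm)
    return pd.DataFrame({"human_label": h, "mouse_label": m})
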