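"""Pipeline orchestration and cross-model report assembly.

``run_correspondence`` executes the full battery of correspondence
statistics for one mouse model against one human DE table;
``build_report`` aggregates several models into the cross-model comparison
tables (per-model correlation, concordance percentages, term matrix,
inflammation matrix, consensus genes).  ``RunManifest`` records the
configuration, input checksums, seed and outputs of a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .de import classify_de
from .io import OrthologMap, PathLike
from .pairing import build_pair_table, fold_change_correlation, mahalanobis_core
from .stats import (
    adjusted_residuals,
    classify_pairs,
    detection_rate_curves,
    gsea_null,
    gsea_running_score,
    proportion_concordance_test,
    ranked_overlap_curve,
)


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline invocation."""

    command: str
    config: dict
    seed: Optional[int]
    inputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256
    outputs: List[str] = field(default_factory=list)
    timings: Dict[str, float] = field(default_factory=dict)
    version: str = ""

    def add_input(self, path: PathLike) -> None:
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.inputs[str(p)] = h

    def write(self, path: PathLike) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)


class _Timer:
    def __init__(self, manifest: Optional[RunManifest], stage: str):
        self.manifest = manifest
        self.stage = stage

    def __enter__(self):
        self.t0 = time.perf_counter()
        return self

    def __exit__(self, *exc):
        if self.manifest is not None:
            self.manifest.timings[self.stage] = round(time.perf_counter() - self.t0, 4)
        return False


def run_correspondence(
    human_de: pd.DataFrame,
    mouse_de: pd.DataFrame,
    omap: OrthologMap,
    cfg: Optional[AnalysisConfig] = None,
    model_name: str = "model",
    gene_ranking: Optional[Sequence[str]] = None,
    gsea_set: Optional[Sequence[str]] = None,
    manifest: Optional[RunManifest] = None,
) -> Dict[str, object]:
    """Run the correspondence statistics battery for one mouse model.

    Returns a dict with the global correlation, strict-set concordance
    summaries (up and down), overlap curves, the 3x3 contingency analysis
    with adjusted residuals, detection-rate areas, and (if a gene-level
    ranking and set are supplied) the enrichment-score result.
    """
    cfg = cfg or AnalysisConfig()
    out: Dict[str, object] = {"model": model_name, "seed": cfg.seed}

    with _Timer(manifest, f"{model_name}:pairing"):
        pairs = build_pair_table(human_de, mouse_de, omap)
        out["correlation"] = fold_change_correlation(pairs)
        out["core_set"] = mahalanobis_core(pairs)
        out["pair_table"] = pairs

    with _Timer(manifest, f"{model_name}:concordance"):
        strict = classify_de(human_de, "human_strict", cfg)
        for direction in ("up", "down"):
            selected = strict.index[strict == direction]
            out[f"concordance_{direction}"] = proportion_concordance_test(
                selected, omap, mouse_de, cfg, set_label=f"human_{direction}", direction=direction
            )

    with _Timer(manifest, f"{model_name}:overlap"):
        max_rank = min(
            cfg.rank_max,
            omap.pairs["mouse_transcript"].nunique(),
            omap.pairs["human_transcript"].nunique(),
        )
        local_cfg = dataclasses.replace(cfg, rank_max=max_rank)
        grid = np.unique(np.linspace(10, max_rank, 100).astype(int))
        for direction in ("up", "down"):
            out[f"overlap_{direction}"] = ranked_overlap_curve(
                human_de, mouse_de, omap, direction, local_cfg, grid=grid
            )

    with _Timer(manifest, f"{model_name}:contingency"):
        mouse_labels = classify_de(mouse_de, "mouse", cfg)
        cont = classify_pairs(strict, mouse_labels, omap)
        out["contingency"] = cont
        resid, flags = adjusted_residuals(cont, cfg.residual_cutoff)
        out["residuals"] = resid
        out["residual_flags"] = flags

    with _Timer(manifest, f"{model_name}:detection"):
        for direction in ("up", "down"):
            try:
                out[f"detection_{direction}"] = detection_rate_curves(
                    human_de, mouse_de, omap, direction, cfg
                )
            except ValueError:
                out[f"detection_{direction}"] = None

    if gene_ranking is not None and gsea_set is not None:
        with _Timer(manifest, f"{model_name}:gsea"):
            res = gsea_running_score(gene_ranking, gsea_set)
            out["gsea"] = gsea_null(res, cfg.n_perm, seed=cfg.seed)
    return out


def cross_species_gsea(
    human_gene_de: pd.DataFrame,
    mouse_gene_de: pd.DataFrame,
    omap: OrthologMap,
    direction: str = "up",
    n_top: int = 200,
    n_perm: int = 1000,
    seed: Optional[int] = None,
):
    """Enrichment score of mouse-derived gene sets along the human ranking.

    Both DE tables must be gene-level (indices are gene symbols, e.g. after
    max-collapse of transcripts).  The human genes with a mouse ortholog
    are ranked by fold change (descending for ``up``); the set S contains
    the human genes orthologous to the *n_top* mouse genes most strongly
    altered in that direction.  Returns the ES with its permutation null.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    ascending = direction == "down"
    gene_pairs = omap.pairs[["human_gene", "mouse_gene"]].drop_duplicates()

    human_mapped = human_gene_de.index.intersection(gene_pairs["human_gene"].unique())
    ranking = (
        human_gene_de.loc[human_mapped, "log2fc"]
        .sort_values(ascending=ascending, kind="stable")
        .index.tolist()
    )
    mouse_mapped = mouse_gene_de.index.intersection(gene_pairs["mouse_gene"].unique())
    top_mouse = (
        mouse_gene_de.loc[mouse_mapped, "log2fc"]
        .sort_values(ascending=ascending, kind="stable")
        .index[:n_top]
    )
    S = set(
        gene_pairs.loc[gene_pairs["mouse_gene"].isin(top_mouse), "human_gene"]
    ) & set(ranking)
    if not S:
        raise ValueError("mouse top set maps to no ranked human genes")
    res = gsea_running_score(ranking, S)
    return gsea_null(res, n_perm=n_perm, seed=seed)


def build_report(per_model: Mapping[str, Mapping[str, object]]) -> Dict[str, pd.DataFrame]:
    """Aggregate per-model results into cross-model comparison tables."""
    if not per_model:
        raise ValueError("need at least one model result set")
    sizes = {
        name: res["correlation"].n_pairs for name, res in per_model.items() if "correlation" in res
    }
    if len(set(sizes.values())) > 1:
        raise ValueError(f"mixed pair universes across models: {sizes}")

    corr_rows = []
    conc_rows = []
    gsea_rows = []
    for name, res in per_model.items():
        c = res["correlation"]
        corr_rows.append(
            {"model": name, "r": c.r, "slope": c.slope, "intercept": c.intercept, "n_pairs": c.n_pairs}
        )
        for direction in ("up", "down"):
            s = res.get(f"concordance_{direction}")
            if s is not None:
                row = {"model": name, **s.to_dict()}
                ov = res.get(f"overlap_{direction}")
                if ov is not None:
                    row["overlap_exceedance"] = ov.exceedance_fraction()
                det = res.get(f"detection_{direction}")
                if det is not None:
                    row["detection_area"] = det.area
                conc_rows.append(row)
        g = res.get("gsea")
        if g is not None:
            gsea_rows.append(
                {"model": name, "es": g.es, "p": g.p, "band": g.band, "set_size": g.set_size}
            )

    report: Dict[str, pd.DataFrame] = {
        "correlation": pd.DataFrame(corr_rows).set_index("model").sort_values("r", ascending=False),
        "concordance": pd.DataFrame(conc_rows),
    }
    if gsea_rows:
        report["gsea"] = pd.DataFrame(gsea_rows).set_index("model")

    resid_rows = []
    for name, res in per_model.items():
        resid = res.get("residuals")
        if resid is not None:
            resid_rows.append(
                {
                    "model": name,
                    "resid_up_up": resid.loc["up", "up"],
                    "resid_down_down": resid.loc["down", "down"],
                    "resid_up_down": resid.loc["up", "down"],
                    "resid_down_up": resid.loc["down", "up"],
                }
            )
    if resid_rows:
        report["residuals"] = pd.DataFrame(resid_rows).set_index("model")

    profiles = {
        name: res["inflammation"] for name, res in per_model.items() if "inflammation" in res
    }
    if profiles:
        ratio = pd.DataFrame({name: prof["ratio"] for name, prof in profiles.items()})
        sig = pd.DataFrame({name: prof["significant"] for name, prof in profiles.items()})
        report["inflammation_ratio"] = ratio
        report["inflammation_significant"] = sig
        report["inflammation_intensity"] = (
            sig.sum(axis=0).rename("n_significant_populations").to_frame()
        )
    return report


def write_report(report: Mapping[str, pd.DataFrame], outdir: PathLike) -> List[str]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in report.items():
        path = outdir / f"report_{name}.tsv"
        df.to_csv(path, sep="\t")
        written.append(str(path))
    return written
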