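"""Analysis configuration: the thresholds that define every selection rule.

All thresholds used downstream live here so a run can be described by one
object, serialized into every output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional


@dataclass
class AnalysisConfig:
    """Thresholds and sizes shared by the correspondence pipeline.

    Attributes
    ----------
    human_fdr:
        BH-adjusted p cutoff for calling a human transcript differentially
        expressed (both broad and strict human selections use it).
    human_lfc_broad:
        |log2 fold change| cutoff for the broad human DE selection
        (term-level analyses and model clustering).
    human_lfc_strict:
        |log2 fold change| cutoff for the strict human DE selection
        (concordance proportion tests, contingency analysis).
    mouse_alpha:
        Comparison-wise p cutoff for calling a mouse transcript DE.
    background_p:
        Mouse p-value above which a transcript counts as "unchanged" and is
        eligible for the detection-rate background set.
    foreground_size:
        Size of the detection-rate foreground (top mouse transcripts).
    rank_max:
        Largest rank N for ranked-list overlap curves.
    top_k_trademark:
        Number of trademark genes reported per direction.
    band_level:
        Coverage level of null bands (equal-tail construction).
    residual_cutoff:
        |adjusted residual| above which a contingency cell is flagged.
    min_term_size_main / min_term_size_supp:
        Minimum DE members for a term to be reported (main-figure vs
        supplementary-figure stringency).
    n_perm:
        Permutations for the enrichment-score null.
    n_sim_consensus:
        Monte-Carlo draws for the consensus-gene test.
    seed:
        Seed recorded in (and driving) every randomized output.
    """

    human_fdr: float = 0.05
    human_lfc_broad: float = 0.50
    human_lfc_strict: float = 1.00
    mouse_alpha: float = 0.05
    background_p: float = 0.20
    foreground_size: int = 200
    rank_max: int = 5000
    top_k_trademark: int = 50
    band_level: float = 0.95
    residual_cutoff: float = 3.0
    min_term_size_main: int = 10
    min_term_size_supp: int = 3
    n_perm: int = 1000
    n_sim_consensus: int = 10000
    linkage: str = "average"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("human_fdr", "mouse_alpha", "background_p", "band_level"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1); got {v}")
        for name in ("human_lfc_broad", "human_lfc_strict", "residual_cutoff"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in (
            "foreground_size",
            "rank_max",
            "top_k_trademark",
            "min_term_size_main",
            "min_term_size_supp",
            "n_perm",
            "n_sim_consensus",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.linkage not in ("average", "complete"):
            raise ValueError("linkage must be 'average' or 'complete'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
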