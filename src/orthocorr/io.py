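"""Domain containers and plain-text readers/writers.

File dialects
-------------
Expression matrix
    UTF-8 tab-delimited; first column header ``transcript_id``, remaining
    headers are sample ids; one row per transcript.  A separate two-column
    design file maps every sample id to ``case`` or ``control``.
Ortholog map
    CSV with header ``human_transcript,human_gene,mouse_transcript,mouse_gene``.
Gene sets
    Standard GMT: ``set_id <TAB> description <TAB> member ...``.

Values are assumed already normalized and on the log2 scale; no
normalization is performed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_VALID_GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix (transcripts x samples) with a case/control design.

    Parameters
    ----------
    species:
        Free-form species tag, conventionally ``"human"`` or ``"mouse"``.
    values:
        DataFrame indexed by unique transcript ids, columns are sample ids,
        entries are finite log2 expression values.
    design:
        Series mapping each sample id to ``"case"`` or ``"control"``.
    gene_symbols:
        Optional Series mapping transcript id -> gene symbol.  Transcripts
        without a symbol (NaN/empty) are kept for transcript-level analyses
        and dropped only by gene-level collapse.
    """

    species: str
    values: pd.DataFrame
    design: pd.Series
    gene_symbols: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        idx = self.values.index
        if len(idx) == 0:
            raise ValueError("expression matrix has no transcripts")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate transcript ids: {dups[:10]}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite (log2 scale)")
        self.design = self.design.reindex(self.values.columns)
        if self.design.isna().any():
            missing = self.design.index[self.design.isna()].tolist()
            raise ValueError(f"samples absent from design: {missing}")
        bad = set(self.design.unique()) - set(_VALID_GROUPS)
        if bad:
            raise ValueError(f"design labels must be case/control; got {sorted(bad)}")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one case and one control sample")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(idx)

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def case_samples(self) -> List[str]:
        return list(self.design.index[self.design == "case"])

    @property
    def control_samples(self) -> List[str]:
        return list(self.design.index[self.design == "control"])

    @property
    def n_case(self) -> int:
        return int((self.design == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.design == "control").sum())

    @property
    def shape(self) -> tuple:
        return self.values.shape


@dataclass
class OrthologMap:
    """Many-to-many transcript pairing between a human and a mouse platform.

    ``pairs`` has columns ``human_transcript, human_gene, mouse_transcript,
    mouse_gene``; rows are unique (human_transcript, mouse_transcript)
    combinations.  One human transcript may pair with several mouse
    transcripts and vice versa.
    """

    pairs: pd.DataFrame

    REQUIRED = ("human_transcript", "human_gene", "mouse_transcript", "mouse_gene")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.pairs.columns]
        if missing:
            raise ValueError(f"ortholog map missing columns: {missing}")
        if len(self.pairs) == 0:
            raise ValueError("ortholog map is empty")
        self.pairs = (
            self.pairs.loc[:, list(self.REQUIRED)]
            .astype(str)
            .drop_duplicates(subset=["human_transcript", "mouse_transcript"])
            .reset_index(drop=True)
        )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_human_mapped(self) -> int:
        return self.pairs["human_transcript"].nunique()

    @property
    def n_mouse_mapped(self) -> int:
        return self.pairs["mouse_transcript"].nunique()

    @property
    def human_gene(self) -> pd.Series:
        return self.pairs.drop_duplicates("human_transcript").set_index(
            "human_transcript"
        )["human_gene"]

    @property
    def mouse_gene(self) -> pd.Series:
        return self.pairs.drop_duplicates("mouse_transcript").set_index(
            "mouse_transcript"
        )["mouse_gene"]

    def mouse_orthologs(self, human_transcripts: Iterable[str]) -> pd.Index:
        """Unique mouse transcripts paired with any of the given human transcripts."""
        wanted = set(map(str, human_transcripts))
        sub = self.pairs[self.pairs["human_transcript"].isin(wanted)]
        return pd.Index(sub["mouse_transcript"].unique())

    def human_orthologs(self, mouse_transcripts: Iterable[str]) -> pd.Index:
        wanted = set(map(str, mouse_transcripts))
        sub = self.pairs[self.pairs["mouse_transcript"].isin(wanted)]
        return pd.Index(sub["human_transcript"].unique())

    def fanout_histogram(self) -> Dict[str, Dict[int, int]]:
        """Counts of partners per transcript, per side."""
        h = self.pairs.groupby("human_transcript").size().value_counts().to_dict()
        m = self.pairs.groupby("mouse_transcript").size().value_counts().to_dict()
        return {
            "human": {int(k): int(v) for k, v in h.items()},
            "mouse": {int(k): int(v) for k, v in m.items()},
        }

    def summary(self) -> Dict[str, int]:
        return {
            "n_pairs": self.n_pairs,
            "n_human_mapped": self.n_human_mapped,
            "n_mouse_mapped": self.n_mouse_mapped,
        }


@dataclass
class GeneSet:
    """One named set of transcript or gene identifiers."""

    set_id: str
    name: str
    members: List[str]
    namespace: str = "transcript"  # or "gene"
    source: str = ""

    def __post_init__(self) -> None:
        seen: Dict[str, None] = {}
        n_before = len(self.members)
        for m in self.members:
            seen.setdefault(str(m), None)
        self.members = list(seen)
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.set_id!r} has no members")
        if len(self.members) < n_before:
            logger.warning(
                "gene set %s: %d duplicate members removed",
                self.set_id,
                n_before - len(self.members),
            )
        if self.namespace not in ("transcript", "gene"):
            raise ValueError("namespace must be 'transcript' or 'gene'")


@dataclass
class GeneSetCollection:
    """An ordered mapping set_id -> :class:`GeneSet`."""

    sets: Dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.sets

    def add(self, gs: GeneSet) -> None:
        self.sets[gs.set_id] = gs

    def ids(self) -> List[str]:
        return list(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression_matrix(
    path: PathLike,
    design_path: PathLike,
    species: str = "",
    gene_symbols: Optional[Mapping[str, str]] = None,
) -> ExpressionMatrix:
    """Read a tab-delimited log2 expression matrix plus its design file.

    The first column of *path* must be ``transcript_id``; the header row
    lists sample ids.  *design_path* is two-column tab-delimited
    (``sample_id`` then ``case``/``control``), with or without a header.
    Errors name the offending transcript id, sample, or cell.
    """
    raw = pd.read_csv(path, sep="\t", dtype={0: str})
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: expected transcript_id column plus >=1 sample")
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "transcript_id"
    if raw.index.has_duplicates:
        dups = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate transcript ids: {dups[:10]}")
    try:
        values = raw.astype(float)
    except (TypeError, ValueError):
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                row = raw.index[bad][0]
                raise ValueError(
                    f"{path}: non-numeric value at transcript {row!r}, sample {col!r}"
                ) from None
        raise

    design_df = pd.read_csv(design_path, sep="\t", header=None, dtype=str)
    if design_df.shape[1] < 2:
        raise ValueError(f"{design_path}: expected two columns (sample, group)")
    # tolerate a header line
    if str(design_df.iloc[0, 1]).lower() not in _VALID_GROUPS:
        design_df = design_df.iloc[1:]
    design = pd.Series(
        design_df.iloc[:, 1].str.lower().to_numpy(),
        index=design_df.iloc[:, 0].to_numpy(),
    )
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise ValueError(f"{path}: samples absent from design file: {missing}")

    symbols = None
    if gene_symbols is not None:
        symbols = pd.Series(dict(gene_symbols)).reindex(values.index)
    return ExpressionMatrix(
        species=species, values=values, design=design[values.columns], gene_symbols=symbols
    )


def write_expression_matrix(
    m: ExpressionMatrix, path: PathLike, design_path: Optional[PathLike] = None
) -> None:
    out = m.values.copy()
    out.index.name = "transcript_id"
    out.to_csv(path, sep="\t")
    if design_path is not None:
        m.design.to_csv(design_path, sep="\t", header=False)


def read_ortholog_map(path: PathLike) -> OrthologMap:
    """Read a human<->mouse transcript pair CSV; de-duplicates and reports counts."""
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise ValueError(f"{path}: ortholog map file is empty")
    missing = [c for c in OrthologMap.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: ortholog map missing columns: {missing}")
    omap = OrthologMap(pairs=df)
    logger.info(
        "ortholog map %s: %d pairs, %d human mapped, %d mouse mapped",
        path,
        omap.n_pairs,
        omap.n_human_mapped,
        omap.n_mouse_mapped,
    )
    return omap


def write_ortholog_map(omap: OrthologMap, path: PathLike) -> None:
    omap.pairs.to_csv(path, index=False)


def ortholog_coverage(omap: OrthologMap, universe_size: int) -> float:
    """Percentage of the human transcript universe with >=1 mouse ortholog.

    Returned at one-decimal precision; round to the nearest integer for
    headline reporting (33,322 of 54,675 -> 60.9, i.e. ~61%).
    """
    if universe_size == 0:
        raise ValueError("universe_size must be positive")
    if universe_size < omap.n_human_mapped:
        raise ValueError(
            f"universe_size {universe_size} smaller than mapped count {omap.n_human_mapped}"
        )
    return round(100.0 * omap.n_human_mapped / universe_size, 1)


def read_gmt(path: PathLike, namespace: str = "transcript") -> GeneSetCollection:
    """Read a standard GMT file (set_id TAB description TAB members...)."""
    coll = GeneSetCollection()
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            set_id, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            coll.add(
                GeneSet(
                    set_id=set_id,
                    name=desc,
                    members=members,
                    namespace=namespace,
                    source=str(path),
                )
            )
    return coll


def write_gmt(coll: GeneSetCollection, path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in coll:
            fh.write("\t".join([gs.set_id, gs.name, *gs.members]) + "\n")
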