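"""Multi-source miRNA target-prediction consensus.

Individual target-prediction databases disagree widely; requiring a
predicted miRNA->gene interaction to appear in at least ``min_support``
independent sources is a simple, effective precision filter.  Retained
edges carry an integrated confidence score (mean of the per-source
scores by default) and are split into empirical confidence tertiles so
that downstream analysis can drop the bottom third.

Identifier conventions: gene symbols are matched uppercase, miRNA names
case-insensitively with any leading ``hsa-`` prefix ignored.  No alias
or orthology resolution is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

TARGET_COLUMNS = ["source", "mirna", "gene", "score"]
BANDS = ("bottom", "middle", "top")


def canonical_mirna(name: str) -> str:
    """Case-insensitive miRNA name with the species prefix dropped."""
    n = str(name).strip().lower()
    if n.startswith("hsa-"):
        n = n[4:]
    return n


def canonical_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class ConsensusTargetSet:
    """Consensus miRNA->gene edges surviving the support filter.

    ``edges`` columns: mirna, gene, support, integrated_score and,
    after banding, confidence_band.
    """

    edges: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.edges["gene"].unique())

    @property
    def mirnas(self) -> set[str]:
        return set(self.edges["mirna"].unique())

    def targets_of(self, mirna: str) -> set[str]:
        m = canonical_mirna(mirna)
        return set(self.edges.loc[self.edges["mirna"] == m, "gene"])


def load_targets(path: str | Path) -> pd.DataFrame:
    """Load and validate a target-prediction TSV.

    Columns: ``source, mirna, gene, score`` with score in [0, 1].
    Duplicate (source, mirna, gene) rows keep the maximum score (logged).
    Identifiers are canonicalized on load.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"target table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TARGET_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"target TSV missing columns {missing}")
    if df.empty:
        warnings.warn(f"target table {path} is empty", stacklevel=2)
        return df[TARGET_COLUMNS]
    df = df[TARGET_COLUMNS].copy()
    df["score"] = pd.to_numeric(df["score"], errors="coerce")
    bad = df["score"].isna() | (df["score"] < 0) | (df["score"] > 1)
    if bad.any():
        raise ValidationError(
            f"{int(bad.sum())} target rows have scores outside [0, 1] "
            f"(first offending row index {int(np.nonzero(bad.to_numpy())[0][0])})")
    df["mirna"] = df["mirna"].map(canonical_mirna)
    df["gene"] = df["gene"].map(canonical_gene)
    n_before = len(df)
    df = (df.groupby(["source", "mirna", "gene"], as_index=False)["score"].max())
    if len(df) < n_before:
        logger.info("deduplicated %d target rows (kept max score)", n_before - len(df))
    return df


def consensus_filter(
    records: pd.DataFrame,
    mirnas,
    min_support: int = 5,
    score_mode: str = "mean",
) -> ConsensusTargetSet:
    """Keep edges of the selected miRNAs supported by >= ``min_support``
    distinct sources.

    ``integrated_score`` is the arithmetic mean of the per-source scores
    (``score_mode="max"`` keeps the maximum instead).
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    if score_mode not in ("mean", "max"):
        raise ValidationError(f"unknown score_mode '{score_mode}'")
    selected = {canonical_mirna(m) for m in mirnas}
    params = {"min_support": min_support, "score_mode": score_mode,
              "n_selected_mirnas": len(selected)}
    empty = pd.DataFrame(columns=["mirna", "gene", "support", "integrated_score"])
    if records.empty:
        warnings.warn("no target records supplied", stacklevel=2)
        return ConsensusTargetSet(edges=empty, params=params)
    n_sources = records["source"].nunique()
    if min_support > n_sources:
        warnings.warn(
            f"min_support={min_support} exceeds the {n_sources} sources present; "
            "result is empty", stacklevel=2)
        return ConsensusTargetSet(edges=empty, params=params)
    sub = records[records["mirna"].isin(selected)]
    agg = (sub.groupby(["mirna", "gene"], as_index=False)
              .agg(support=("source", "nunique"), integrated_score=("score", score_mode)))
    kept = agg[agg["support"] >= min_support].reset_index(drop=True)
    kept = kept.sort_values(["mirna", "gene"], kind="mergesort").reset_index(drop=True)
    logger.info("consensus filter: %d/%d edges kept at min_support=%d (%d genes)",
                len(kept), len(agg), min_support, kept["gene"].nunique())
    return ConsensusTargetSet(edges=kept, params=params)


def confidence_bands(cts: ConsensusTargetSet) -> ConsensusTargetSet:
    """Assign empirical confidence tertiles over the retained edges.

    Edges with integrated score strictly below the 1/3 quantile are
    "bottom"; below the 2/3 quantile, "middle"; the rest "top" — ties at
    a boundary stay in the upper band.  Identical scores collapse to a
    single "top" band with a warning.
    """
    if cts.edges.empty:
        raise ValidationError("cannot band an empty consensus set")
    edges = cts.edges.copy()
    scores = edges["integrated_score"].to_numpy(dtype=float)
    q1, q2 = np.quantile(scores, [1 / 3, 2 / 3])
    if np.all(scores == scores[0]):
        warnings.warn("all integrated scores identical; single 'top' band", stacklevel=2)
        edges["confidence_band"] = "top"
    else:
        band = np.where(scores < q1, "bottom", np.where(scores < q2, "middle", "top"))
        edges["confidence_band"] = band
    params = dict(cts.params, band_quantiles=(float(q1), float(q2)))
    return ConsensusTargetSet(edges=edges, params=params)


def keep_top_two_thirds(cts: ConsensusTargetSet) -> ConsensusTargetSet:
    """Drop the bottom confidence tertile; the gene universe is
    recomputed from the surviving edges."""
    if "confidence_band" not in cts.edges.columns:
        cts = confidence_bands(cts)
    kept = cts.edges[cts.edges["confidence_band"] != "bottom"].reset_index(drop=True)
    logger.info("top-two-thirds filter: %d edges, %d genes",
                len(kept), kept["gene"].nunique())
    return ConsensusTargetSet(edges=kept, params=dict(cts.params, band_rule="top_two_thirds"))


def write_consensus(cts: ConsensusTargetSet, edges_path: str | Path,
                    genes_path: str | Path | None = None) -> None:
    """Write the consensus edge TSV and, optionally, the gene list."""
    cts.edges.to_csv(edges_path, sep="\t", index=False)
    if genes_path is not None:
        Path(genes_path).write_text("\n".join(sorted(cts.genes)) + "\n")
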