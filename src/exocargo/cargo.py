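"""Selection of the dominant exosomal miRNA cargo set.

Vesicle miRNA content is typically dominated by a small number of
species: a handful of probes carry most of the reads while a long tail
contributes fractions of a percent each.  This module ranks a merged,
normalized profile and cuts it into a "cargo" prefix and an excluded
tail by one of two rules:

* share floor — keep every miRNA whose share of total signal exceeds a
  floor (default 0.007, i.e. the tail tops out below 0.7%);
* cumulative fraction — keep the minimal prefix whose cumulative share
  reaches a target fraction (default 0.79).

The selection is summarized by its coverage (summed share of the
selected set) and its dominance ratio (mean selected abundance over
mean excluded abundance).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CargoSelection:
    """A ranked profile plus a prefix selection and its statistics."""

    ranked: pd.DataFrame          # mirna, value, share, cumulative (desc by value)
    selected: list[str]           # prefix of ranked mirna ids
    rule: dict = field(default_factory=dict)
    dominance_ratio: float = math.nan
    dominance_infinite: bool = False
    coverage: float = math.nan

    @property
    def excluded(self) -> list[str]:
        k = len(self.selected)
        return list(self.ranked["mirna"].iloc[k:])


def rank_mirnas(profile: pd.Series) -> pd.DataFrame:
    """Rank a merged normalized profile from highest to lowest value.

    Ties are broken lexicographically by miRNA id so the ordering is
    reproducible regardless of input row order.  Returns a DataFrame
    with columns ``mirna, value, share, cumulative``.
    """
    values = profile.astype(float)
    if values.size == 0 or (values <= 0).all():
        raise ValidationError("cannot rank an all-zero profile")
    if (values < 0).any():
        raise ValidationError("negative values in profile")
    df = pd.DataFrame({"mirna": values.index.astype(str), "value": values.to_numpy()})
    df = df.sort_values(["value", "mirna"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    total = df["value"].sum()
    df["share"] = df["value"] / total
    df["cumulative"] = df["share"].cumsum()
    return df


def _prefix_selection(ranked: pd.DataFrame, k: int, rule: dict) -> CargoSelection:
    selected = list(ranked["mirna"].iloc[:k])
    coverage = float(ranked["share"].iloc[:k].sum())
    sel = CargoSelection(ranked=ranked, selected=selected, rule=rule, coverage=coverage)
    if 0 < k < len(ranked):
        ratio, infinite = dominance_ratio(ranked, selected)
        sel.dominance_ratio = ratio
        sel.dominance_infinite = infinite
    logger.info("cargo selection %s: %d of %d miRNAs, coverage %.4f",
                rule, k, len(ranked), coverage)
    return sel


def select_by_share_floor(ranked: pd.DataFrame, floor: float = 0.007) -> CargoSelection:
    """Select every miRNA whose share strictly exceeds ``floor``.

    Because shares are non-increasing down the ranking, the result is a
    prefix.  An empty selection raises, suggesting a lower floor.
    """
    if not 0 < floor < 1:
        raise ValidationError(f"share floor must be in (0, 1), got {floor}")
    k = int((ranked["share"] > floor).sum())
    if k == 0:
        raise ValidationError(
            f"no miRNA has share > {floor} (max share "
            f"{ranked['share'].max():.4g}); try a lower floor")
    return _prefix_selection(ranked, k, {"rule": "share_floor", "floor": floor})


def select_by_cumulative_fraction(ranked: pd.DataFrame, f: float = 0.79) -> CargoSelection:
    """Select the minimal prefix whose cumulative share reaches ``f``."""
    if not 0 < f <= 1:
        raise ValidationError(f"cumulative fraction must be in (0, 1], got {f}")
    cum = ranked["cumulative"].to_numpy()
    # tolerate float round-off at f == 1
    hits = np.nonzero(cum >= f - 1e-12)[0]
    k = int(hits[0]) + 1 if hits.size else len(ranked)
    return _prefix_selection(ranked, k, {"rule": "cumulative_fraction", "f": f})


def dominance_ratio(ranked: pd.DataFrame, selected) -> tuple[float, bool]:
    """Mean selected value over mean excluded value.

    Returns ``(ratio, infinite_flag)``; an all-zero excluded tail yields
    ``(inf, True)``.
    """
    sel = set(selected)
    in_sel = ranked["mirna"].isin(sel)
    if not in_sel.any() or in_sel.all():
        raise ValidationError("dominance ratio needs non-empty selected and excluded sets")
    mean_sel = float(ranked.loc[in_sel, "value"].mean())
    mean_rest = float(ranked.loc[~in_sel, "value"].mean())
    if mean_rest == 0:
        return math.inf, True
    return mean_sel / mean_rest, False


def selection_report(sel: CargoSelection) -> dict:
    """JSON-serializable summary of a cargo selection."""
    return {
        "rule": sel.rule,
        "n_ranked": int(len(sel.ranked)),
        "n_selected": int(len(sel.selected)),
        "n_excluded": int(len(sel.ranked) - len(sel.selected)),
        "coverage": sel.coverage,
        "dominance_ratio": None if sel.dominance_infinite else sel.dominance_ratio,
        "dominance_infinite": sel.dominance_infinite,
        "selected": list(sel.selected),
    }


def ranked_table(sel: CargoSelection) -> pd.DataFrame:
    """Ranked table with a per-row selected flag (TSV export view)."""
    df = sel.ranked.copy()
    df["selected"] = df["mirna"].isin(set(sel.selected))
    return df
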