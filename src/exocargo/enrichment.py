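"""Over-representation analysis with a fold-enrichment filter.

A query gene set (here, the consensus targets of the dominant cargo
miRNAs) is tested against flat gene-set annotations (GMT) with the
one-sided hypergeometric test; Benjamini-Hochberg q-values are reported
alongside the raw p-values.  On top of the usual p cutoff sits a
data-driven fold filter: a term is called significant only if its fold
enrichment exceeds the mean plus ``sd_mult`` standard deviations of the
fold distribution over all terms with non-zero overlap, AND its raw p
is below ``p_max`` (default 1e-6).  Terms that miss significance but
fall in a near-miss p window can be reported as "trends".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError
from .targets import canonical_gene


@dataclass
class AnnotationSet:
    """Flat gene-set annotations: term id -> (name, member genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.universe:
            members: set[str] = set()
            for _, genes in self.terms.values():
                members |= genes
            self.universe = frozenset(members)
        for tid, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValidationError(f"term {tid} has genes outside the universe")

    def genes_of(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file (``term_id<TAB>term_name<TAB>gene...``)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GMT file not found: {path}")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs id, name and >=1 gene")
        tid, name, *genes = fields
        if tid in terms:
            raise ValidationError(f"duplicate term id '{tid}' in {path}")
        terms[tid] = (name, frozenset(canonical_gene(g) for g in genes if g.strip()))
    return AnnotationSet(terms=terms)


def write_gmt(annotations: AnnotationSet, path: str | Path) -> None:
    lines = [
        "\t".join([tid, name, *sorted(genes)])
        for tid, (name, genes) in annotations.terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EnrichmentResult:
    """Per-term ORA table plus filter summary statistics.

    ``table`` columns: term_id, term_name, k, n, K, N, fold, p, q and,
    after :func:`bespoke_filter`, passes_fold / passes_p / significant.
    ``summary`` holds fold_mean, fold_sd, fold_threshold once the
    filter has run.
    """

    table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N`` genes in the background, ``K`` of them in the term, ``n``
    drawn in the query, ``k`` observed in the overlap.  Equivalent to a
    one-sided Fisher exact test on the 2x2 table.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"inconsistent margins: n={n}, K={K}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValidationError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k < max(0, n + K - N):
        raise ValidationError(f"overlap k={k} below the margin floor {n + K - N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query,
    annotations: AnnotationSet,
    background=None,
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` against every
    term, on a common background.

    The background defaults to the annotation universe; a user-supplied
    background is intersected with the universe first.  Terms with no
    background genes are skipped.  Fold enrichment is (k/n)/(K/N).
    """
    query_canon = {canonical_gene(g) for g in query}
    if background is None:
        bg = set(annotations.universe)
    else:
        bg = {canonical_gene(g) for g in background} & set(annotations.universe)
    N = len(bg)
    eff_query = query_canon & bg
    n = len(eff_query)
    if n == 0:
        unmatched = sorted(query_canon)[:20]
        raise ValidationError(
            "no query gene matches the background/universe; unmatched symbols "
            f"include {unmatched}")
    rows = []
    for tid, (name, genes) in annotations.terms.items():
        term_bg = genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        k = len(eff_query & term_bg)
        fold = (k / n) / (K / N)
        rows.append({
            "term_id": tid, "term_name": name,
            "k": k, "n": n, "K": K, "N": N,
            "fold": fold, "p": hypergeom_pvalue(k, n, K, N),
        })
    table = pd.DataFrame(rows)
    if not table.empty:
        table["q"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    else:
        table = pd.DataFrame(columns=["term_id", "term_name", "k", "n", "K", "N",
                                      "fold", "p", "q"])
    return EnrichmentResult(table=table)


def bespoke_filter(
    res: EnrichmentResult,
    p_max: float = 1e-6,
    sd_mult: float = 1.0,
) -> EnrichmentResult:
    """Flag terms exceeding both the data-driven fold threshold and the
    p cutoff.

    The threshold is ``mean + sd_mult * sd`` (sample sd) of fold over
    terms with k >= 1 — zero-overlap terms are never candidates and
    would only drag the mean down.  ``passes_fold`` is strict (>).
    """
    eligible = res.table[res.table["k"] >= 1]
    if len(eligible) < 2:
        raise ValidationError(
            f"fold filter needs >= 2 terms with non-zero overlap, got {len(eligible)}")
    folds = eligible["fold"].to_numpy(dtype=float)
    fold_mean = float(np.mean(folds))
    fold_sd = float(np.std(folds, ddof=1))
    threshold = fold_mean + sd_mult * fold_sd
    table = res.table.copy()
    table["passes_fold"] = (table["k"] >= 1) & (table["fold"] > threshold)
    table["passes_p"] = table["p"] < p_max
    table["significant"] = table["passes_fold"] & table["passes_p"]
    summary = {
        "fold_mean": fold_mean,
        "fold_sd": fold_sd,
        "fold_threshold": threshold,
        "sd_mult": sd_mult,
        "p_max": p_max,
        "n_terms_eligible": int(len(eligible)),
        "n_significant": int(table["significant"].sum()),
    }
    return EnrichmentResult(table=table, summary=summary)


def trend_report(
    res: EnrichmentResult,
    p_lo: float = 1e-6,
    p_hi: float = 0.1,
) -> pd.DataFrame:
    """Terms that miss significance but show a p-value trend in
    [p_lo, p_hi)."""
    table = res.table
    if "significant" not in table.columns:
        warnings.warn("trend report before bespoke_filter; treating no term as "
                      "significant", stacklevel=2)
        sig = pd.Series(False, index=table.index)
    else:
        sig = table["significant"]
    mask = ~sig & (table["p"] >= p_lo) & (table["p"] < p_hi)
    out = table[mask].copy()
    out["label"] = "trend"
    return out


def significant_terms(res: EnrichmentResult) -> list[str]:
    if "significant" not in res.table.columns:
        raise ValidationError("run bespoke_filter before extracting significant terms")
    return list(res.table.loc[res.table["significant"], "term_id"])
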