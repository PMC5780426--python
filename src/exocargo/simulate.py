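"""Seed-reproducible synthetic inputs with ground truth.

The generator emulates the data regime of an exosomal miRNA profiling
experiment so every pipeline stage can be tested against a known
answer:

* counts — log-normal miRNA abundances with a heavy top tail (by
  default a minority of ~171 probes carries most of the reads),
  positive-control probes following a known titration, low-count
  Poisson negative controls, per-lane multiplicative effects, and
  overdispersed counting noise;
* target predictions — several sources that each report planted "true"
  miRNA->gene edges with high probability and high scores, plus
  low-probability low-score false edges, so consensus support
  separates true from false;
* annotations — GMT terms drawn uniformly from the gene universe,
  except planted terms whose members are drawn preferentially from the
  true targets of the selected cargo miRNAs (and, for the planted
  "pro-angiogenic" term, from the targets of one designated miRNA).

Sub-generators are seeded by spawning a single seed sequence, so
counts, target-DB and annotation outputs are each independently
reproducible for a given (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .enrichment import AnnotationSet
from .nanostring import CountMatrix

EFFECT_FRACTIONS = {"null": 0.0, "moderate": 0.5, "strong": 0.9}

#: Standard six-point positive-control titration (fM).
POS_TITRATION = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)


@dataclass
class SimConfig:
    """All knobs of the synthetic generator; defaults are calibrated to
    the target data regime (see docs/methods.md)."""

    seed: int = 0
    # counts
    n_mirnas: int = 171
    n_replicates: int = 2
    abundance_mu: float = 4.0
    abundance_sigma: float = 1.9
    lane_effect_range: tuple[float, float] = (0.8, 1.2)
    count_noise_sigma: float = 0.2
    pos_control_fm: tuple[float, ...] = POS_TITRATION
    pos_counts_per_fm: float = 60.0
    n_neg_controls: int = 6
    neg_control_mean: float = 8.0
    n_selected: int = 23
    # target DB
    n_genes: int = 2000
    n_sources: int = 6
    true_edge_density: float = 0.02
    p_true: float = 0.85
    p_false: float = 0.05
    beta_true: tuple[float, float] = (6.0, 2.0)
    beta_false: tuple[float, float] = (2.0, 4.0)
    planted_mirna_boost: float = 2.5
    # annotations
    n_terms: int = 50
    term_size_range: tuple[int, int] = (15, 40)
    planted_terms: tuple[tuple[str, str], ...] = ()

    def validate(self) -> None:
        problems = []
        if self.n_mirnas < 1:
            problems.append("n_mirnas must be >= 1")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if self.abundance_sigma < 0:
            problems.append("abundance_sigma must be >= 0")
        for name in ("p_true", "p_false", "true_edge_density"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name} must be in [0, 1]")
        for name in ("beta_true", "beta_false"):
            a, b = getattr(self, name)
            if a <= 0 or b <= 0:
                problems.append(f"{name} parameters must be > 0")
        if not 1 <= self.n_selected <= self.n_mirnas:
            problems.append("n_selected must be in [1, n_mirnas]")
        lo, hi = self.term_size_range
        if not 1 <= lo <= hi:
            problems.append("term_size_range must satisfy 1 <= lo <= hi")
        if hi > self.n_genes:
            problems.append("max term size exceeds the gene universe")
        for tid, effect in self.planted_terms:
            if effect not in EFFECT_FRACTIONS:
                problems.append(f"planted term {tid}: unknown effect '{effect}'")
        if problems:
            raise ValidationError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """What the generator planted, for scoring pipeline output."""

    true_dominant: list[str] = field(default_factory=list)
    true_abundance: dict[str, float] = field(default_factory=dict)
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    planted_mirna: str | None = None
    planted_terms: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "true_dominant": self.true_dominant,
            "true_edges": sorted(list(e) for e in self.true_edges),
            "planted_mirna": self.planted_mirna,
            "planted_terms": self.planted_terms,
        }


def _rngs(cfg: SimConfig) -> tuple[np.random.Generator, ...]:
    children = np.random.SeedSequence(cfg.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _mirna_ids(n: int) -> list[str]:
    return [f"syn-mir-{i + 1:03d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:04d}" for i in range(n)]


def simulate_counts(cfg: SimConfig) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the raw probe-by-sample count matrix.

    Endogenous expectation for probe i in lane s is
    ``abundance_i * lane_s * exp(N(0, count_noise_sigma))`` rounded
    through a Poisson draw; positive controls follow
    ``pos_counts_per_fm * fM * lane_s`` with the same noise; negative
    controls are Poisson at ``neg_control_mean * lane_s``.
    """
    cfg.validate()
    rng, _, _ = _rngs(cfg)
    mirnas = _mirna_ids(cfg.n_mirnas)
    samples = [f"rep{i + 1}" for i in range(cfg.n_replicates)]
    lane = rng.uniform(*cfg.lane_effect_range, size=len(samples))

    # Stratified (Latin-hypercube) log-normal draw: one point per
    # probability stratum, randomly permuted.  The marginal stays
    # log-normal(mu, sigma) but the realized abundance spectrum — and
    # hence the top-tail share — is stable across seeds.
    strata = (rng.permutation(cfg.n_mirnas) + rng.uniform(size=cfg.n_mirnas)) / cfg.n_mirnas
    abundance = np.exp(cfg.abundance_mu
                       + cfg.abundance_sigma * norm.ppf(strata))
    noise = np.exp(rng.normal(0.0, cfg.count_noise_sigma,
                              size=(cfg.n_mirnas, len(samples))))
    endo = rng.poisson(abundance[:, None] * lane[None, :] * noise)

    pos_ids = [f"POS_{chr(65 + i)}" for i in range(len(cfg.pos_control_fm))]
    pos_noise = np.exp(rng.normal(0.0, cfg.count_noise_sigma,
                                  size=(len(pos_ids), len(samples))))
    pos_mean = (np.asarray(cfg.pos_control_fm)[:, None] * cfg.pos_counts_per_fm
                * lane[None, :] * pos_noise)
    pos = rng.poisson(pos_mean)

    neg_ids = [f"NEG_{i + 1:02d}" for i in range(cfg.n_neg_controls)]
    neg = rng.poisson(cfg.neg_control_mean * lane[None, :],
                      size=(cfg.n_neg_controls, len(samples)))

    index = mirnas + pos_ids + neg_ids
    counts = pd.DataFrame(np.vstack([endo, pos, neg]), index=index, columns=samples)
    counts.index.name = "probe_id"
    probe_class = pd.Series(
        ["endogenous"] * cfg.n_mirnas + ["positive"] * len(pos_ids)
        + ["negative"] * len(neg_ids), index=index)
    expected = pd.Series(np.nan, index=index, dtype=float)
    expected.loc[pos_ids] = list(cfg.pos_control_fm)

    cm = CountMatrix(counts=counts, probe_class=probe_class, expected_conc=expected,
                     replicate_groups={s: "exo" for s in samples})
    order = np.argsort(-abundance, kind="stable")
    truth = GroundTruth(
        true_dominant=[mirnas[i] for i in order[:cfg.n_selected]],
        true_abundance=dict(zip(mirnas, abundance.tolist())),
    )
    return cm, truth


def simulate_target_db(
    cfg: SimConfig,
    mirnas,
    genes=None,
    planted_mirna: str | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate multi-source target predictions for the given miRNAs.

    True edges are planted per (miRNA, gene) with probability
    ``true_edge_density`` (the designated planted miRNA gets a boosted
    density, making it the broadest regulator); each source reports a
    true edge with probability ``p_true`` and a high Beta score, and a
    false pair with probability ``p_false`` and a low Beta score.
    """
    cfg.validate()
    _, rng, _ = _rngs(cfg)
    mirnas = list(mirnas)
    genes = list(genes) if genes is not None else _gene_ids(cfg.n_genes)
    if planted_mirna is None:
        planted_mirna = mirnas[0]
    if planted_mirna not in mirnas:
        raise ValidationError(f"planted miRNA '{planted_mirna}' not among the miRNAs")

    n_m, n_g = len(mirnas), len(genes)
    density = np.full(n_m, cfg.true_edge_density)
    density[mirnas.index(planted_mirna)] = min(
        1.0, cfg.true_edge_density * cfg.planted_mirna_boost)
    true_mask = rng.random((n_m, n_g)) < density[:, None]

    rows = []
    at, bt = cfg.beta_true
    af, bf = cfg.beta_false
    for s in range(cfg.n_sources):
        present = np.where(true_mask,
                           rng.random((n_m, n_g)) < cfg.p_true,
                           rng.random((n_m, n_g)) < cfg.p_false)
        scores = np.where(true_mask,
                          rng.beta(at, bt, size=(n_m, n_g)),
                          rng.beta(af, bf, size=(n_m, n_g)))
        mi, gi = np.nonzero(present)
        for i, j in zip(mi.tolist(), gi.tolist()):
            rows.append((f"src{s + 1}", mirnas[i], genes[j], round(scores[i, j], 6)))
    df = pd.DataFrame(rows, columns=["source", "mirna", "gene", "score"])
    truth = GroundTruth(
        true_edges={(mirnas[i], genes[j]) for i, j in zip(*np.nonzero(true_mask))},
        planted_mirna=planted_mirna,
    )
    return df, truth


def simulate_annotations(
    cfg: SimConfig,
    genes,
    true_edges,
    selected,
) -> tuple[AnnotationSet, GroundTruth]:
    """Simulate GMT annotations with optional planted enriched terms.

    Null terms sample genes uniformly; a planted term draws its effect
    fraction (0.5 moderate, 0.9 strong) from genes truly targeted by
    the selected miRNAs.  Planted processes emulate coordinate
    regulation: picks prefer genes hit by two or more cargo miRNAs
    (weighted by that degree), and half of them come from the
    designated planted miRNA's own targets, which makes that miRNA the
    top-ranked candidate for the planted process.
    """
    cfg.validate()
    if cfg.n_terms < 1:
        raise ValidationError("need at least one term")
    _, _, rng = _rngs(cfg)
    genes = list(genes)
    selected = list(selected)
    lo, hi = cfg.term_size_range
    if hi > len(genes):
        raise ValidationError("term size exceeds gene universe")

    selected_set = set(selected)
    pool_degree: dict[str, int] = {}
    for m, g in true_edges:
        if m in selected_set:
            pool_degree[g] = pool_degree.get(g, 0) + 1
    target_pool = sorted(pool_degree)
    planted_map = dict(cfg.planted_terms)
    planted_mirna = selected[0] if selected else None
    planted_all = sorted({g for m, g in true_edges if m == planted_mirna})
    # prefer coordinately targeted genes (>= 2 cargo miRNAs) when enough exist
    coord = [g for g in target_pool if pool_degree[g] >= 2]
    eff_pool = coord if len(coord) >= 2 * hi else target_pool
    planted_coord = [g for g in planted_all if pool_degree[g] >= 2]
    planted_pool = planted_coord if len(planted_coord) >= hi else planted_all

    terms: dict[str, tuple[str, frozenset]] = {}
    ids = [f"T{i + 1:03d}" for i in range(cfg.n_terms)]
    extra = [tid for tid in planted_map if tid not in ids]
    for offset, tid in enumerate(extra, start=1):  # displace trailing null terms
        ids[-offset] = tid
    for tid in ids:
        effect = planted_map.get(tid, "null")
        # planted processes are full-sized terms; null terms vary
        size = hi if effect != "null" else int(rng.integers(lo, hi + 1))
        frac = EFFECT_FRACTIONS[effect]
        members: set[str] = set()
        if frac > 0 and target_pool:
            n_eff = min(int(round(frac * size)), len(target_pool))
            n_from_planted = min(n_eff // 2, len(planted_pool))
            if n_from_planted > 0:
                members |= set(rng.choice(planted_pool, size=n_from_planted,
                                          replace=False))
            remaining_pool = [g for g in eff_pool if g not in members]
            n_rest = min(n_eff - len(members), len(remaining_pool))
            if n_rest > 0:
                # planted processes are coordinately targeted: sample
                # genes weighted by how many cargo miRNAs truly hit them
                w = np.array([pool_degree[g] for g in remaining_pool], dtype=float)
                members |= set(rng.choice(remaining_pool, size=n_rest,
                                          replace=False, p=w / w.sum()))
        filler = [g for g in genes if g not in members]
        n_fill = min(size - len(members), len(filler))
        if n_fill > 0:
            members |= set(rng.choice(filler, size=n_fill, replace=False))
        terms[tid] = (f"synthetic term {tid}" + (f" ({effect})" if effect != "null" else ""),
                      frozenset(members))
    annotations = AnnotationSet(terms=terms, universe=frozenset(genes))
    truth = GroundTruth(planted_terms=planted_map, planted_mirna=planted_mirna)
    return annotations, truth


def simulate_dataset(cfg: SimConfig, outdir: str | Path) -> dict:
    """Emit the three input files plus a ground-truth JSON.

    Writes ``counts.csv``, ``targets.tsv``, ``annotations.gmt`` and
    ``ground_truth.json`` under ``outdir``; returns the file paths.
    """
    from .nanostring import write_counts
    from .enrichment import write_gmt

    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, truth_counts = simulate_counts(cfg)
    db, truth_db = simulate_target_db(cfg, truth_counts.true_dominant)
    planted = cfg.planted_terms or ((f"T{cfg.n_terms:03d}", "strong"),)
    cfg_eff = SimConfig(**{**asdict(cfg), "planted_terms": tuple(planted)})
    annotations, truth_ann = simulate_annotations(
        cfg_eff, _gene_ids(cfg.n_genes), truth_db.true_edges,
        truth_counts.true_dominant)

    paths = {
        "counts": outdir / "counts.csv",
        "targets": outdir / "targets.tsv",
        "gmt": outdir / "annotations.gmt",
        "ground_truth": outdir / "ground_truth.json",
    }
    write_counts(cm, paths["counts"])
    db.to_csv(paths["targets"], sep="\t", index=False)
    write_gmt(annotations, paths["gmt"])
    truth = GroundTruth(
        true_dominant=truth_counts.true_dominant,
        true_edges=truth_db.true_edges,
        planted_mirna=truth_db.planted_mirna,
        planted_terms=dict(truth_ann.planted_terms),
    )
    paths["ground_truth"].write_text(json.dumps(truth.to_json(), indent=1))
    return {k: str(v) for k, v in paths.items()}
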