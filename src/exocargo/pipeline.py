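"""End-to-end orchestration: normalize -> select -> consensus -> enrich
-> network, from one JSON run config.

Every stage writes its artifact as a plain file (TSV/JSON/GMT/GraphML)
under the output directory, so stages can also be re-run independently.
A machine-readable ``summary.json`` records every parameter actually
used plus the headline numbers of each stage.  Stage failures surface
as :class:`~exocargo.errors.StageError` carrying the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import cargo, enrichment, nanostring, network, targets
from .errors import ExocargoError, StageError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated run configuration (see JSON schema in the README)."""

    counts: str
    targets: str
    gmt: str
    outdir: str
    replicate_groups: dict[str, str] = field(default_factory=dict)
    # normalization
    k_sd: float = 2.0
    pseudocount: float = 0.5
    top_n: int = 100
    background_mode: str = "floor"
    pos_mean_type: str = "arithmetic"
    # selection
    selection_rule: str = "share_floor"     # or "cumulative_fraction"
    selection_param: float = 0.007
    profile_group: str | None = None        # merged group to rank; default: first
    # consensus
    min_support: int = 5
    score_mode: str = "mean"
    band_rule: str = "top_two_thirds"       # or "all"
    # enrichment
    p_max: float = 1e-6
    sd_mult: float = 1.0
    background: str | None = None           # optional path to a gene list
    # network
    term_scope: list[str] = field(default_factory=list)  # default: all significant
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ExocargoError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for key in ("counts", "targets", "gmt"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise ExocargoError(f"config path '{key}' does not exist: {p}")
        if self.selection_rule not in ("share_floor", "cumulative_fraction"):
            raise ExocargoError(f"unknown selection rule '{self.selection_rule}'")
        if not 0 < self.selection_param <= 1:
            raise ExocargoError("selection_param must be in (0, 1]")
        if self.min_support < 1:
            raise ExocargoError("min_support must be >= 1")
        if self.band_rule not in ("top_two_thirds", "all"):
            raise ExocargoError(f"unknown band rule '{self.band_rule}'")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages; returns (and writes) the summary dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config": asdict(cfg), "stages": {}}

    # ---- normalize -------------------------------------------------
    try:
        cm = nanostring.read_counts(cfg.counts, replicate_groups=cfg.replicate_groups)
        params = nanostring.NormParams(
            k_sd=cfg.k_sd, pseudocount=cfg.pseudocount, top_n=cfg.top_n,
            background_mode=cfg.background_mode, pos_mean_type=cfg.pos_mean_type)
        profile = nanostring.normalize(cm, params)
        merged = nanostring.merged_profile(profile, cm)
        profile.values.to_csv(outdir / "normalized.tsv", sep="\t")
        qc = profile.qc.copy()
        qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
        summary["stages"]["normalize"] = {
            "input_checksum": _checksum(Path(cfg.counts)),
            "scale_factors_pos": profile.scale_factors_pos.to_dict(),
            "scale_factors_content": profile.scale_factors_content.to_dict(),
            "background_threshold": profile.background_threshold.to_dict(),
            "replicate_pearson_r": qc["pearson_r"].tolist(),
        }
    except ExocargoError as exc:
        raise StageError("normalize", str(exc)) from exc

    # ---- select ----------------------------------------------------
    try:
        group = cfg.profile_group or merged.columns[0]
        ranked = cargo.rank_mirnas(merged[group])
        if cfg.selection_rule == "share_floor":
            sel = cargo.select_by_share_floor(ranked, cfg.selection_param)
        else:
            sel = cargo.select_by_cumulative_fraction(ranked, cfg.selection_param)
        cargo.ranked_table(sel).to_csv(outdir / "ranked.tsv", sep="\t", index=False)
        report = cargo.selection_report(sel)
        (outdir / "selection.json").write_text(json.dumps(report, indent=1))
        summary["stages"]["select"] = report
    except ExocargoError as exc:
        raise StageError("select", str(exc)) from exc

    # ---- consensus -------------------------------------------------
    try:
        records = targets.load_targets(cfg.targets)
        cts = targets.consensus_filter(records, sel.selected,
                                       min_support=cfg.min_support,
                                       score_mode=cfg.score_mode)
        n_union = len(targets.consensus_filter(records, sel.selected,
                                               min_support=1).genes)
        if cts.edges.empty:
            raise ExocargoError("consensus filter left no edges")
        banded = targets.confidence_bands(cts)
        final = targets.keep_top_two_thirds(banded) if cfg.band_rule == "top_two_thirds" else banded
        targets.write_consensus(final, outdir / "consensus_edges.tsv",
                                outdir / "consensus_genes.txt")
        summary["stages"]["consensus"] = {
            "n_sources": int(records["source"].nunique()),
            "genes_union": n_union,
            "genes_consensus": len(cts.genes),
            "genes_banded": len(final.genes),
            "edges_banded": int(len(final.edges)),
        }
    except ExocargoError as exc:
        raise StageError("consensus", str(exc)) from exc

    # ---- enrich ----------------------------------------------------
    try:
        annotations = enrichment.read_gmt(cfg.gmt)
        background = None
        if cfg.background:
            background = [ln.strip() for ln in Path(cfg.background).read_text().splitlines()
                          if ln.strip()]
        res = enrichment.run_ora(final.genes, annotations, background=background)
        res = enrichment.bespoke_filter(res, p_max=cfg.p_max, sd_mult=cfg.sd_mult)
        res.table.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
        (outdir / "enrichment_summary.json").write_text(json.dumps(res.summary, indent=1))
        trends = enrichment.trend_report(res)
        trends.to_csv(outdir / "trends.tsv", sep="\t", index=False)
        summary["stages"]["enrich"] = dict(res.summary)
    except ExocargoError as exc:
        raise StageError("enrich", str(exc)) from exc

    # ---- network ---------------------------------------------------
    try:
        sig_terms = enrichment.significant_terms(res)
        if sig_terms:
            net = network.build_network(final, sig_terms, annotations)
            net.check_invariants()
            network.export_graph(net, "graphml", outdir / "network.graphml")
            network.export_graph(net, "sif", outdir / "network.sif")
            counts_tbl = network.per_mirna_term_counts(net)
            counts_tbl.to_csv(outdir / "mirna_term_counts.tsv", sep="\t", index=False)
            scope = cfg.term_scope or sig_terms
            ranking = network.rank_candidates(net, scope)
            ranking.to_csv(outdir / "candidate_ranking.tsv", sep="\t", index=False)
            uniq = {m: sorted(network.unique_targets(net, m))
                    for m in net.nodes_of_kind("mirna")}
            (outdir / "unique_targets.json").write_text(json.dumps(uniq, indent=1))
            summary["stages"]["network"] = {
                "n_mirna_nodes": len(net.nodes_of_kind("mirna")),
                "n_gene_nodes": len(net.nodes_of_kind("gene")),
                "n_term_nodes": len(net.nodes_of_kind("term")),
                "n_edges": net.graph.number_of_edges(),
                "candidate_ranking": ranking.to_dict(orient="records"),
            }
        else:
            summary["stages"]["network"] = {"skipped": "no significant terms"}
    except ExocargoError as exc:
        raise StageError("network", str(exc)) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    logger.info("pipeline complete; summary at %s", outdir / "summary.json")
    return summary
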