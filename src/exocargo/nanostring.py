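"""nCounter-style miRNA count normalization.

Raw hybridization counts from a digital counting platform carry two
technical components that must be removed before probes can be compared
across lanes: per-lane efficiency differences (estimated from spiked
positive-control probes at a known titration) and input-amount
differences (estimated from a large, fixed set of abundant endogenous
probes).  Spiked negative-control probes estimate the non-specific
background.  The sequence implemented here is the conventional one:

1. positive-control scaling — each sample is scaled so its geometric
   mean of positive-control counts matches the cross-sample average;
2. background thresholding — endogenous counts at or below
   ``mean + k_sd * sd`` of the sample's negative controls are floored to
   zero (or the threshold is subtracted, with clamping);
3. content normalization — a secondary scaling by the geometric mean of
   the top ``top_n`` endogenous probes (chosen once, by cross-sample
   mean abundance, so factors are comparable across samples).

Replicate agreement is reported as the Pearson correlation of
normalized endogenous profiles within each replicate group; replicates
are then merged by per-probe averaging.
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

PROBE_CLASSES = ("endogenous", "positive", "negative", "housekeeping")

#: Columns that precede the per-sample count columns in the counts CSV.
_META_COLUMNS = ["probe_id", "probe_class", "expected_conc"]


@dataclass
class CountMatrix:
    """Raw probe-by-sample counts with probe-class metadata.

    Attributes
    ----------
    counts:
        Integer DataFrame indexed by probe id, one column per sample.
    probe_class:
        Series mapping probe id to one of :data:`PROBE_CLASSES`.
    expected_conc:
        Series of spike-in concentrations (fM); NaN except for
        positive-control probes.
    replicate_groups:
        Mapping sample id -> replicate-group label.  Samples absent
        from the mapping form singleton groups named after themselves.
    """

    counts: pd.DataFrame
    probe_class: pd.Series
    expected_conc: pd.Series
    replicate_groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dupes = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValidationError(f"duplicate probe ids: {dupes}")
        unknown = set(self.probe_class) - set(PROBE_CLASSES)
        if unknown:
            raise ValidationError(f"unknown probe classes: {sorted(unknown)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValidationError("negative counts present")
        if not np.allclose(arr, np.round(arr)):
            raise ValidationError("counts must be integral")
        for cls in ("positive", "negative"):
            if not (self.probe_class == cls).any():
                raise ValidationError(f"no {cls}-control probes present")

    def probes_of_class(self, cls: str) -> pd.Index:
        return self.counts.index[self.probe_class.reindex(self.counts.index) == cls]

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def groups(self) -> dict[str, list[str]]:
        """Replicate groups as group -> ordered sample list."""
        out: dict[str, list[str]] = {}
        for s in self.samples:
            out.setdefault(self.replicate_groups.get(s, s), []).append(s)
        return out


@dataclass
class NormalizedProfile:
    """Output of the three-step normalization, per sample, plus QC."""

    values: pd.DataFrame                  # probe x sample, after all scaling
    shares: pd.DataFrame                  # endogenous probe x sample, sums to 1
    background_threshold: pd.Series       # per sample
    scale_factors_pos: pd.Series          # per sample
    scale_factors_content: pd.Series      # per sample
    qc: pd.DataFrame                      # group, sample_a, sample_b, pearson_r


def read_counts(path: str | Path, replicate_groups: dict[str, str] | None = None) -> CountMatrix:
    """Read the counts CSV dialect into a validated :class:`CountMatrix`.

    Expected header: ``probe_id,probe_class,expected_conc,<sample>...``,
    UTF-8, comma-separated; ``expected_conc`` empty except for positive
    controls.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"counts file not found: {path}")
    df = pd.read_csv(path, dtype={"probe_id": str})
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts CSV missing columns {missing}; header must start "
                          f"with {','.join(_META_COLUMNS)}")
    sample_cols = [c for c in df.columns if c not in _META_COLUMNS]
    if not sample_cols:
        raise FormatError("counts CSV has no sample columns")
    counts = df.set_index("probe_id")[sample_cols]
    try:
        counts = counts.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric count value: {exc}") from exc
    cm = CountMatrix(
        counts=counts,
        probe_class=df.set_index("probe_id")["probe_class"],
        expected_conc=pd.to_numeric(df.set_index("probe_id")["expected_conc"], errors="coerce"),
        replicate_groups=dict(replicate_groups or {}),
    )
    return cm


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write a :class:`CountMatrix` in the same CSV dialect read by
    :func:`read_counts` (round-trip safe)."""
    df = pd.DataFrame({
        "probe_id": cm.counts.index,
        "probe_class": cm.probe_class.reindex(cm.counts.index).to_numpy(),
        "expected_conc": cm.expected_conc.reindex(cm.counts.index).to_numpy(),
    })
    for s in cm.samples:
        df[s] = cm.counts[s].to_numpy().astype(int)
    df.to_csv(path, index=False)


def _apply_pseudocount(values: np.ndarray, pseudocount: float) -> np.ndarray:
    """Replace zeros by the pseudocount so geometric means are defined."""
    out = np.asarray(values, dtype=float).copy()
    out[out == 0] = pseudocount
    return out


def geometric_mean(values) -> float:
    """exp(mean(log(values))) over strictly positive values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValidationError("geometric mean of empty input")
    if (arr <= 0).any():
        raise ValidationError("geometric mean requires strictly positive values "
                              "(apply a pseudocount to zeros upstream)")
    return float(np.exp(np.mean(np.log(arr))))


def positive_control_normalize(
    cm: CountMatrix,
    mean_type: str = "arithmetic",
    pseudocount: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Scale each sample so its positive-control geometric mean matches
    the cross-sample average.

    Returns ``(factors, scaled_counts)`` where per sample ``s``,
    ``factor_s = mean(g) / g_s`` with ``g_s`` the geometric mean of the
    sample's positive-control counts.
    """
    pos = cm.probes_of_class("positive")
    geomeans = {}
    for s in cm.samples:
        v = cm.counts.loc[pos, s].to_numpy(dtype=float)
        if (v == 0).all():
            raise ValidationError(f"all positive controls are zero in sample '{s}'")
        geomeans[s] = geometric_mean(_apply_pseudocount(v, pseudocount))
    g = pd.Series(geomeans)
    if mean_type == "arithmetic":
        center = float(g.mean())
    elif mean_type == "geometric":
        center = geometric_mean(g.to_numpy())
    else:
        raise ValidationError(f"unknown mean_type '{mean_type}'")
    factors = center / g
    scaled = cm.counts.astype(float) * factors
    logger.info("positive-control factors: %s", factors.to_dict())
    return factors, scaled


def background_threshold(
    values: pd.DataFrame,
    cm: CountMatrix,
    k_sd: float = 2.0,
    mode: str = "floor",
) -> tuple[pd.Series, pd.DataFrame]:
    """Background-threshold endogenous values against negative controls.

    ``threshold_s = mean(neg_s) + k_sd * sd(neg_s)`` (sample sd, n-1).
    In mode ``"floor"`` endogenous values <= threshold are set to 0
    (boundary inclusive); in mode ``"subtract"`` the threshold is
    subtracted and negatives clamped to 0.
    """
    if k_sd < 0:
        raise ValidationError("k_sd must be non-negative")
    if mode not in ("floor", "subtract"):
        raise ValidationError(f"unknown background mode '{mode}'")
    neg = cm.probes_of_class("negative")
    endo = cm.probes_of_class("endogenous")
    thresholds = {}
    out = values.copy()
    for s in values.columns:
        nv = values.loc[neg, s].to_numpy(dtype=float)
        sd = float(np.std(nv, ddof=1)) if nv.size > 1 else 0.0
        thr = float(np.mean(nv)) + k_sd * sd
        thresholds[s] = thr
        col = out.loc[endo, s]
        if mode == "floor":
            out.loc[endo, s] = col.where(col > thr, 0.0)
        else:
            out.loc[endo, s] = (col - thr).clip(lower=0.0)
    thr_series = pd.Series(thresholds)
    logger.info("background thresholds: %s", thr_series.to_dict())
    return thr_series, out


def content_normalize(
    values: pd.DataFrame,
    cm: CountMatrix,
    top_n: int = 100,
    pseudocount: float = 0.5,
) -> tuple[pd.Series, pd.DataFrame, list[str]]:
    """Scale each sample by the geometric mean of a fixed top-``top_n``
    endogenous probe set.

    The probe set is chosen once, by mean abundance across samples, so
    the per-sample factors are directly comparable.  Returns
    ``(factors, normalized, top_probes)``.
    """
    endo = cm.probes_of_class("endogenous")
    sub = values.loc[endo]
    if (sub.sum(axis=0) == 0).any():
        dead = [s for s in sub.columns if sub[s].sum() == 0]
        raise ValidationError(f"all endogenous counts are zero in sample(s) {dead}")
    if len(endo) < top_n:
        warnings.warn(
            f"only {len(endo)} endogenous probes (< top_n={top_n}); using all",
            stacklevel=2,
        )
        top_n = len(endo)
    mean_abundance = sub.mean(axis=1)
    # stable choice: abundance desc, probe id asc on ties
    order = mean_abundance.to_frame("m").assign(pid=mean_abundance.index)
    order = order.sort_values(["m", "pid"], ascending=[False, True])
    top_probes = list(order.index[:top_n])
    t = pd.Series({
        s: geometric_mean(_apply_pseudocount(sub.loc[top_probes, s].to_numpy(), pseudocount))
        for s in sub.columns
    })
    factors = float(t.mean()) / t
    normalized = values * factors
    logger.info("content-normalization factors (top %d probes): %s", top_n, factors.to_dict())
    return factors, normalized, top_probes


def compute_shares(values: pd.DataFrame, cm: CountMatrix) -> pd.DataFrame:
    """Per-sample fraction of total endogenous signal (columns sum to 1
    when the sample has any signal)."""
    endo = cm.probes_of_class("endogenous")
    sub = values.loc[endo]
    totals = sub.sum(axis=0)
    shares = sub.div(totals.where(totals > 0, np.nan), axis=1).fillna(0.0)
    return shares


def replicate_qc(values: pd.DataFrame, cm: CountMatrix) -> pd.DataFrame:
    """Pearson correlation of normalized endogenous profiles for every
    within-group sample pair.

    Zero-variance samples yield an undefined r, reported as NaN with a
    warning.
    """
    endo = cm.probes_of_class("endogenous")
    rows = []
    for group, samples in cm.groups().items():
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                a, b = samples[i], samples[j]
                va = values.loc[endo, a].to_numpy(dtype=float)
                vb = values.loc[endo, b].to_numpy(dtype=float)
                if np.std(va) == 0 or np.std(vb) == 0:
                    warnings.warn(
                        f"zero-variance sample in pair ({a}, {b}); Pearson r undefined",
                        stacklevel=2,
                    )
                    r = np.nan
                else:
                    r = float(np.corrcoef(va, vb)[0, 1])
                rows.append({"group": group, "sample_a": a, "sample_b": b, "pearson_r": r})
    return pd.DataFrame(rows, columns=["group", "sample_a", "sample_b", "pearson_r"])


def merge_replicates(values: pd.DataFrame, cm: CountMatrix) -> pd.DataFrame:
    """Average normalized values per probe across each replicate group;
    singleton groups pass through unchanged."""
    groups = cm.groups()
    if any(len(s) == 0 for s in groups.values()):
        raise ValidationError("empty replicate group")
    return pd.DataFrame({g: values[samples].mean(axis=1) for g, samples in groups.items()})


@dataclass
class NormParams:
    """Tunable normalization parameters (see module docstring)."""

    k_sd: float = 2.0
    pseudocount: float = 0.5
    top_n: int = 100
    background_mode: str = "floor"
    pos_mean_type: str = "arithmetic"


def normalize(cm: CountMatrix, params: NormParams | None = None) -> NormalizedProfile:
    """Run the full normalization sequence and QC on a count matrix."""
    p = params or NormParams()
    pos_factors, scaled = positive_control_normalize(
        cm, mean_type=p.pos_mean_type, pseudocount=p.pseudocount)
    thresholds, floored = background_threshold(
        scaled, cm, k_sd=p.k_sd, mode=p.background_mode)
    content_factors, normalized, _top = content_normalize(
        floored, cm, top_n=p.top_n, pseudocount=p.pseudocount)
    shares = compute_shares(normalized, cm)
    qc = replicate_qc(normalized, cm)
    return NormalizedProfile(
        values=normalized,
        shares=shares,
        background_threshold=thresholds,
        scale_factors_pos=pos_factors,
        scale_factors_content=content_factors,
        qc=qc,
    )


def merged_profile(profile: NormalizedProfile, cm: CountMatrix) -> pd.DataFrame:
    """Replicate-merged endogenous profile (probe x group)."""
    endo = cm.probes_of_class("endogenous")
    return merge_replicates(profile.values.loc[endo], cm)
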