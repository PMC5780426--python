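import numpy as np
import pandas as pd
import pytest

from exocargo.nanostring import CountMatrix


def make_count_matrix(
    endo: dict[str, list[int]],
    pos: dict[str, list[int]] | None = None,
    neg: dict[str, list[int]] | None = None,
    samples: list[str] | None = None,
    groups: dict[str, str] | None = None,
) -> CountMatrix:
    """Build a small CountMatrix from per-probe count lists."""
    pos = pos if pos is not None else {"POS_A": None}
    neg = neg if neg is not None else {"NEG_1": None}
    n_samples = len(next(iter(endo.values())))
    samples = samples or [f"s{i + 1}" for i in range(n_samples)]
    rows, classes = {}, {}
    for pid, vals in endo.items():
        rows[pid] = vals
        classes[pid] = "endogenous"
    for pid, vals in pos.items():
        rows[pid] = vals if vals is not None else [100] * n_samples
        classes[pid] = "positive"
    for pid, vals in neg.items():
        rows[pid] = vals if vals is not None else [0] * n_samples
        classes[pid] = "negative"
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    probe_class = pd.Series(classes)
    conc = pd.Series(
        {pid: (32.0 if cls == "positive" else np.nan) for pid, cls in classes.items()})
    return CountMatrix(counts=counts.astype(float), probe_class=probe_class,
                       expected_conc=conc, replicate_groups=groups or {})


def random_count_matrix(rng: np.random.Generator, n_endo: int = 20,
                        n_samples: int = 3) -> CountMatrix:
    """Random fixture with strictly positive counts (exact invariance
    checks need no pseudocount effects)."""
    endo = {f"mir-{i:02d}": (1 + rng.poisson(rng.uniform(5, 500), n_samples)).tolist()
            for i in range(n_endo)}
    pos = {f"POS_{c}": (1 + rng.poisson(m, n_samples)).tolist()
           for c, m in zip("ABC", (800, 200, 50))}
    neg = {f"NEG_{i}": rng.poisson(5, n_samples).tolist() for i in range(3)}
    groups = {f"s{i + 1}": "g1" for i in range(n_samples)}
    return make_count_matrix(endo, pos, neg, groups=groups)


@pytest.fixture
def tiny_cm() -> CountMatrix:
    """Two endogenous probes, one positive and one negative control,
    two samples in one replicate group."""
    return make_count_matrix(
        endo={"mir-a": [50, 60], "mir-b": [10, 12]},
        pos={"POS_A": [100, 100]},
        neg={"NEG_1": [0, 0]},
        groups={"s1": "g", "s2": "g"},
    )
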