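"""Statistical comparisons used at the figure level.

Pooled per-molecule distributions are compared with the two-sample
Kolmogorov-Smirnov test; per-cell summary values are compared with a
two-tailed unpaired t-test (two groups) or one-way ANOVA followed by
Bonferroni-adjusted pairwise t-tests (more than two groups).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = ["ComparisonResult", "ks_compare", "percell_compare"]


@dataclass
class ComparisonResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    p_value: float
    group_stats: dict  # label -> {mean, sd, n}

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value out of [0, 1]")


def _group_stats(samples: dict[str, np.ndarray]) -> dict:
    out = {}
    for label, x in samples.items():
        x = np.asarray(x, dtype=float)
        out[label] = {"mean": float(x.mean()), "sd": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                      "n": int(len(x))}
    return out


def ks_compare(sample_a, sample_b, label_a: str = "a", label_b: str = "b",
               min_n: int = 10) -> ComparisonResult:
    """Two-sided two-sample KS test (sup |ECDF_a - ECDF_b|, asymptotic p)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    if len(a) < min_n or len(b) < min_n:
        raise ValueError(f"need >= {min_n} values per sample")
    res = sps.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return ComparisonResult("KS", (label_a, label_b), float(res.statistic),
                            float(res.pvalue), _group_stats({label_a: a, label_b: b}))


def percell_compare(groups: dict[str, np.ndarray],
                    test: str = "auto") -> list[ComparisonResult]:
    """Compare per-cell values across conditions.

    Two groups: two-tailed unpaired t-test. More than two: one-way ANOVA,
    followed by all pairwise t-tests with Bonferroni adjustment
    (adjusted p = min(1, raw * m)). ``test`` may force 'ttest' or
    'anova_bonferroni'.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs >= 2 cells")
    gstats = _group_stats(arrays)

    if test == "ttest" or (test == "auto" and len(labels) == 2):
        if len(labels) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        a, b = arrays[labels[0]], arrays[labels[1]]
        t, p = sps.ttest_ind(a, b, equal_var=True)
        return [ComparisonResult("t-test", tuple(labels), float(t), float(p),
                                 {k: gstats[k] for k in labels})]

    f, p_anova = sps.f_oneway(*arrays.values())
    results = [ComparisonResult("ANOVA", tuple(labels), float(f), float(p_anova), gstats)]
    pairs = list(combinations(labels, 2))
    m = len(pairs)
    for a_label, b_label in pairs:
        t, p_raw = sps.ttest_ind(arrays[a_label], arrays[b_label], equal_var=True)
        results.append(ComparisonResult(
            "ANOVA+Bonferroni", (a_label, b_label), float(t),
            float(min(1.0, p_raw * m)),
            {k: gstats[k] for k in (a_label, b_label)},
        ))
    return results
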