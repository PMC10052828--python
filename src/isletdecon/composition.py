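"""Bootstrap estimation of subpopulation composition per cohort.

The point estimate is the observed subtype fraction over all of a cohort's
cells; uncertainty comes from repeatedly drawing a fixed number of cells with
replacement (default 1,000 cells, 100 iterations) and taking percentile
intervals of the bootstrap fractions.  Two cohorts differ significantly in a
subtype when their confidence intervals are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class CompositionEstimate:
    cohort: str
    point: pd.Series  # subtype -> observed fraction (sums to 1)
    ci_low: pd.Series
    ci_high: pd.Series
    n_boot: int
    n_sample: int
    seed: int


def bootstrap_proportions(
    subtype_labels: Sequence,
    cohort: str = "",
    n_sample: int = 1000,
    n_boot: int = 100,
    ci: float = 0.95,
    seed: int = 0,
    subtypes: Sequence | None = None,
) -> CompositionEstimate:
    """Percentile bootstrap CIs for subtype fractions in one cohort.

    Cells are drawn with replacement even when the cohort holds fewer than
    ``n_sample`` cells.  ``subtypes`` fixes the category universe (absent
    subtypes get proportion 0 with CI [0, 0]).
    """
    labels = pd.Series(subtype_labels)
    if labels.empty:
        raise ValidationError("cohort has no cells")
    cats = list(subtypes) if subtypes is not None else sorted(labels.unique())
    codes = pd.Categorical(labels, categories=cats).codes
    if (codes < 0).any():
        raise ValidationError("labels outside the given subtype universe")
    n_cells = len(codes)
    point = pd.Series(np.bincount(codes, minlength=len(cats)) / n_cells, index=cats)

    rng = np.random.default_rng(seed)
    fractions = np.empty((n_boot, len(cats)))
    for i in range(n_boot):
        draw = codes[rng.integers(0, n_cells, size=n_sample)]
        fractions[i] = np.bincount(draw, minlength=len(cats)) / n_sample
    lo_q, hi_q = (1 - ci) / 2, 1 - (1 - ci) / 2
    ci_low = pd.Series(np.quantile(fractions, lo_q, axis=0), index=cats)
    ci_high = pd.Series(np.quantile(fractions, hi_q, axis=0), index=cats)
    return CompositionEstimate(
        cohort=cohort, point=point, ci_low=ci_low, ci_high=ci_high,
        n_boot=n_boot, n_sample=n_sample, seed=seed,
    )


def compositions_by_cohort(
    obs: pd.DataFrame,
    cohort_key: str = "cohort",
    subtype_key: str = "subtype",
    n_sample: int = 1000,
    n_boot: int = 100,
    ci: float = 0.95,
    seed: int = 0,
) -> dict[str, CompositionEstimate]:
    """Run the bootstrap per cohort over a shared subtype universe."""
    cats = sorted(obs[subtype_key].unique())
    out = {}
    for i, cohort in enumerate(sorted(obs[cohort_key].unique())):
        labels = obs.loc[obs[cohort_key] == cohort, subtype_key]
        out[cohort] = bootstrap_proportions(
            labels, cohort=cohort, n_sample=n_sample, n_boot=n_boot,
            ci=ci, seed=seed + i, subtypes=cats,
        )
    return out


def compare_compositions(
    estimates: Mapping[str, CompositionEstimate] | Sequence[CompositionEstimate],
) -> pd.DataFrame:
    """Pairwise CI-overlap significance calls across cohorts.

    Two estimates differ significantly in a subtype iff the intervals are
    strictly disjoint (one interval's low exceeds the other's high; touching
    endpoints are not significant).  Subtype universes are aligned on the
    union; a subtype missing from a cohort gets proportion 0 with CI [0, 0].
    """
    ests = list(estimates.values()) if isinstance(estimates, Mapping) else list(estimates)
    if len(ests) < 2:
        raise ValidationError("need at least 2 cohorts to compare")
    universe = sorted({st for e in ests for st in e.point.index})
    rows = []
    for i in range(len(ests)):
        for j in range(i + 1, len(ests)):
            a, b = ests[i], ests[j]
            for st in universe:
                lo_a = float(a.ci_low.get(st, 0.0))
                hi_a = float(a.ci_high.get(st, 0.0))
                lo_b = float(b.ci_low.get(st, 0.0))
                hi_b = float(b.ci_high.get(st, 0.0))
                rows.append(
                    {
                        "subtype": st,
                        "cohort_a": a.cohort,
                        "cohort_b": b.cohort,
                        "ci_a_low": lo_a,
                        "ci_a_high": hi_a,
                        "ci_b_low": lo_b,
                        "ci_b_high": hi_b,
                        "significant": lo_a > hi_b or lo_b > hi_a,
                    }
                )
    return pd.DataFrame(rows)


def composition_long_table(
    estimates: Mapping[str, CompositionEstimate],
) -> pd.DataFrame:
    """Long-format table (cohort, subtype, proportion, ci) for plotting."""
    rows = []
    for cohort, est in estimates.items():
        for st in est.point.index:
            rows.append(
                {
                    "cohort": cohort,
                    "subtype": st,
                    "proportion": est.point[st],
                    "ci_low": est.ci_low[st],
                    "ci_high": est.ci_high[st],
                }
            )
    return pd.DataFrame(rows)
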