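"""One-tailed Wilcoxon signed-rank test of rate contrasts against richness.

Each sister pair contributes one signed difference, species-rich value
minus species-poor value.  Absolute differences are ranked ascending
(mean ranks for ties) and W is the sum of ranks of positive differences.
The one-tailed p-value P(W* >= W) under the symmetric null is exact (a
dynamic program over all sign assignments) up to n = 25 pairs, beyond
which a tie- and continuity-corrected normal approximation is used.

Zero-difference policies:

* ``drop`` - exclude zero differences (the R default);
* ``rank_zero_positive`` - keep them, ranked among the absolute
  differences (a zero is the smallest magnitude) and counted positive;
  this is the convention that reproduces published rank sums computed
  from values rounded to a finite number of digits, where an underlying
  tiny positive difference prints as a tie;
* ``pratt`` - keep zeros in the ranking but exclude their ranks from W.

Pairs with equal species richness cannot be oriented and are excluded
here (not during contrast construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from claderates.sister_pairs import PairContrast

EXACT_CUTOFF = 25
ZERO_POLICIES = ("drop", "rank_zero_positive", "pratt")
METRICS = ("total", "dN", "dS", "omega")


@dataclass
class WilcoxonResult:
    W: float
    n_used: int
    p_one_tailed: float
    method: str  # "exact" | "normal_approx" | "degenerate"
    zero_policy: str
    alternative: str = "rich_greater"
    excluded: list[tuple[str, str]] = field(default_factory=list)
    low_power: bool = False

    @property
    def max_W(self) -> float:
        return self.n_used * (self.n_used + 1) / 2.0


def _exact_tail_prob(ranks: np.ndarray, w_obs: float, signable: np.ndarray) -> float:
    """P(W* >= w_obs) over uniform signs of the signable ranks.

    ``ranks`` may contain mean-rank halves; everything is doubled to keep
    the DP integral.  Non-signable ranks (Pratt zeros) contribute to
    neither W* nor the sign space.
    """
    r2 = np.rint(2.0 * ranks[signable]).astype(int)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    w2 = int(np.ceil(2.0 * w_obs - 1e-9))
    tail = counts[w2:].sum()
    return float(tail / 2.0 ** len(r2))


def signed_rank_test(
    contrasts: Iterable[PairContrast] | Sequence[float],
    alternative: str = "rich_greater",
    zero_policy: str = "drop",
    tie_policy: str = "mean_rank",
    exact_cutoff: int = EXACT_CUTOFF,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on rich-minus-poor contrasts.

    ``contrasts`` may be :class:`PairContrast` objects or raw signed
    differences.  W is the sum of ranks of positive differences; the
    p-value direction follows ``alternative`` ("rich_greater" for the
    upper tail, or "two_sided").
    """
    if zero_policy not in ZERO_POLICIES:
        raise ValueError(f"zero_policy must be one of {ZERO_POLICIES}")
    if tie_policy != "mean_rank":
        raise ValueError("only mean_rank tie handling is supported")
    items = list(contrasts)
    if not items:
        raise ValueError("no contrasts supplied")
    if hasattr(items[0], "diff"):
        ids = [c.pair_id for c in items]
        diffs = np.array([c.diff for c in items], dtype=float)
    else:
        ids = [str(i) for i in range(len(items))]
        diffs = np.array(items, dtype=float)

    excluded: list[tuple[str, str]] = []
    if zero_policy == "drop":
        keep = diffs != 0
        excluded += [(ids[i], "zero difference") for i in np.where(~keep)[0]]
        diffs = diffs[keep]
    if diffs.size == 0 or np.all(diffs == 0):
        return WilcoxonResult(
            W=0.0, n_used=int(diffs.size), p_one_tailed=1.0, method="degenerate",
            zero_policy=zero_policy, alternative=alternative, excluded=excluded,
        )

    ranks = rankdata(np.abs(diffs), method="average")
    if zero_policy == "pratt":
        signable = diffs != 0
        w = float(ranks[diffs > 0].sum())
    elif zero_policy == "rank_zero_positive":
        signable = np.ones(diffs.shape, dtype=bool)
        w = float(ranks[diffs >= 0].sum())
    else:
        signable = np.ones(diffs.shape, dtype=bool)
        w = float(ranks[diffs > 0].sum())

    n_used = int(diffs.size)
    n_sign = int(signable.sum())
    if n_sign <= exact_cutoff:
        p_upper = _exact_tail_prob(ranks, w, signable)
        method = "exact"
    else:
        sr = ranks[signable]
        mean = sr.sum() / 2.0
        sd = np.sqrt((sr ** 2).sum() / 4.0)
        p_upper = float(norm.sf((w - mean - 0.5) / sd))
        method = "normal_approx"
    if alternative == "rich_greater":
        p = p_upper
    elif alternative == "two_sided":
        if method == "exact":
            p_lower = 1.0 - _exact_tail_prob(ranks, w + 0.5, signable)
            p = min(1.0, 2.0 * min(p_upper, p_lower))
        else:
            p = min(1.0, 2.0 * min(p_upper, 1.0 - p_upper))
    else:
        raise ValueError("alternative must be 'rich_greater' or 'two_sided'")

    return WilcoxonResult(
        W=w, n_used=n_used, p_one_tailed=min(max(p, 0.0), 1.0), method=method,
        zero_policy=zero_policy, alternative=alternative, excluded=excluded,
        low_power=n_used < 5,
    )


def run_all_metrics(
    pair_table: pd.DataFrame | str,
    metrics: Sequence[str] = METRICS,
    zero_policy: str = "drop",
    alternative: str = "rich_greater",
    zero_policy_overrides: dict[str, str] | None = None,
) -> dict[str, WilcoxonResult]:
    """Signed-rank tests for every metric column pair of a contrast table.

    The table needs ``pair_id``, ``richness_rich``, ``richness_poor`` and,
    per metric, ``<metric>_rich`` / ``<metric>_poor`` columns.  Pairs with
    equal species richness are excluded from every metric (recorded on
    each result).  ``zero_policy_overrides`` sets a per-metric policy.
    """
    if isinstance(pair_table, (str, bytes)) or hasattr(pair_table, "__fspath__"):
        pair_table = pd.read_csv(pair_table, sep="\t")
    for col in ("pair_id", "richness_rich", "richness_poor"):
        if col not in pair_table.columns:
            raise ValueError(f"pair table missing column: {col}")
    overrides = zero_policy_overrides or {}

    equal = pair_table["richness_rich"] == pair_table["richness_poor"]
    usable = pair_table[~equal]
    equal_excluded = [(str(r["pair_id"]), "equal species richness")
                      for _, r in pair_table[equal].iterrows()]

    results: dict[str, WilcoxonResult] = {}
    for metric in metrics:
        cols = (f"{metric}_rich", f"{metric}_poor")
        for col in cols:
            if col not in pair_table.columns:
                raise ValueError(f"pair table missing column: {col}")
        contrasts = [
            PairContrast(str(r["pair_id"]), float(r[cols[0]]), float(r[cols[1]]), metric)
            for _, r in usable.iterrows()
        ]
        res = signed_rank_test(
            contrasts,
            alternative=alternative,
            zero_policy=overrides.get(metric, zero_policy),
        )
        res.excluded = equal_excluded + res.excluded
        results[metric] = res
    return results


def summary_table(results: dict[str, WilcoxonResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {"metric": m, "n_used": r.n_used, "W": r.W, "p_one_tailed": r.p_one_tailed,
         "method": r.method, "zero_policy": r.zero_policy}
        for m, r in results.items()
    ])
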