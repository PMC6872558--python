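"""Inter- and intraspecific divergence statistics and marker comparison.

Six statistics summarise a labelled distance matrix, three interspecific and
three intraspecific:

* **all interspecific distance** — mean distance over heterospecific pairs;
* **theta prime (θ′)** — each species' mean distance to all heterospecific
  individuals, averaged over species;
* **minimum interspecific distance** — each species' minimum distance to any
  heterospecific individual, averaged over species;
* **all intraspecific distance** — mean distance over conspecific pairs;
* **theta (θ)** — each species' mean conspecific distance, averaged over
  species with at least two sampled individuals;
* **coalescent depth** — each species' maximum conspecific distance, averaged
  over the same qualifying species.

Markers are compared with the Wilcoxon signed-rank test on distances paired by
sample pair (the same two individuals measured with two markers).  The exact
two-sided p-value (the distribution over all 2^n sign assignments, mid-ranked
ties, zero differences dropped) is used for n <= 25 and a tie- and
continuity-corrected normal approximation beyond.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .seqdata import DistanceMatrix
from .site_stats import UndefinedValueError

logger = logging.getLogger(__name__)

EXACT_N_MAX = 25

STATISTIC_ROWS = (
    "all_interspecific_distance",
    "theta_prime",
    "minimum_interspecific_distance",
    "all_intraspecific_distance",
    "theta",
    "coalescent_depth",
)


@dataclass(frozen=True)
class Dispersed:
    """A mean with both dispersion conventions (the field reports either)."""

    mean: float
    sd: float
    se: float

    @classmethod
    def of(cls, xs: np.ndarray) -> "Dispersed":
        xs = np.asarray(xs, dtype=float)
        if xs.size == 0:
            return cls(math.nan, math.nan, math.nan)
        sd = float(np.std(xs, ddof=1)) if xs.size > 1 else 0.0
        return cls(float(np.mean(xs)), sd, sd / math.sqrt(xs.size))

    @property
    def defined(self) -> bool:
        return not math.isnan(self.mean)


@dataclass(frozen=True)
class DivergenceSummary:
    marker: str
    all_interspecific_distance: Dispersed
    theta_prime: Dispersed
    minimum_interspecific_distance: Dispersed
    all_intraspecific_distance: Dispersed
    theta: Dispersed
    coalescent_depth: Dispersed
    n_species: int
    n_samples: int

    def as_dict(self) -> dict[str, float]:
        return {row: getattr(self, row).mean for row in STATISTIC_ROWS}


@dataclass(frozen=True)
class RankTestResult:
    marker_a: str
    marker_b: str
    W: float
    n_pairs: int
    p_value: float
    method: str  # "exact" or "normal_approximation"


def divergence_summary(
    dm: DistanceMatrix, marker: str = "", theta_prime: str = "per_species"
) -> DivergenceSummary:
    """Compute the six divergence statistics from a labelled distance matrix.

    Undefined (NaN) distances are excluded pairwise.  Interspecific fields are
    NaN when the matrix holds a single species; intraspecific fields are NaN
    when no species has two or more samples.  ``theta_prime`` selects the
    convention: ``"per_species"`` (each species' mean distance to all
    heterospecific individuals, averaged over species — the default) or
    ``"per_species_pair"`` (mean cross-distance per species pair, averaged
    over pairs).
    """
    if theta_prime not in ("per_species", "per_species_pair"):
        raise ValueError(f"unknown theta_prime convention {theta_prime!r}")
    species = np.asarray(dm.species)
    vals = dm.values
    n = dm.n
    iu, ju = np.triu_indices(n, k=1)
    d = vals[iu, ju]
    ok = ~np.isnan(d)
    same = species[iu] == species[ju]

    inter_all = d[ok & ~same]
    intra_all = d[ok & same]

    uniq = sorted(set(dm.species))
    theta_prime_per, min_inter_per = [], []
    theta_per, depth_per = [], []
    for sp in uniq:
        mine = species == sp
        block = vals[np.ix_(mine, ~mine)]
        block = block[~np.isnan(block)]
        if block.size:
            theta_prime_per.append(block.mean())
            min_inter_per.append(block.min())
        k = int(mine.sum())
        if k >= 2:
            within = vals[np.ix_(mine, mine)]
            wi, wj = np.triu_indices(k, k=1)
            w = within[wi, wj]
            w = w[~np.isnan(w)]
            if w.size:
                theta_per.append(w.mean())
                depth_per.append(w.max())
    if theta_prime == "per_species_pair":
        theta_prime_per = []
        for i, a in enumerate(uniq):
            for b in uniq[i + 1:]:
                cross = vals[np.ix_(species == a, species == b)]
                cross = cross[~np.isnan(cross)]
                if cross.size:
                    theta_prime_per.append(cross.mean())

    if inter_all.size == 0:
        logger.warning("no heterospecific pairs: interspecific fields undefined")
    if intra_all.size == 0:
        logger.warning("no conspecific pairs: intraspecific fields undefined")

    return DivergenceSummary(
        marker=marker,
        all_interspecific_distance=Dispersed.of(inter_all),
        theta_prime=Dispersed.of(np.asarray(theta_prime_per)),
        minimum_interspecific_distance=Dispersed.of(np.asarray(min_inter_per)),
        all_intraspecific_distance=Dispersed.of(intra_all),
        theta=Dispersed.of(np.asarray(theta_per)),
        coalescent_depth=Dispersed.of(np.asarray(depth_per)),
        n_species=len(uniq),
        n_samples=n,
    )


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided tail of the signed-rank sum over all 2^n sign assignments.

    Ties give half-integer mid-ranks, so ranks are doubled to integers and the
    distribution of the positive-rank sum is accumulated by dynamic
    programming — arithmetically identical to full enumeration.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2.0 * w_obs))
    mean2 = total / 2.0
    dev = abs(w2 - mean2)
    support = np.arange(total + 1, dtype=float)
    # tolerance guards the half-integer midpoint comparison
    tail = counts[np.abs(support - mean2) >= dev - 1e-9].sum()
    return min(1.0, float(tail))


def wilcoxon_signed_rank(
    x, y, marker_a: str = "a", marker_b: str = "b"
) -> RankTestResult:
    """Paired two-sided Wilcoxon signed-rank test of x vs y.

    Zero differences are dropped; ties are mid-ranked.  W is the sum of ranks
    of positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    diffs = x - y
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise UndefinedValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(diffs))
    W = float(ranks[diffs > 0].sum())
    if n <= EXACT_N_MAX:
        p = _exact_two_sided_p(ranks, W)
        method = "exact"
    else:
        mean = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        var -= float(((tie_counts**3 - tie_counts) / 48.0).sum())
        dev = abs(W - mean)
        z = max(0.0, dev - 0.5) / math.sqrt(var)  # continuity correction
        p = min(1.0, 2.0 * sps.norm.sf(z))
        method = "normal_approximation"
    return RankTestResult(
        marker_a=marker_a, marker_b=marker_b,
        W=W, n_pairs=n, p_value=p, method=method,
    )


def paired_distances(
    long_a: pd.DataFrame, long_b: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Align two long-format distance tables on their (sample_i, sample_j) keys.

    Pairs present in only one marker (or undefined in either) are dropped and
    counted in the log.
    """
    def keyed(df: pd.DataFrame) -> pd.DataFrame:
        key = [tuple(sorted(k)) for k in zip(df["sample_i"], df["sample_j"])]
        out = df.assign(_key=key).dropna(subset=["d"])
        return out.set_index("_key")

    a, b = keyed(long_a), keyed(long_b)
    shared = a.index.intersection(b.index)
    n_dropped = (len(a) - len(shared)) + (len(b) - len(shared))
    if n_dropped:
        logger.warning("wilcoxon pairing: dropped %d unmatched sample pairs",
                       n_dropped)
    if len(shared) == 0:
        raise UndefinedValueError("no shared sample pairs between markers")
    return (a.loc[shared, "d"].to_numpy(), b.loc[shared, "d"].to_numpy())


def compare_markers(
    long_tables: dict[str, pd.DataFrame]
) -> list[RankTestResult]:
    """All pairwise signed-rank tests among markers' interspecific distances."""
    results = []
    names = list(long_tables)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            xa, xb = paired_distances(long_tables[a], long_tables[b])
            try:
                results.append(wilcoxon_signed_rank(xa, xb, a, b))
            except UndefinedValueError:
                logger.warning("markers %s vs %s: identical paired distances, "
                               "test undefined", a, b)
    return results


def rank_markers(
    summaries: list[DivergenceSummary],
    tests: list[RankTestResult] | None = None,
) -> list[dict]:
    """Order markers by mean interspecific distance (ties keep input order).

    Each adjacent comparison is annotated with its signed-rank p-value when a
    matching test is supplied.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two markers to rank")
    order = sorted(
        range(len(summaries)),
        key=lambda i: (-_safe(summaries[i].all_interspecific_distance.mean), i),
    )
    p_by_pair = {}
    for t in tests or []:
        p_by_pair[frozenset((t.marker_a, t.marker_b))] = t.p_value
    ranking = []
    for pos, idx in enumerate(order):
        s = summaries[idx]
        entry = {
            "rank": pos + 1,
            "marker": s.marker,
            "all_interspecific_distance": s.all_interspecific_distance.mean,
        }
        if pos > 0:
            prev = summaries[order[pos - 1]].marker
            entry["p_vs_previous"] = p_by_pair.get(frozenset((prev, s.marker)))
        ranking.append(entry)
    return ranking


def _safe(x: float) -> float:
    return -math.inf if math.isnan(x) else x


def summaries_table(summaries: list[DivergenceSummary]) -> pd.DataFrame:
    """Markers as columns, the six statistics (mean ± SD) as rows."""
    cols = {}
    for s in summaries:
        col = {}
        for row in STATISTIC_ROWS:
            disp: Dispersed = getattr(s, row)
            col[row] = (f"{disp.mean:.4f} ± {disp.sd:.4f}"
                        if disp.defined else "NA")
        cols[s.marker] = col
    return pd.DataFrame(cols).reindex(STATISTIC_ROWS)
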