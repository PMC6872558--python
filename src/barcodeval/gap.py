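"""Barcoding-gap assessment.

A usable barcode shows a "barcoding gap": the distribution of within-species
(intraspecific) pairwise distances separates cleanly from the distribution of
between-species (interspecific) distances.  The gap criterion used here is the
distribution-extrema rule: a gap is present iff the smallest interspecific
distance exceeds the largest intraspecific distance, and the gap interval is
``[max_intra, min_inter]`` (reported in percent, 100·d).  When distributions
overlap, the overlap fraction — the share of interspecific distances at or
below the intraspecific maximum — quantifies how badly.

Histograms on shared percent-scale bins are provided for plotting the paired
distributions marker by marker.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqdata import DistanceMatrix
from .site_stats import UndefinedValueError

DEFAULT_BIN_WIDTH_PERCENT = 0.2


@dataclass(frozen=True)
class GapProfile:
    marker: str
    intra_distances: np.ndarray  # substitutions/site
    inter_distances: np.ndarray
    bin_width: float             # percent scale
    max_intra: float
    min_inter: float
    gap_present: bool
    gap_interval_percent: tuple[float, float] | None  # (100*max_intra, 100*min_inter)
    overlap_fraction: float
    bin_edges_percent: np.ndarray
    intra_counts: np.ndarray
    inter_counts: np.ndarray

    @property
    def gap_width_percent(self) -> float:
        if not self.gap_present:
            return 0.0
        return self.gap_interval_percent[1] - self.gap_interval_percent[0]


def gap_profile(
    dm: DistanceMatrix,
    bin_width: float = DEFAULT_BIN_WIDTH_PERCENT,
    marker: str = "",
) -> GapProfile:
    """Split a distance matrix into intra/inter distributions and detect a gap.

    Undefined (NaN) distances are excluded.  Raises when either side is empty,
    naming the missing side.
    """
    species = np.asarray(dm.species)
    iu, ju = np.triu_indices(dm.n, k=1)
    d = dm.values[iu, ju]
    same = species[iu] == species[ju]
    ok = ~np.isnan(d)
    intra = np.sort(d[ok & same])
    inter = np.sort(d[ok & ~same])
    if intra.size == 0:
        raise UndefinedValueError("no intraspecific distances defined")
    if inter.size == 0:
        raise UndefinedValueError("no interspecific distances defined")
    max_intra = float(intra[-1])
    min_inter = float(inter[0])
    gap_present = min_inter > max_intra
    overlap = float((inter <= max_intra).sum() / inter.size)
    top = max(float(inter[-1]), max_intra) * 100.0
    n_bins = max(1, int(math.ceil(top / bin_width + 1e-9)))
    edges = np.arange(n_bins + 1) * bin_width
    intra_counts, _ = np.histogram(intra * 100.0, bins=edges)
    inter_counts, _ = np.histogram(inter * 100.0, bins=edges)
    return GapProfile(
        marker=marker,
        intra_distances=intra,
        inter_distances=inter,
        bin_width=bin_width,
        max_intra=max_intra,
        min_inter=min_inter,
        gap_present=gap_present,
        gap_interval_percent=(
            (100.0 * max_intra, 100.0 * min_inter) if gap_present else None
        ),
        overlap_fraction=overlap,
        bin_edges_percent=edges,
        intra_counts=intra_counts,
        inter_counts=inter_counts,
    )


def gap_report(profiles: list[GapProfile]) -> pd.DataFrame:
    """Rank markers by gap quality.

    Gapped markers first; overlapping markers by ascending overlap fraction;
    among gapped markers, wider gap intervals first.
    """
    if not profiles:
        raise UndefinedValueError("no gap profiles to report")
    ordered = sorted(
        profiles,
        key=lambda p: (not p.gap_present, p.overlap_fraction, -p.gap_width_percent),
    )
    rows = []
    for p in ordered:
        rows.append(
            {
                "marker": p.marker,
                "gap_present": p.gap_present,
                "max_intra_percent": 100.0 * p.max_intra,
                "min_inter_percent": 100.0 * p.min_inter,
                "gap_width_percent": p.gap_width_percent,
                "overlap_fraction": p.overlap_fraction,
                "n_intra": p.intra_distances.size,
                "n_inter": p.inter_distances.size,
            }
        )
    return pd.DataFrame(rows)


def histogram_table(profile: GapProfile) -> pd.DataFrame:
    """Shared-bin histogram of the two distributions, percent-scale edges."""
    return pd.DataFrame(
        {
            "bin_left_percent": profile.bin_edges_percent[:-1],
            "bin_right_percent": profile.bin_edges_percent[1:],
            "intra_count": profile.intra_counts,
            "inter_count": profile.inter_counts,
        }
    )
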