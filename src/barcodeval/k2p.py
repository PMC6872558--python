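"""Kimura two-parameter (K2P) pairwise distances.

The K2P model corrects observed differences for multiple hits while
distinguishing transitions (A<->G, C<->T; proportion P) from transversions
(proportion Q):

    d = -(1/2) * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

P and Q are computed over *comparable* columns only — both residues
unambiguous and ungapped (pairwise deletion by default; complete deletion of
any column with missing data is available as an option).  Pairs whose observed
divergence saturates the correction (the log argument reaching zero or below)
are flagged undefined and excluded from downstream summaries rather than
clamped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np

from .seqdata import MISSING, DistanceMatrix, InputError, MarkerAlignment
from .site_stats import UndefinedValueError

logger = logging.getLogger(__name__)


class SaturationError(ValueError):
    """Observed divergence too large for the K2P correction to be defined."""


@dataclass(frozen=True)
class K2PPair:
    """Transition/transversion proportions and distance for one sample pair."""

    P: float
    Q: float
    n: int
    d: float  # NaN when saturated

    @property
    def defined(self) -> bool:
        return not math.isnan(self.d)


def k2p_from_proportions(P: float, Q: float) -> float:
    """Evaluate the K2P closed form; raises on saturation."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K2P undefined at P={P}, Q={Q}")
    return -0.5 * math.log(w1 * math.sqrt(w2)) + 0.0  # +0.0 avoids -0.0


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(transitions, transversions, comparable columns) for encoded rows."""
    comparable = (a != MISSING) & (b != MISSING)
    n = int(comparable.sum())
    if n == 0:
        return 0, 0, 0
    ai, bi = a[comparable], b[comparable]
    diff = ai != bi
    # purines (A=0, G=2) are even codes, pyrimidines (C=1, T=3) odd:
    # a difference within one parity class is a transition.
    transversion = diff & ((ai & 1) != (bi & 1))
    nv = int(transversion.sum())
    ns = int(diff.sum()) - nv
    return ns, nv, n


def k2p_pair(a, b) -> K2PPair:
    """K2P distance between two aligned sequences (SampleRecords or arrays)."""
    ea = a if isinstance(a, np.ndarray) else a.encoded()
    eb = b if isinstance(b, np.ndarray) else b.encoded()
    if ea.shape != eb.shape:
        raise InputError("sequences have unequal aligned length")
    ns, nv, n = _pair_counts(ea, eb)
    if n == 0:
        raise UndefinedValueError("no comparable columns between the pair")
    P, Q = ns / n, nv / n
    try:
        d = k2p_from_proportions(P, Q)
    except SaturationError:
        d = math.nan
    return K2PPair(P=P, Q=Q, n=n, d=d)


def k2p_matrix(aln: MarkerAlignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Full pairwise K2P matrix for an alignment.

    ``deletion`` is ``"pairwise"`` (per-pair comparable columns) or
    ``"complete"`` (drop every column with any gap/ambiguity first).
    Saturated or zero-overlap pairs become NaN entries, logged, never raised.
    """
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    mat = aln.encoded_matrix()
    if deletion == "complete":
        keep = (mat != MISSING).all(axis=0)
        mat = mat[:, keep]
    return k2p_matrix_encoded(mat, aln.sample_ids, aln.species, name=aln.marker)


def k2p_matrix_encoded(
    mat: np.ndarray,
    labels: list[str],
    species: list[str],
    name: str = "",
) -> DistanceMatrix:
    """K2P matrix from an already-encoded (n, L) int matrix (pairwise deletion)."""
    m = mat.shape[0]
    values = np.zeros((m, m))
    n_eff = np.zeros((m, m), dtype=int)
    n_eff[np.diag_indices(m)] = mat.shape[1]
    n_undef = 0
    for i, j in itertools.combinations(range(m), 2):
        ns, nv, n = _pair_counts(mat[i], mat[j])
        if n == 0:
            d = math.nan
        else:
            try:
                d = k2p_from_proportions(ns / n, nv / n)
            except SaturationError:
                d = math.nan
        if math.isnan(d):
            n_undef += 1
        values[i, j] = values[j, i] = d
        n_eff[i, j] = n_eff[j, i] = n
    if n_undef:
        logger.warning("k2p_matrix(%s): %d undefined (saturated/empty) pairs",
                       name, n_undef)
    return DistanceMatrix(
        labels=list(labels), species=list(species),
        values=values, n_effective=n_eff,
    )
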