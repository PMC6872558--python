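"""Per-marker sequence characteristics.

Reproduces the standard marker-description table of a barcoding study:
sequence-length and GC ranges, conserved / variable / parsimony-informative
site counts, the aberration rate (variable sites as a percentage of alignment
length), and mean pairwise similarity.

Column classification rules
---------------------------
A column containing any gap or ambiguity code is excluded from the
conserved/variable classification (``gap_containing``; ``all_missing`` when no
unambiguous base remains at all).  Among fully unambiguous columns, a column
is *conserved* when all states agree and *variable* otherwise; a variable
column is *parsimony-informative* when at least two states each occur in at
least two sequences.  The aberration rate keeps the full alignment length in
its denominator.  This reconciles the arithmetic of published marker tables,
where conserved+variable equals alignment length for gap-free markers but
falls short of it by exactly the gap-containing columns otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .seqdata import MISSING, InputError, MarkerAlignment, SampleRecord

logger = logging.getLogger(__name__)

CONSERVED, VARIABLE, GAP_CONTAINING, ALL_MISSING = (
    "conserved", "variable", "gap_containing", "all_missing",
)


class UndefinedValueError(ValueError):
    """A statistic has no defined value on this input (e.g. no bases)."""


@dataclass(frozen=True)
class SiteClassification:
    """Per-column labels plus the summary counts derived from them."""

    column_labels: tuple[str, ...]
    conserved_sites: int
    variable_sites: int
    informative_sites: int
    gap_containing_sites: int
    all_missing_sites: int
    alignment_length: int
    aberration_rate_percent: float

    def __post_init__(self) -> None:
        total = (self.conserved_sites + self.variable_sites
                 + self.gap_containing_sites + self.all_missing_sites)
        assert total == self.alignment_length, "site partition identity violated"
        assert self.informative_sites <= self.variable_sites


@dataclass(frozen=True)
class SequenceCharacteristics:
    """One marker's row-set of the characteristics table."""

    marker: str
    length_range: tuple[int, int]          # ungapped bp, min-max over samples
    gc_range: tuple[float, float]          # percent, min-max over samples
    classification: SiteClassification
    mean_pairwise_similarity_percent: float


def gc_content(record: SampleRecord) -> float:
    """Percent G+C among unambiguous bases (gaps/ambiguities excluded)."""
    enc = record.encoded()
    counted = enc[enc != MISSING]
    if counted.size == 0:
        raise UndefinedValueError(
            f"record {record.sample_id!r} has no unambiguous bases"
        )
    gc = np.isin(counted, (1, 2)).sum()  # C=1, G=2
    return 100.0 * float(gc) / counted.size


def classify_sites(aln: MarkerAlignment) -> SiteClassification:
    """Classify every alignment column and summarise the counts."""
    mat = aln.encoded_matrix()
    n, L = mat.shape
    if L == 0:
        raise InputError("alignment has zero columns")
    labels: list[str] = []
    conserved = variable = informative = gapcols = allmiss = 0
    for col in mat.T:
        present = col != MISSING
        if not present.any():
            labels.append(ALL_MISSING)
            allmiss += 1
        elif not present.all():
            labels.append(GAP_CONTAINING)
            gapcols += 1
        else:
            counts = np.bincount(col, minlength=4)
            states = (counts > 0).sum()
            if states == 1:
                labels.append(CONSERVED)
                conserved += 1
            else:
                labels.append(VARIABLE)
                variable += 1
                if (counts >= 2).sum() >= 2:
                    informative += 1
    return SiteClassification(
        column_labels=tuple(labels),
        conserved_sites=conserved,
        variable_sites=variable,
        informative_sites=informative,
        gap_containing_sites=gapcols,
        all_missing_sites=allmiss,
        alignment_length=L,
        aberration_rate_percent=100.0 * variable / L,
    )


def classification_ranges(cls: SiteClassification):
    """Per-column labels as 0-based, half-open column ranges (BED-like).

    Returns a DataFrame with columns start, end, label, merging runs of
    identically labelled columns.
    """
    import pandas as pd

    rows = []
    start = 0
    labels = cls.column_labels
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            rows.append({"start": start, "end": i, "label": labels[start]})
            start = i
    return pd.DataFrame(rows)


def _pair_similarity(a: np.ndarray, b: np.ndarray) -> float | None:
    comparable = (a != MISSING) & (b != MISSING)
    n = int(comparable.sum())
    if n == 0:
        return None
    ident = int((a[comparable] == b[comparable]).sum())
    return 100.0 * ident / n


def mean_pairwise_similarity(aln: MarkerAlignment, scope: str = "all") -> float:
    """Average percent identity over comparable columns of sample pairs.

    ``scope`` restricts to ``"interspecific"`` (heterospecific pairs only),
    ``"intraspecific"`` (conspecific), or ``"all"``.  Comparable columns are
    those unambiguous and ungapped in both sequences (pairwise deletion);
    pairs with no comparable column are skipped with a warning.
    """
    if scope not in ("all", "interspecific", "intraspecific"):
        raise ValueError(f"unknown scope {scope!r}")
    mat = aln.encoded_matrix()
    species = aln.species
    sims = []
    skipped = 0
    for i, j in itertools.combinations(range(len(aln.records)), 2):
        if scope == "interspecific" and species[i] == species[j]:
            continue
        if scope == "intraspecific" and species[i] != species[j]:
            continue
        s = _pair_similarity(mat[i], mat[j])
        if s is None:
            skipped += 1
        else:
            sims.append(s)
    if skipped:
        logger.warning("similarity (%s): skipped %d pairs with no comparable columns",
                       scope, skipped)
    if not sims:
        raise UndefinedValueError(f"no scorable pairs in scope {scope!r}")
    return float(np.mean(sims))


def sequence_characteristics(aln: MarkerAlignment) -> SequenceCharacteristics:
    """Compute the full characteristics summary for one marker."""
    lengths = [r.ungapped_length() for r in aln.records]
    gcs = [gc_content(r) for r in aln.records]
    return SequenceCharacteristics(
        marker=aln.marker,
        length_range=(min(lengths), max(lengths)),
        gc_range=(min(gcs), max(gcs)),
        classification=classify_sites(aln),
        mean_pairwise_similarity_percent=mean_pairwise_similarity(aln, "all"),
    )
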