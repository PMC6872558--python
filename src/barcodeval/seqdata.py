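"""Domain types and I/O for species-annotated marker alignments.

A *marker* is a short barcoding locus (ITS, ITS2, matK, rbcL, psbA-trnH, or a
concatenation label such as "ITS2+psbA-trnH").  Every downstream stage —
sequence characteristics, K2P distances, divergence statistics, barcoding-gap
assessment, and tree building — consumes a :class:`MarkerAlignment`: an aligned
FASTA of one marker joined with a sample-metadata table (sample id, species,
marker, optional provenance).

Sequences are stored as aligned uppercase strings over the IUPAC nucleotide
alphabet plus ``-`` for gaps.  Ambiguity codes are accepted on input but are
treated as missing data by every analysis stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Unambiguous bases, in the internal integer coding (A=0, C=1, G=2, T=3).
#: Purines (A, G) are even, pyrimidines (C, T) odd, so two comparable residues
#: differ by a transition iff they differ and share parity.
BASES = "ACGT"

#: IUPAC ambiguity codes (anything here is treated as missing by analyses).
AMBIGUITY_CODES = set("RYSWKMBDHVN")

#: Full accepted residue alphabet.
ALPHABET = set(BASES) | AMBIGUITY_CODES | {"-"}

_CODE = {b: i for i, b in enumerate(BASES)}

#: Integer code for gap/ambiguous (missing) residues.
MISSING = -1

METADATA_COLUMNS = ("sample_id", "species", "marker", "origin")


class AlignmentError(ValueError):
    """Sequences violate alignment invariants (length mismatch, bad residues)."""


class MetadataError(ValueError):
    """FASTA and metadata table disagree or the table is malformed."""


class InputError(ValueError):
    """Empty or structurally unusable input."""


@dataclass(frozen=True)
class SampleRecord:
    """One aligned sequence of one marker for one sampled individual."""

    sample_id: str
    species: str
    marker: str
    residues: str
    origin: str = ""

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise MetadataError("sample_id must be non-empty")
        residues = self.residues.upper()
        bad = set(residues) - ALPHABET
        if bad:
            raise AlignmentError(
                f"record {self.sample_id!r} contains non-IUPAC residues: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", residues)
        object.__setattr__(self, "species", " ".join(self.species.split()))

    def ungapped_length(self) -> int:
        """Length in bp excluding alignment gaps."""
        return len(self.residues) - self.residues.count("-")

    def encoded(self) -> np.ndarray:
        """Residues as int8: A=0, C=1, G=2, T=3, gap/ambiguity = -1."""
        return encode(self.residues)


def encode(residues: str) -> np.ndarray:
    out = np.full(len(residues), MISSING, dtype=np.int8)
    for i, ch in enumerate(residues):
        out[i] = _CODE.get(ch, MISSING)
    return out


@dataclass
class MarkerAlignment:
    """A species-annotated multiple sequence alignment for one marker."""

    marker: str
    records: list[SampleRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise InputError(
                f"alignment for marker {self.marker!r} needs >= 2 records, "
                f"got {len(self.records)}"
            )
        lengths = {len(r.residues) for r in self.records}
        if len(lengths) > 1:
            offenders = sorted(
                {r.sample_id: len(r.residues) for r in self.records}.items(),
                key=lambda kv: kv[1],
            )
            raise AlignmentError(
                f"unequal aligned lengths in marker {self.marker!r}: {offenders}"
            )
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise MetadataError(f"duplicate sample_ids in {self.marker!r}: {dupes}")

    @property
    def n_columns(self) -> int:
        return len(self.records[0].residues)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def species_set(self) -> set[str]:
        return set(self.species)

    def encoded_matrix(self) -> np.ndarray:
        """(n_records, n_columns) int8 matrix; missing residues are -1."""
        return np.vstack([r.encoded() for r in self.records])

    def record(self, sample_id: str) -> SampleRecord:
        for r in self.records:
            if r.sample_id == sample_id:
                return r
        raise KeyError(sample_id)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) with species labels.

    Undefined entries (saturated or zero-overlap pairs) are NaN; the diagonal
    is zero.  ``n_effective[i, j]`` is the number of comparable columns the
    (i, j) distance was computed from.
    """

    labels: list[str]
    species: list[str]
    values: np.ndarray
    n_effective: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.allclose(
            np.nan_to_num(self.values), np.nan_to_num(self.values.T), atol=0
        ):
            raise InputError("distance matrix is not symmetric")
        defined = ~np.isnan(self.values)
        if np.any(self.values[defined] < 0):
            raise InputError("negative distances")

    @property
    def n(self) -> int:
        return len(self.labels)

    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def is_fully_defined(self) -> bool:
        return self.n_undefined_pairs() == 0

    def submatrix(self, keep: Sequence[int]) -> "DistanceMatrix":
        keep = list(keep)
        return DistanceMatrix(
            labels=[self.labels[i] for i in keep],
            species=[self.species[i] for i in keep],
            values=self.values[np.ix_(keep, keep)],
            n_effective=self.n_effective[np.ix_(keep, keep)],
        )

    def to_long_df(self) -> pd.DataFrame:
        """Long format: one row per unordered pair (the inter-stage contract)."""
        rows = []
        for i in range(self.n):
            for j in range(i + 1, self.n):
                rows.append(
                    {
                        "sample_i": self.labels[i],
                        "sample_j": self.labels[j],
                        "species_i": self.species[i],
                        "species_j": self.species[j],
                        "n": int(self.n_effective[i, j]),
                        "d": self.values[i, j],
                    }
                )
        return pd.DataFrame(rows)

    def to_square_df(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# readers / writers


def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    """Read the sample-metadata TSV (columns sample_id, species, marker, origin)."""
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS[:3] if c not in meta.columns]
    if missing:
        raise MetadataError(f"metadata {metadata_path} lacks columns: {missing}")
    if "origin" not in meta.columns:
        meta["origin"] = ""
    return meta


def read_marker_alignment(
    fasta_path: str | Path,
    metadata_path: str | Path,
    marker: str,
) -> MarkerAlignment:
    """Read one marker's aligned FASTA and join it with the metadata table.

    FASTA record ids must appear in the metadata rows for ``marker``; file
    order is preserved.
    """
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not seqs:
        raise InputError(f"no FASTA records in {fasta_path}")
    meta = read_metadata(metadata_path)
    meta = meta[meta["marker"] == marker]
    by_id = {row.sample_id: row for row in meta.itertuples()}
    records = []
    for s in seqs:
        if s.id not in by_id:
            raise MetadataError(
                f"FASTA id {s.id!r} has no metadata row for marker {marker!r}"
            )
        row = by_id[s.id]
        records.append(
            SampleRecord(
                sample_id=s.id,
                species=row.species,
                marker=marker,
                residues=str(s.seq),
                origin=row.origin,
            )
        )
    return MarkerAlignment(marker=marker, records=records)


def write_marker_alignment(
    aln: MarkerAlignment,
    fasta_path: str | Path,
    metadata_path: str | Path | None = None,
) -> None:
    """Write aligned FASTA (and optionally a metadata TSV) for one marker."""
    seqs = [
        SeqRecord(Seq(r.residues), id=r.sample_id, description="")
        for r in aln.records
    ]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    if metadata_path is not None:
        pd.DataFrame(
            {
                "sample_id": aln.sample_ids,
                "species": aln.species,
                "marker": [aln.marker] * len(aln.records),
                "origin": [r.origin for r in aln.records],
            }
        ).to_csv(metadata_path, sep="\t", index=False)


def concatenate_markers(
    a: MarkerAlignment,
    b: MarkerAlignment,
    joined_name: str | None = None,
) -> MarkerAlignment:
    """Column-wise concatenation over the samples present in both markers.

    Samples sequenced for only one of the two markers are dropped (never
    padded) and logged; species labels are taken from the first input.
    """
    joined_name = joined_name or f"{a.marker}+{b.marker}"
    b_by_id = {r.sample_id: r for r in b.records}
    shared, dropped = [], []
    for r in a.records:
        if r.sample_id in b_by_id:
            shared.append(r)
        else:
            dropped.append(r.sample_id)
    dropped += [r.sample_id for r in b.records if r.sample_id not in
                {s.sample_id for s in shared}]
    if not shared:
        raise InputError(
            f"no shared samples between {a.marker!r} and {b.marker!r}"
        )
    if dropped:
        logger.warning(
            "concatenation %s: dropped %d samples missing one marker: %s",
            joined_name, len(dropped), sorted(set(dropped)),
        )
    records = [
        SampleRecord(
            sample_id=r.sample_id,
            species=r.species,
            marker=joined_name,
            residues=r.residues + b_by_id[r.sample_id].residues,
            origin=r.origin,
        )
        for r in shared
    ]
    return MarkerAlignment(marker=joined_name, records=records)


def subset_by_species(aln: MarkerAlignment, species: Iterable[str]) -> MarkerAlignment:
    wanted = set(species)
    recs = [r for r in aln.records if r.species in wanted]
    return MarkerAlignment(marker=aln.marker, records=recs)
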