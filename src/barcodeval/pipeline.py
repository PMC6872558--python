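"""End-to-end orchestration of the marker-evaluation pipeline.

``run_all`` executes, per marker and per configured concatenation:
sequence characteristics → K2P distances → divergence statistics →
barcoding-gap assessment → NJ tree with bootstrap support and monophyly
calls; then the cross-marker signed-rank comparisons and the interspecific
ranking.  All stage tables are written under the output directory and a
single machine-readable JSON summary ties them together.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import divergence as dv
from . import gap as gp
from . import njtree as nj
from . import site_stats as ss
from .k2p import k2p_matrix
from .seqdata import (
    InputError,
    MarkerAlignment,
    concatenate_markers,
    read_marker_alignment,
)

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    markers: list[dict]                      # [{"name": ..., "fasta": ...}, ...]
    metadata: str
    out_dir: str
    concatenations: list[tuple[str, str]] = field(default_factory=list)
    bootstrap_replicates: int = 1000
    seed: int = 0
    deletion: str = "pairwise"
    bin_width: float = gp.DEFAULT_BIN_WIDTH_PERCENT
    outgroup: str | None = None

    def __post_init__(self) -> None:
        names = {m["name"] for m in self.markers}
        for m in self.markers:
            if not Path(m["fasta"]).exists():
                raise InputError(f"FASTA not found for {m['name']}: {m['fasta']}")
        if not Path(self.metadata).exists():
            raise InputError(f"metadata not found: {self.metadata}")
        for a, b in self.concatenations:
            if a not in names or b not in names:
                raise InputError(
                    f"concatenation ({a}, {b}) references unknown markers"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            markers=raw["markers"],
            metadata=raw["metadata"],
            out_dir=raw["out_dir"],
            concatenations=[tuple(c) for c in raw.get("concatenations", [])],
            bootstrap_replicates=int(raw.get("bootstrap_replicates", 1000)),
            seed=int(raw.get("seed", 0)),
            deletion=raw.get("deletion", "pairwise"),
            bin_width=float(raw.get("bin_width", gp.DEFAULT_BIN_WIDTH_PERCENT)),
            outgroup=raw.get("outgroup"),
        )


def _round(x, nd=10):
    if isinstance(x, float):
        return round(x, nd)
    return x


def evaluate_marker(
    aln: MarkerAlignment,
    bootstrap_replicates: int,
    seed: int,
    deletion: str = "pairwise",
    bin_width: float = gp.DEFAULT_BIN_WIDTH_PERCENT,
) -> dict:
    """Run every per-marker stage; returns the stage objects keyed by name."""
    chars = ss.sequence_characteristics(aln)
    dm = k2p_matrix(aln, deletion=deletion)
    summary = dv.divergence_summary(dm, marker=aln.marker)
    profile = gp.gap_profile(dm, bin_width=bin_width, marker=aln.marker)
    tree = nj.bootstrap_support(
        aln, replicates=bootstrap_replicates, seed=seed, deletion=deletion
    )
    calls = nj.monophyly(tree, dict(zip(aln.sample_ids, aln.species)))
    return {
        "alignment": aln,
        "characteristics": chars,
        "distance_matrix": dm,
        "divergence": summary,
        "gap": profile,
        "tree": tree,
        "monophyly": calls,
    }


def _marker_block(r: dict) -> dict:
    chars: ss.SequenceCharacteristics = r["characteristics"]
    cls = chars.classification
    summary: dv.DivergenceSummary = r["divergence"]
    profile: gp.GapProfile = r["gap"]
    return {
        "characteristics": {
            "n_samples": len(r["alignment"].records),
            "n_species": len(r["alignment"].species_set()),
            "alignment_length": cls.alignment_length,
            "sequence_length_range": list(chars.length_range),
            "gc_percent_range": [_round(x, 4) for x in chars.gc_range],
            "conserved_sites": cls.conserved_sites,
            "variable_sites": cls.variable_sites,
            "informative_sites": cls.informative_sites,
            "gap_containing_sites": cls.gap_containing_sites,
            "aberration_rate_percent": _round(cls.aberration_rate_percent, 4),
            "mean_pairwise_similarity_percent": _round(
                chars.mean_pairwise_similarity_percent, 4
            ),
        },
        "divergence": {
            row: {
                "mean": _round(getattr(summary, row).mean),
                "sd": _round(getattr(summary, row).sd),
                "se": _round(getattr(summary, row).se),
            }
            for row in dv.STATISTIC_ROWS
        },
        "gap": {
            "gap_present": profile.gap_present,
            "max_intra_percent": _round(100 * profile.max_intra, 6),
            "min_inter_percent": _round(100 * profile.min_inter, 6),
            "gap_interval_percent": (
                [_round(x, 6) for x in profile.gap_interval_percent]
                if profile.gap_present else None
            ),
            "overlap_fraction": _round(profile.overlap_fraction, 6),
        },
        "tree": {
            "newick": r["tree"].newick(),
            "monophyly": [
                {
                    "species": c.species,
                    "monophyletic": c.monophyletic,
                    "trivial": c.trivial,
                    "n_leaves": c.n_leaves,
                    "support": _round(c.support, 2) if c.support is not None
                    else None,
                }
                for c in r["monophyly"]
            ],
        },
    }


def run_all(cfg: PipelineConfig) -> dict:
    """Run the whole evaluation; writes stage TSVs plus summary.json."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    alignments: dict[str, MarkerAlignment] = {}
    for m in cfg.markers:
        alignments[m["name"]] = read_marker_alignment(
            m["fasta"], cfg.metadata, m["name"]
        )
    for a, b in cfg.concatenations:
        joined = concatenate_markers(alignments[a], alignments[b])
        alignments[joined.marker] = joined

    results: dict[str, dict] = {}
    for idx, (name, aln) in enumerate(alignments.items()):
        logger.info("evaluating marker %s (%d samples, %d columns)",
                    name, len(aln.records), aln.n_columns)
        try:
            results[name] = evaluate_marker(
                aln,
                bootstrap_replicates=cfg.bootstrap_replicates,
                seed=cfg.seed + idx,
                deletion=cfg.deletion,
                bin_width=cfg.bin_width,
            )
        except Exception as exc:
            raise RuntimeError(f"stage failure on marker {name!r}: {exc}") from exc
        _write_marker_outputs(results[name], out, name)

    long_tables = {n: r["distance_matrix"].to_long_df() for n, r in results.items()}
    tests = dv.compare_markers(long_tables)
    summaries = [r["divergence"] for r in results.values()]
    ranking = dv.rank_markers(summaries, tests) if len(summaries) >= 2 else []
    report = gp.gap_report([r["gap"] for r in results.values()])
    report.to_csv(out / "gap_report.tsv", sep="\t", index=False)
    dv.summaries_table(summaries).to_csv(out / "divergence_table.tsv", sep="\t")

    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": cfg.seed,
        "deletion": cfg.deletion,
        "bootstrap_replicates": cfg.bootstrap_replicates,
        "markers": {name: _marker_block(r) for name, r in results.items()},
        "ranking": [
            {k: _round(v) for k, v in entry.items()} for entry in ranking
        ],
        "rank_tests": [
            {
                "marker_a": t.marker_a, "marker_b": t.marker_b,
                "W": t.W, "n_pairs": t.n_pairs,
                "p_value": _round(t.p_value), "method": t.method,
            }
            for t in tests
        ],
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _write_marker_outputs(r: dict, out: Path, name: str) -> None:
    safe = name.replace("/", "_")
    dm = r["distance_matrix"]
    dm.to_square_df().to_csv(out / f"{safe}.dist.tsv", sep="\t")
    dm.to_long_df().to_csv(out / f"{safe}.dist_long.tsv", sep="\t", index=False)
    gp.histogram_table(r["gap"]).to_csv(
        out / f"{safe}.gap_hist.tsv", sep="\t", index=False
    )
    (out / f"{safe}.nwk").write_text(r["tree"].newick() + "\n")
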