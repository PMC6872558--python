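"""Synthetic multi-marker barcode datasets with known truth.

The generator emulates the structure of a small-genus barcoding study: a
handful of closely related species (2-6), uneven sampling dominated by one
heavily collected species, and several markers that share the species history
but differ in length, base composition, substitution rate, and indel load.

Sequences evolve down a user-supplied species tree (Newick, branch lengths in
expected substitutions/site) under the two-rate Kimura substitution process —
transitions occur ``kappa`` times faster than each transversion — scaled per
marker by ``rate_multiplier``.  Within a species, individuals radiate as a
star from the species ancestor: each individual's private branch is half of
``intraspecific_scale × terminal branch``, so the expected distance between
two conspecific individuals is ``intraspecific_scale × terminal branch``
(times the marker's rate multiplier).  Base composition is set by the root
frequencies only (the Kimura process itself is composition-neutral).  Indels
are whole-column gap events hitting a random subset of sequences.

Every dataset comes with a :class:`TruthTable` holding the exact expected
inter- and intraspecific divergences per marker, the generating topology, the
expected gap verdicts, and the planted monophyly — the reference downstream
stages are tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from .seqdata import BASES, MarkerAlignment, SampleRecord, write_marker_alignment


class ConfigError(ValueError):
    """Simulation configuration is invalid or unparseable."""


@dataclass(frozen=True)
class MarkerConfig:
    name: str
    n_columns: int
    rate_multiplier: float
    kappa: float = 2.0          # transition/transversion rate ratio (alpha/beta)
    gc_target: float = 50.0     # percent, root composition
    indel_rate: float = 0.0     # per-column probability of a gap event

    def __post_init__(self) -> None:
        if self.n_columns < 1 or self.rate_multiplier < 0 or self.kappa <= 0:
            raise ConfigError(f"invalid marker config for {self.name!r}")
        if not 0.0 < self.gc_target < 100.0:
            raise ConfigError(f"gc_target for {self.name!r} must be in (0, 100)")
        if not 0.0 <= self.indel_rate <= 1.0:
            raise ConfigError(f"indel_rate for {self.name!r} must be in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    species_tree: str                      # Newick with branch lengths
    n_individuals: dict[str, int]          # species -> sample count
    markers: tuple[MarkerConfig, ...]
    intraspecific_scale: float = 0.0       # within-species divergence as a
                                           # fraction of the terminal branch

    def __post_init__(self) -> None:
        if self.intraspecific_scale < 0:
            raise ConfigError("intraspecific_scale must be >= 0")
        for sp, n in self.n_individuals.items():
            if n < 1:
                raise ConfigError(f"n_individuals[{sp!r}] must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            markers = tuple(MarkerConfig(**m) for m in raw["markers"])
            return cls(
                seed=int(raw["seed"]),
                species_tree=raw["species_tree"],
                n_individuals={k: int(v) for k, v in raw["n_individuals"].items()},
                markers=markers,
                intraspecific_scale=float(raw.get("intraspecific_scale", 0.0)),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"bad simulation config {path}: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "seed": self.seed,
            "species_tree": self.species_tree,
            "n_individuals": dict(self.n_individuals),
            "intraspecific_scale": self.intraspecific_scale,
            "markers": [vars(m) for m in self.markers],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


@dataclass(frozen=True)
class MarkerTruth:
    marker: str
    expected_inter_mean: float      # mean over heterospecific individual pairs
    expected_intra_mean: float      # mean over conspecific individual pairs
    expected_min_inter: float       # smallest expected heterospecific distance
    expected_max_intra: float       # largest expected conspecific distance
    gap_expected: bool


@dataclass(frozen=True)
class TruthTable:
    topology: str                           # generating species tree (Newick)
    species: tuple[str, ...]
    monophyly: dict[str, bool]              # planted truth (star model: all True)
    markers: dict[str, MarkerTruth]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.markers.values()])


# ---------------------------------------------------------------------------
# the substitution process (two-rate Kimura / K80)


def _k80_rates(kappa: float) -> tuple[float, float]:
    """(alpha, beta) normalised so the expected substitution rate is 1."""
    beta = 1.0 / (kappa + 2.0)
    return kappa * beta, beta


def k80_transition_probs(t: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch length t."""
    alpha, beta = _k80_rates(kappa)
    e4 = math.exp(-4.0 * beta * t)
    e2 = math.exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e4 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e4 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e4
    return p_same, p_ts, p_tv


def _evolve(seq: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence along a branch of length t substitutions/site."""
    if t <= 0.0:
        return seq.copy()
    p_same, p_ts, _ = k80_transition_probs(t, kappa)
    u = rng.random(seq.size)
    out = seq.copy()
    ts = (u >= p_same) & (u < p_same + p_ts)
    tv = u >= p_same + p_ts
    # coding A=0,C=1,G=2,T=3: transition partner is base XOR 2;
    # the two transversion targets are base XOR 1 and base XOR 3.
    out[ts] ^= 2
    which = rng.integers(0, 2, size=int(tv.sum()))
    out[tv] = np.where(which == 0, seq[tv] ^ 1, seq[tv] ^ 3)
    return out


def _root_sequence(n_columns: int, gc_target: float,
                   rng: np.random.Generator) -> np.ndarray:
    g = gc_target / 100.0
    pi = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])  # A, C, G, T
    return rng.choice(4, size=n_columns, p=pi).astype(np.int8)


# ---------------------------------------------------------------------------
# dataset generation


def _parse_tree(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ConfigError(f"unparseable species tree: {exc}") from exc
    for leaf in tree.leaf_node_iter():
        if leaf.edge.length is None:
            raise ConfigError("species tree must have branch lengths")
    return tree


def _species_paths(tree: dendropy.Tree) -> tuple[list[str], dict, dict]:
    """(species, terminal branch lengths, patristic path lengths per pair)."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    species = sorted(taxa)
    terminal = {
        leaf.taxon.label: float(leaf.edge.length)
        for leaf in tree.leaf_node_iter()
    }
    paths = {}
    for i, a in enumerate(species):
        for b in species[i + 1:]:
            paths[(a, b)] = float(pdm.patristic_distance(taxa[a], taxa[b]))
    return species, terminal, paths


def _sanitize(name: str) -> str:
    return name.replace(" ", "_")


def simulate_dataset(
    cfg: SimulationConfig,
) -> tuple[dict[str, MarkerAlignment], TruthTable]:
    """Generate aligned sequences for every marker plus the truth table."""
    tree = _parse_tree(cfg.species_tree)
    species, terminal, paths = _species_paths(tree)
    unknown = set(cfg.n_individuals) - set(species)
    if unknown:
        raise ConfigError(f"n_individuals names species not in tree: {sorted(unknown)}")
    sampled = [sp for sp in species if cfg.n_individuals.get(sp, 0) >= 1]
    # per-species private branch of each individual (species-tree scale)
    t_ind = {sp: 0.5 * cfg.intraspecific_scale * terminal[sp] for sp in sampled}

    seed_seqs = np.random.SeedSequence(cfg.seed).spawn(len(cfg.markers))
    alignments: dict[str, MarkerAlignment] = {}
    truths: dict[str, MarkerTruth] = {}
    for mcfg, sseq in zip(cfg.markers, seed_seqs):
        rng = np.random.default_rng(sseq)
        aln = _simulate_marker(mcfg, tree, sampled, cfg.n_individuals, t_ind, rng)
        alignments[mcfg.name] = aln
        truths[mcfg.name] = _marker_truth(
            mcfg, sampled, cfg.n_individuals, t_ind, paths
        )
    truth = TruthTable(
        topology=cfg.species_tree.strip(),
        species=tuple(sampled),
        monophyly={sp: True for sp in sampled},
        markers=truths,
    )
    return alignments, truth


def _simulate_marker(mcfg, tree, sampled, n_individuals, t_ind, rng):
    root_seq = _root_sequence(mcfg.n_columns, mcfg.gc_target, rng)
    tip_seqs: dict[str, np.ndarray] = {}

    def descend(node, seq):
        for child in node.child_nodes():
            t = float(child.edge.length or 0.0) * mcfg.rate_multiplier
            child_seq = _evolve(seq, t, mcfg.kappa, rng)
            if child.is_leaf():
                tip_seqs[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    start = tree.seed_node
    if start.is_leaf():  # single-species tree
        tip_seqs[start.taxon.label] = root_seq
    else:
        descend(start, root_seq)

    records = []
    for sp in sampled:
        t = t_ind[sp] * mcfg.rate_multiplier
        for k in range(n_individuals[sp]):
            seq = _evolve(tip_seqs[sp], t, mcfg.kappa, rng)
            records.append((f"{_sanitize(sp)}_{k + 1:02d}", sp, seq))

    mat = np.vstack([seq for _, _, seq in records])
    residues = _with_indels(mat, mcfg.indel_rate, rng)
    return MarkerAlignment(
        marker=mcfg.name,
        records=[
            SampleRecord(sample_id=sid, species=sp, marker=mcfg.name,
                         residues=res)
            for (sid, sp, _), res in zip(records, residues)
        ],
    )


def _with_indels(mat: np.ndarray, indel_rate: float,
                 rng: np.random.Generator) -> list[str]:
    n, L = mat.shape
    gapped = np.zeros((n, L), dtype=bool)
    if indel_rate > 0:
        cols = np.where(rng.random(L) < indel_rate)[0]
        for c in cols:
            hit = rng.random(n) < 0.5
            if not hit.any():
                hit[rng.integers(0, n)] = True
            gapped[hit, c] = True
    out = []
    lut = np.array(list(BASES))
    for i in range(n):
        chars = lut[mat[i]]
        chars[gapped[i]] = "-"
        out.append("".join(chars))
    return out


def _marker_truth(mcfg, sampled, n_individuals, t_ind, paths) -> MarkerTruth:
    r = mcfg.rate_multiplier
    inter_vals, inter_weights = [], []
    for (a, b), path in paths.items():
        if a in sampled and b in sampled:
            inter_vals.append(r * (path + t_ind[a] + t_ind[b]))
            inter_weights.append(n_individuals[a] * n_individuals[b])
    intra_vals, intra_weights = [], []
    for sp in sampled:
        n = n_individuals[sp]
        if n >= 2:
            intra_vals.append(r * 2.0 * t_ind[sp])
            intra_weights.append(n * (n - 1) // 2)
    inter_mean = (
        float(np.average(inter_vals, weights=inter_weights))
        if inter_vals else math.nan
    )
    intra_mean = (
        float(np.average(intra_vals, weights=intra_weights))
        if intra_vals else math.nan
    )
    min_inter = min(inter_vals) if inter_vals else math.nan
    max_intra = max(intra_vals) if intra_vals else math.nan
    gap_expected = bool(inter_vals and intra_vals and min_inter > max_intra)
    return MarkerTruth(
        marker=mcfg.name,
        expected_inter_mean=inter_mean,
        expected_intra_mean=intra_mean,
        expected_min_inter=min_inter,
        expected_max_intra=max_intra,
        gap_expected=gap_expected,
    )


def write_dataset(
    alignments: dict[str, MarkerAlignment],
    truth: TruthTable,
    out_dir: str | Path,
) -> None:
    """Write per-marker FASTA, a joint metadata TSV, and the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for name, aln in alignments.items():
        write_marker_alignment(aln, out / f"{name}.fasta")
        for rec in aln.records:
            meta_rows.append(
                {"sample_id": rec.sample_id, "species": rec.species,
                 "marker": name, "origin": rec.origin}
            )
    pd.DataFrame(meta_rows).to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    (out / "species_tree.nwk").write_text(truth.topology + "\n")


# ---------------------------------------------------------------------------
# the default study emulation


#: Six congeneric species; three cherry pairs, equal tip depths.  All
#: heterospecific tip paths are 0.6 (within a pair) or 1.0 (across pairs);
#: the weighted mean heterospecific path is close to 1, so a marker's
#: rate_multiplier is, to first order, its expected interspecific divergence.
REFERENCE_SPECIES_TREE = (
    "((R_glutinosa:0.3,R_solanifolia:0.3):0.2,"
    "(R_piasezkii:0.3,R_elata:0.3):0.2,"
    "(R_chingii:0.3,R_henryi:0.3):0.2);"
)

#: Sampling skewed toward one heavily collected species, as in cultivar
#: panels of a medicinal plant.
REFERENCE_SAMPLING = {
    "R_glutinosa": 20,
    "R_solanifolia": 2,
    "R_piasezkii": 3,
    "R_elata": 2,
    "R_chingii": 2,
    "R_henryi": 3,
}

#: Marker profiles: alignment length and GC set to the ranges typical of the
#: five classic plant barcodes; rate multipliers planted in the order
#: ITS2 > ITS > psbA-trnH > matK > rbcL with interspecific divergences at the
#: levels such studies report (0.027 down to 0.001 substitutions/site).
REFERENCE_MARKERS = (
    MarkerConfig("ITS", 610, rate_multiplier=0.0160, kappa=4.0, gc_target=61.3),
    MarkerConfig("ITS2", 225, rate_multiplier=0.0250, kappa=4.0, gc_target=65.4),
    MarkerConfig("rbcL", 1287, rate_multiplier=0.0009, kappa=2.0, gc_target=43.6),
    MarkerConfig("matK", 1560, rate_multiplier=0.0019, kappa=2.0, gc_target=33.4,
                 indel_rate=0.015),
    MarkerConfig("psbA-trnH", 497, rate_multiplier=0.0085, kappa=2.0,
                 gc_target=26.9, indel_rate=0.02),
)


def reference_config(seed: int = 0) -> SimulationConfig:
    """The default synthetic study: 6 species, 32 samples, 5 markers."""
    return SimulationConfig(
        seed=seed,
        species_tree=REFERENCE_SPECIES_TREE,
        n_individuals=dict(REFERENCE_SAMPLING),
        markers=REFERENCE_MARKERS,
        intraspecific_scale=0.75,
    )


#: Markers for the planted-ranking experiment.  Same lengths as the reference
#: profiles, but adjacent rate multipliers spaced so every marker accrues
#: enough expected substitutions tree-wide (n_i ≈ 2.4 · rate · length) that a
#: single dataset realisation orders adjacent markers correctly with high
#: probability: log(rate ratio) > 2.6 · sqrt(1/n_i + 1/n_j).  At realistic
#: (much smaller) rate magnitudes the slowest markers yield only a handful of
#: substitutions and their realised ranking is close to a coin flip.
RANKING_MARKERS = (
    MarkerConfig("ITS", 610, rate_multiplier=0.144, kappa=4.0, gc_target=61.3),
    MarkerConfig("ITS2", 225, rate_multiplier=0.30, kappa=4.0, gc_target=65.4),
    MarkerConfig("rbcL", 1287, rate_multiplier=0.004, kappa=2.0, gc_target=43.6),
    MarkerConfig("matK", 1560, rate_multiplier=0.016, kappa=2.0, gc_target=33.4),
    MarkerConfig("psbA-trnH", 497, rate_multiplier=0.048, kappa=2.0,
                 gc_target=26.9),
)


def ranking_config(seed: int = 0) -> SimulationConfig:
    """Planted-ordering dataset: rates in the order ITS2 > ITS > psbA-trnH >
    matK > rbcL, separated widely enough to be recoverable per dataset."""
    return SimulationConfig(
        seed=seed,
        species_tree=REFERENCE_SPECIES_TREE,
        n_individuals=dict(REFERENCE_SAMPLING),
        markers=RANKING_MARKERS,
        intraspecific_scale=0.3,
    )
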