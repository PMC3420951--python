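"""Aligned ITS-like datasets with a planted species partition.

The generator emulates the statistical shape of a barcode database for
culture-collection strains: ~550-column aligned sequences, conspecific
divergence well under the 2% species cutoff, heterospecific divergence
an order of magnitude larger, near-identical rDNA paralogue copies per
strain, and optional injected anomalies (mislabelled strains, declared
synonym twins, alignment gaps).

Divergence targets are *expected p-distances*, not substitution rates.
Each lineage applies one round of per-site replacement with probability
q, substituting to a uniformly random different base; two lineages
derived independently from a common ancestor then differ per site with
probability 2q - (4/3)q^2, and q is solved from that closed form so the
realised pairwise p-distance matches the target in expectation despite
multiple hits (valid for targets <= 0.75, accurate within Monte-Carlo
noise below ~0.3; above that, saturation flattens the response).

The species "tree" is a star by default — all species ancestors
equidistant from a single root — which keeps the inter-species target
exactly interpretable; ``species_tree='random'`` instead evolves the
ancestors down a random bifurcating tree for NJ-recovery exercises (the
inter target then holds on average, not per pair).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .seqio import (
    Alignment,
    CloneGroupTable,
    SequenceRecord,
    StrainRow,
    StrainTable,
    write_clone_groups,
    write_fasta,
    write_strain_table,
)

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulationResult",
    "simulate",
    "make_fixture",
    "PRESETS",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for one synthetic dataset; every field has a dataset-shape meaning.

    Defaults mirror a realistic barcode study: 550-column alignments,
    1% conspecific divergence, 20% heterospecific divergence, 0.5%
    intragenomic paralogue divergence, no anomalies.
    """

    n_species: int = 5
    strains_per_species: int | tuple[int, ...] = 4
    seq_length: int = 550
    intra_divergence: float = 0.01
    inter_divergence: float = 0.20
    paralogues_per_strain: int = 1
    paralogue_divergence: float = 0.005
    mislabel_rate: float = 0.0
    synonym_pairs: int = 0
    gap_rate: float = 0.0
    species_tree: str = "star"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1 or self.seq_length < 1:
            raise ValueError("n_species and seq_length must be positive")
        if not 0.0 <= self.intra_divergence < self.inter_divergence <= 0.75:
            raise ValueError(
                "need 0 <= intra_divergence < inter_divergence <= 0.75 "
                f"(got {self.intra_divergence}, {self.inter_divergence})"
            )
        for name in ("paralogue_divergence", "mislabel_rate", "gap_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.paralogue_divergence > 0.75:
            raise ValueError("paralogue_divergence saturates above 0.75")
        if self.paralogues_per_strain < 1 or self.synonym_pairs < 0:
            raise ValueError("paralogues_per_strain >= 1, synonym_pairs >= 0")
        if self.species_tree not in ("star", "random"):
            raise ValueError("species_tree must be 'star' or 'random'")
        if self.mislabel_rate > 0 and self.n_species < 2:
            raise ValueError("mislabelling needs at least 2 species")

    def strains_for(self, species_idx: int) -> int:
        if isinstance(self.strains_per_species, int):
            return self.strains_per_species
        return self.strains_per_species[species_idx]


def substitution_probability(target_p: float) -> float:
    """Per-lineage replacement probability q with E[p-distance] = target.

    Two sequences independently derived from a common ancestor, each by
    one round of per-site replacement to a uniformly random different
    base with probability q, differ per site with probability
    2q - (4/3)q^2; invert that for q.
    """
    if not 0.0 <= target_p <= 0.75:
        raise ValueError("expected p-distance must be in [0, 0.75]")
    # (4/3) q^2 - 2 q + p = 0, smaller root
    return (2.0 - math.sqrt(4.0 - (16.0 / 3.0) * target_p)) / (8.0 / 3.0)


def _mutate(rng: np.random.Generator, seq: np.ndarray, q: float) -> np.ndarray:
    """One round of per-site replacement with probability q (indexes 0..3)."""
    out = seq.copy()
    hit = rng.random(seq.size) < q
    n_hit = int(hit.sum())
    if n_hit:
        # uniform over the 3 *other* bases
        out[hit] = (seq[hit] + rng.integers(1, 4, size=n_hit)) % 4
    return out


@dataclass
class TruthTable:
    """Ground truth for every emitted record."""

    #: record id -> {"species", "parent_strain", "anomaly"}
    records: dict[str, dict[str, str]]

    def partition(self) -> dict[str, list[str]]:
        """True species -> record ids, in emission order."""
        out: dict[str, list[str]] = {}
        for rid, info in self.records.items():
            out.setdefault(info["species"], []).append(rid)
        return out

    def anomalies(self, kind: str) -> list[str]:
        return [r for r, info in self.records.items() if info["anomaly"] == kind]

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.records, fh, indent=1, sort_keys=True)


@dataclass
class SimulationResult:
    alignment: Alignment
    strain_table: StrainTable
    clone_groups: CloneGroupTable
    truth: TruthTable
    config: SimulationConfig


def _species_step_probability(cfg: SimulationConfig) -> float:
    """Per-lineage replacement probability for the root -> species step.

    Substitution rounds compose multiplicatively in the decay factor
    lambda = 1 - (4/3) q, and two leaves differ per site with
    probability (3/4)(1 - lambda_path).  The species step is solved so
    that the *leaf-to-leaf* inter-species distance — which also crosses
    two strain-level steps — hits the configured target in expectation
    (exact under the star model).
    """
    lam_target = 1.0 - (4.0 / 3.0) * cfg.inter_divergence
    lam_intra_pair = 1.0 - (4.0 / 3.0) * cfg.intra_divergence
    lam_step = math.sqrt(lam_target / lam_intra_pair)
    return 3.0 * (1.0 - lam_step) / 4.0


def _random_species_ancestors(
    rng: np.random.Generator, root: np.ndarray, cfg: SimulationConfig
) -> list[np.ndarray]:
    """Species ancestor sequences under the star or random-tree model."""
    q_half = _species_step_probability(cfg)
    if cfg.species_tree == "star" or cfg.n_species <= 2:
        return [_mutate(rng, root, q_half) for _ in range(cfg.n_species)]
    # random bifurcating tree: start from 2 lineages, split a random one
    # at each step; each split applies an extra half-step of divergence.
    lineages = [_mutate(rng, root, q_half), _mutate(rng, root, q_half)]
    while len(lineages) < cfg.n_species:
        idx = int(rng.integers(len(lineages)))
        parent = lineages.pop(idx)
        q_step = q_half * float(rng.uniform(0.3, 1.0))
        lineages.append(_mutate(rng, parent, q_step))
        lineages.append(_mutate(rng, parent, q_step))
    rng.shuffle(lineages)  # type: ignore[arg-type]
    return lineages


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate an aligned dataset with known species structure.

    Fully deterministic given ``config.seed``: identical configs yield
    byte-identical FASTA/tables/truth.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    root = rng.integers(0, 4, size=cfg.seq_length)
    ancestors = _random_species_ancestors(rng, root, cfg)
    q_intra = substitution_probability(cfg.intra_divergence)
    q_para = substitution_probability(cfg.paralogue_divergence)

    species_names = [f"Dinospecies synthetica{i + 1}" for i in range(cfg.n_species)]
    genus = "Dinospecies"

    records: list[tuple[str, np.ndarray]] = []
    strain_rows: list[StrainRow] = []
    truth: dict[str, dict[str, str]] = {}
    clone_map: dict[str, list[str]] = {}
    strain_species: list[tuple[str, int]] = []

    for s, anc in enumerate(ancestors):
        for t in range(cfg.strains_for(s)):
            sid = f"SYN{s + 1:03d}-{t + 1:02d}"
            strain_seq = _mutate(rng, anc, q_intra)
            strain_species.append((sid, s))
            if cfg.paralogues_per_strain == 1:
                records.append((sid, strain_seq))
                truth[sid] = {
                    "species": species_names[s], "parent_strain": sid, "anomaly": "none",
                }
            else:
                clones = []
                for k in range(cfg.paralogues_per_strain):
                    cid = f"{sid}.c{k + 1}"
                    records.append((cid, _mutate(rng, strain_seq, q_para)))
                    truth[cid] = {
                        "species": species_names[s], "parent_strain": sid, "anomaly": "none",
                    }
                    clones.append(cid)
                clone_map[sid] = clones

    # Mislabels: with probability mislabel_rate a strain's given name is
    # swapped for a uniformly random *other* species' name.
    given: dict[str, str] = {sid: species_names[s] for sid, s in strain_species}
    for sid, s in strain_species:
        if cfg.mislabel_rate and rng.random() < cfg.mislabel_rate:
            other = int(rng.integers(cfg.n_species - 1))
            if other >= s:
                other += 1
            given[sid] = species_names[other]
            for rid, info in truth.items():
                if info["parent_strain"] == sid:
                    info["anomaly"] = "mislabel"

    # Synonym twins: duplicate a strain's (first) record verbatim under a
    # new id and declare the synonymy in the metadata.
    twin_of: dict[str, str] = {}
    if cfg.synonym_pairs:
        candidates = [sid for sid, _ in strain_species]
        chosen = rng.choice(len(candidates), size=min(cfg.synonym_pairs, len(candidates)),
                            replace=False)
        for idx in sorted(int(i) for i in chosen):
            sid = candidates[idx]
            twin = f"{sid}-DUP"
            src = next(seq for rid, seq in records if truth[rid]["parent_strain"] == sid)
            records.append((twin, src.copy()))
            truth[twin] = {
                "species": truth_species(truth, sid), "parent_strain": twin,
                "anomaly": "synonym_twin",
            }
            twin_of[twin] = sid
            given[twin] = given[sid]

    # Optional alignment gaps: per column, with probability gap_rate, one
    # random record receives a '-' (exercises column masking downstream).
    seq_matrix = np.stack([seq for _, seq in records])
    gap_mask = np.zeros(seq_matrix.shape, dtype=bool)
    if cfg.gap_rate:
        for col in range(cfg.seq_length):
            if rng.random() < cfg.gap_rate:
                gap_mask[int(rng.integers(len(records))), col] = True

    seq_records = []
    for (rid, _), row_idx in zip(records, range(len(records))):
        chars = _BASES[seq_matrix[row_idx]].tobytes().decode("ascii")
        if cfg.gap_rate:
            chars = "".join(
                "-" if gap_mask[row_idx, col] else ch for col, ch in enumerate(chars)
            )
        parent = truth[rid]["parent_strain"]
        seq_records.append(
            SequenceRecord(id=rid, sequence=chars, taxon_label=given.get(parent, ""))
        )
    alignment = Alignment.from_records(seq_records)

    for sid, s in strain_species:
        syns = tuple(t for t, orig in twin_of.items() if orig == sid)
        strain_rows.append(
            StrainRow(
                strain_id=sid, given_species=given[sid], genus=genus,
                collection="SYNTH", synonyms=syns, status="barcoded",
            )
        )
    for twin, orig in twin_of.items():
        strain_rows.append(
            StrainRow(
                strain_id=twin, given_species=given[twin], genus=genus,
                collection="SYNTH-DUP", synonyms=(orig,), status="barcoded",
            )
        )

    return SimulationResult(
        alignment=alignment,
        strain_table=StrainTable(strain_rows),
        clone_groups=CloneGroupTable(clone_map),
        truth=TruthTable(records=truth),
        config=cfg,
    )


def truth_species(truth: dict[str, dict[str, str]], parent: str) -> str:
    for info in truth.values():
        if info["parent_strain"] == parent:
            return info["species"]
    raise KeyError(parent)


#: Named desk-scale dataset presets.  "database_scale" emulates a full barcode
#: database: 78 species analogues at database-scale strain counts scaled
#: to desk size, 28.7% mean heterospecific divergence, declared synonym
#: twins for the concordance check.
PRESETS: dict[str, SimulationConfig] = {
    "small": SimulationConfig(n_species=3, strains_per_species=3, seed=101),
    "database_scale": SimulationConfig(
        n_species=78, strains_per_species=2, inter_divergence=0.287,
        synonym_pairs=4, seed=202,
    ),
    "paralogue_heavy": SimulationConfig(
        n_species=6, strains_per_species=2, paralogues_per_strain=5,
        paralogue_divergence=0.005, seed=303,
    ),
    "mislabelled": SimulationConfig(
        n_species=8, strains_per_species=3, mislabel_rate=0.1, seed=404,
    ),
}


def make_fixture(name: str, out_dir: str | Path) -> dict[str, Path]:
    """Write a named preset dataset (FASTA + tables + truth JSON) to disk.

    Re-running the same preset produces byte-identical files (the seed
    is part of the preset).
    """
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = simulate(PRESETS[name])
    paths = {
        "fasta": out_dir / "alignment.fasta",
        "strains": out_dir / "strains.tsv",
        "clones": out_dir / "clones.tsv",
        "truth": out_dir / "truth.json",
        "config": out_dir / "config.json",
    }
    write_fasta(result.alignment, paths["fasta"])
    write_strain_table(result.strain_table, paths["strains"])
    write_clone_groups(result.clone_groups, paths["clones"])
    result.truth.to_json(paths["truth"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(result.config), fh, indent=1, sort_keys=True)
    return paths
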