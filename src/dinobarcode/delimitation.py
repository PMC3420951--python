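"""Distance-threshold species delimitation and the naming/QC rules.

Strains are clustered into barcode species groups by single linkage at
a pairwise-distance cutoff theta (2% by default): two strains share a
group when they are connected by a chain of pairs each within theta.
Groups are then labelled:

1. a group with at least one named member takes the majority given
   species name (``confirmed_species``); differently-named members are
   flagged as mismatches;
2. a group of two or more wholly unnamed strains becomes
   "<Genus> group <n>" (``new_group``) and its members are flagged
   newly identified;
3. a singleton with no neighbour within theta is ``undetermined``; its
   given name, if any, is retained;
4. groups whose members belong to a declared species complex are
   labelled "<Complex> <RomanNumeral>" in discovery order
   (``complex_subgroup``);
5. a given species name that spans several groups marks cryptic
   variation: those groups are relabelled "<name> group <k>" and every
   strain carrying the name is cryptic-flagged (complex subgroups are
   exempt — complexes are known, not cryptic).

Single-linkage chaining can join strains whose mutual distance exceeds
theta; such within-group pairs are surfaced in the report rather than
silently accepted or split.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distance import DistanceMatrix
from .seqio import StrainTable

__all__ = [
    "DelimitationConfig",
    "SpeciesGroup",
    "StrainAssignment",
    "DelimitationResult",
    "SynonymCheck",
    "cluster_species",
    "assign_labels",
    "check_synonyms",
    "roman",
]


@dataclass(frozen=True)
class DelimitationConfig:
    """Tuning knobs for delimitation.

    theta
        Species cutoff as a fraction (default 0.02, i.e. 2% divergence).
    strict_threshold
        If True the comparison is exclusive (< theta) instead of the
        default inclusive (<= theta, "2% or less").
    identity_tol
        Distance at or below which two sequences count as identical for
        synonym checking (default 0.0).
    complex_labels
        Enable Roman-numeral labelling of groups inside declared
        species complexes.
    """

    theta: float = 0.02
    strict_threshold: bool = False
    identity_tol: float = 0.0
    complex_labels: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.theta < 1.0:
            raise ValueError(f"theta must be in (0, 1), got {self.theta}")
        if self.identity_tol < 0:
            raise ValueError("identity_tol must be >= 0")

    def conspecific(self, d: float) -> bool:
        return d < self.theta if self.strict_threshold else d <= self.theta


@dataclass
class SpeciesGroup:
    group_id: int
    members: tuple[str, ...]
    assigned_label: str = ""
    label_kind: str = ""  # confirmed_species | new_group | complex_subgroup | undetermined
    name_conflicts: tuple[str, ...] = ()


@dataclass
class StrainAssignment:
    strain_id: str
    given_species: str
    assigned_label: str
    group_id: int
    mismatch: bool = False
    cryptic: bool = False
    newly_identified: bool = False


@dataclass
class DelimitationResult:
    groups: list[SpeciesGroup]
    assignments: list[StrainAssignment]
    #: within-group pairs whose mutual distance exceeds theta (chaining)
    chained_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def assignment_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.assignments])

    def group_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "group_id": g.group_id,
                    "label": g.assigned_label,
                    "kind": g.label_kind,
                    "n_members": len(g.members),
                    "members": ";".join(g.members),
                    "name_conflicts": ";".join(g.name_conflicts),
                }
                for g in self.groups
            ]
        )


def cluster_species(
    dm: DistanceMatrix, config: DelimitationConfig | None = None
) -> list[list[str]]:
    """Partition strain ids into single-linkage clusters at theta.

    The partition is the set of connected components of the graph with
    an edge between i and j iff d[i][j] <= theta (or < theta under the
    strict flag).  Components are ordered by first member appearance in
    the matrix, members keep matrix order.
    """
    config = config or DelimitationConfig()
    n = len(dm)
    if config.strict_threshold:
        adj = dm.values < config.theta
    else:
        adj = dm.values <= config.theta
    np.fill_diagonal(adj, False)
    _, labels = connected_components(csr_matrix(adj), directed=False)
    order: dict[int, int] = {}
    for lab in labels:
        if lab not in order:
            order[lab] = len(order)
    partition: list[list[str]] = [[] for _ in range(len(order))]
    for sid, lab in zip(dm.ids, labels):
        partition[order[lab]].append(sid)
    return partition


_ROMAN = (
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
)


def roman(n: int) -> str:
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def _majority(
    names: list[str], external_counts: Counter | None = None
) -> tuple[str, tuple[str, ...]]:
    """Majority name for a group, with a conflict audit trail.

    Ties are broken by preferring the name with the fewest bearers
    *outside* the group — a name borrowed by mislabelling usually has
    its true home in another group — then lexicographically.  Any
    multi-name group is flagged via the returned conflict list.
    """
    counts = Counter(names)
    top = max(counts.values())
    winners = sorted(n for n, c in counts.items() if c == top)
    if len(winners) > 1 and external_counts is not None:
        fewest = min(external_counts.get(n, 0) for n in winners)
        winners = [n for n in winners if external_counts.get(n, 0) == fewest]
    conflicts = tuple(sorted(counts)) if len(counts) > 1 else ()
    return winners[0], conflicts


def assign_labels(
    partition: list[list[str]],
    strain_table: StrainTable,
    config: DelimitationConfig | None = None,
    dm: DistanceMatrix | None = None,
) -> DelimitationResult:
    """Apply the naming, mismatch, cryptic and novelty rules to a partition.

    Passing the distance matrix additionally surfaces chained
    within-group pairs above theta.
    """
    config = config or DelimitationConfig()
    for group in partition:
        for sid in group:
            if sid not in strain_table:
                raise KeyError(f"strain {sid!r} missing from the strain table")

    all_name_counts: Counter[str] = Counter(
        strain_table[m].given_species
        for group in partition
        for m in group
        if strain_table[m].given_species
    )
    groups: list[SpeciesGroup] = []
    complex_counters: Counter[str] = Counter()
    genus_counters: Counter[str] = Counter()
    for gid, members in enumerate(partition, start=1):
        g = SpeciesGroup(group_id=gid, members=tuple(members))
        named = [strain_table[m].given_species for m in members if strain_table[m].given_species]
        external = all_name_counts - Counter(named)
        complexes = [
            strain_table[m].complex_name for m in members if strain_table[m].complex_name
        ]
        if config.complex_labels and complexes:
            cx, _ = _majority(complexes)
            complex_counters[cx] += 1
            g.assigned_label = f"{cx} {roman(complex_counters[cx])}"
            g.label_kind = "complex_subgroup"
            if named:
                _, g.name_conflicts = _majority(named)
        elif len(members) == 1:
            g.label_kind = "undetermined"
            row = strain_table[members[0]]
            if row.given_species:
                g.assigned_label = row.given_species
            else:
                genus = strain_table.genus_of(members[0])
                g.assigned_label = f"{genus} undetermined".strip()
        elif named:
            g.assigned_label, g.name_conflicts = _majority(named, external)
            g.label_kind = "confirmed_species"
        else:
            genera = [strain_table.genus_of(m) for m in members if strain_table.genus_of(m)]
            genus, _ = _majority(genera) if genera else ("Unknown", ())
            genus_counters[genus] += 1
            g.assigned_label = f"{genus} group {genus_counters[genus]}"
            g.label_kind = "new_group"
        groups.append(g)

    # Cryptic pass: one given name spanning several (non-complex) groups.
    name_to_groups: dict[str, list[SpeciesGroup]] = {}
    for g in groups:
        if g.label_kind == "complex_subgroup":
            continue
        for m in g.members:
            name = strain_table[m].given_species
            if name:
                lst = name_to_groups.setdefault(name, [])
                if g not in lst:
                    lst.append(g)
    cryptic_names = {name for name, gs in name_to_groups.items() if len(gs) > 1}
    for name in sorted(cryptic_names):
        k = 0
        for g in name_to_groups[name]:
            if g.assigned_label == name:
                k += 1
                g.assigned_label = f"{name} group {k}"

    assignments: list[StrainAssignment] = []
    for g in groups:
        for m in g.members:
            row = strain_table[m]
            a = StrainAssignment(
                strain_id=m,
                given_species=row.given_species,
                assigned_label=g.assigned_label,
                group_id=g.group_id,
            )
            if g.label_kind == "confirmed_species":
                base = g.assigned_label.split(" group ")[0]
                if row.given_species and row.given_species != base:
                    a.mismatch = True
                if not row.given_species:
                    a.newly_identified = True
            elif g.label_kind == "new_group":
                a.newly_identified = True
            if row.given_species in cryptic_names:
                a.cryptic = True
            assignments.append(a)

    chained: list[tuple[str, str, float]] = []
    if dm is not None:
        for g in groups:
            if len(g.members) < 2:
                continue
            sub = dm.submatrix(list(g.members))
            iu = np.triu_indices(len(sub), k=1)
            for i, j in zip(*iu):
                d = float(sub.values[i, j])
                if not config.conspecific(d):
                    chained.append((sub.ids[i], sub.ids[j], d))
        if chained:
            warnings.warn(
                f"{len(chained)} within-group pair(s) exceed theta={config.theta} "
                "(single-linkage chaining); see DelimitationResult.chained_pairs",
                stacklevel=2,
            )
    return DelimitationResult(groups=groups, assignments=assignments, chained_pairs=chained)


@dataclass
class SynonymCheck:
    strain_a: str
    strain_b: str
    pwd: float | None
    verdict: str  # identical | within_species | discordant | missing


def check_synonyms(
    dm: DistanceMatrix,
    strain_table: StrainTable,
    config: DelimitationConfig | None = None,
) -> list[SynonymCheck]:
    """Verify that declared strain synonyms carry the same barcode.

    One check per unordered declared pair, sorted by descending distance;
    pairs with a member absent from the matrix yield a non-fatal
    ``missing`` entry (and a warning) at the end of the list.
    """
    config = config or DelimitationConfig()
    present: list[SynonymCheck] = []
    missing: list[SynonymCheck] = []
    for a, b in strain_table.synonym_pairs():
        if a in dm.ids and b in dm.ids:
            d = dm.get(a, b)
            if d <= config.identity_tol:
                verdict = "identical"
            elif config.conspecific(d):
                verdict = "within_species"
            else:
                verdict = "discordant"
            present.append(SynonymCheck(a, b, d, verdict))
        else:
            missing.append(SynonymCheck(a, b, None, "missing"))
    if missing:
        warnings.warn(
            f"{len(missing)} declared synonym pair(s) involve ids absent from the "
            "distance matrix",
            stacklevel=2,
        )
    present.sort(key=lambda c: (-c.pwd, c.strain_a, c.strain_b))
    return present + missing


def synonym_frame(checks: list[SynonymCheck], ndigits: int = 3) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "strain_a": c.strain_a,
                "strain_b": c.strain_b,
                "pwd": None if c.pwd is None else round(c.pwd, ndigits),
                "verdict": c.verdict,
            }
            for c in checks
        ]
    )
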