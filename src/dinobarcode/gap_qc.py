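"""Barcode-gap statistics, clonal paralogue variation, and efficiency accounting.

The barcode gap is the separation between the distribution of
within-species (intraspecific) pairwise distances and the
between-species (interspecific) ones; a clean gap is what justifies a
single species cutoff.  Pairs are labelled by the *given* species names
by default — the gap argument is about named species — with an option
to relabel by assigned barcode groups for post-hoc analysis.

Clonal variation summaries describe rDNA paralogue divergence within a
strain (max/min/mean/SD over all clone pairs).  Efficiency accounting
tallies sequencing outcomes per status category and per genus; it needs
no sequences, only a status table, because most failed strains never
yield a barcode.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .distance import DistanceMatrix
from .seqio import CloneGroupTable, FAILURE_STATUSES, StrainTable

__all__ = [
    "LabelledPairs",
    "GapSummary",
    "ClonalVariationSummary",
    "EfficiencyReport",
    "label_pairs",
    "gap_summary",
    "clonal_variation",
    "efficiency_report",
]


@dataclass
class LabelledPairs:
    """Unordered strain pairs labelled intra/inter, one row per pair."""

    frame: pd.DataFrame  # columns: id_a, id_b, pwd, label
    n_omitted: int  # pairs dropped because a member had no species name

    @property
    def intra(self) -> np.ndarray:
        return self.frame.loc[self.frame["label"] == "intra", "pwd"].to_numpy()

    @property
    def inter(self) -> np.ndarray:
        return self.frame.loc[self.frame["label"] == "inter", "pwd"].to_numpy()


def label_pairs(
    dm: DistanceMatrix,
    strain_table: StrainTable,
    use_assigned: bool = False,
    assigned: dict[str, str] | None = None,
) -> LabelledPairs:
    """Label every unordered pair intra (same species) or inter (different).

    Strains with an empty species label are omitted from the pair set
    and only counted.  With ``use_assigned`` the labels come from the
    ``assigned`` mapping (strain id -> barcode group label) instead of
    the given names.
    """
    if use_assigned and assigned is None:
        raise ValueError("use_assigned=True requires the assigned mapping")

    def name_of(sid: str) -> str:
        if use_assigned:
            return assigned.get(sid, "")
        row = strain_table.get(sid)
        return row.given_species if row is not None else ""

    names = {sid: name_of(sid) for sid in dm.ids}
    rows = []
    n_omitted = 0
    ids = dm.ids
    for i in range(len(ids) - 1):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            if not names[a] or not names[b]:
                n_omitted += 1
                continue
            rows.append(
                {
                    "id_a": a,
                    "id_b": b,
                    "pwd": float(dm.values[i, j]),
                    "label": "intra" if names[a] == names[b] else "inter",
                }
            )
    frame = pd.DataFrame(rows, columns=["id_a", "id_b", "pwd", "label"])
    return LabelledPairs(frame=frame, n_omitted=n_omitted)


@dataclass
class GapSummary:
    intra_mean: float | None
    intra_min: float | None
    intra_max: float | None
    inter_mean: float | None
    inter_min: float | None
    inter_max: float | None
    #: inter_mean / intra_mean; None (undefined) when intra_mean is 0 or absent
    ratio: float | None
    n_intra: int
    n_inter: int
    n_omitted: int
    #: per-bin pair counts; columns bin_left, bin_right, intra, inter
    histogram: pd.DataFrame = field(repr=False, default=None)
    #: intra pairs exceeding theta — conspecific names with species-level divergence
    conspecific_over_theta: list[tuple[str, str, float]] = field(default_factory=list)
    mean_mode: str = "pairs"

    def to_dict(self) -> dict:
        d = {k: v for k, v in vars(self).items() if k != "histogram"}
        d["conspecific_over_theta"] = [list(t) for t in self.conspecific_over_theta]
        return d


def _species_means(frame: pd.DataFrame, strain_table: StrainTable, label: str) -> np.ndarray:
    """Collapse pair values to per species(-pair) means before averaging."""
    sub = frame[frame["label"] == label].copy()
    if sub.empty:
        return np.array([])
    name = lambda sid: strain_table[sid].given_species
    key = sub.apply(
        lambda r: tuple(sorted((name(r["id_a"]), name(r["id_b"])))), axis=1
    )
    return sub.groupby(key)["pwd"].mean().to_numpy()


def gap_summary(
    pairs: LabelledPairs,
    bin_width: float = 0.02,
    theta: float = 0.02,
    mean_mode: str = "pairs",
    strain_table: StrainTable | None = None,
) -> GapSummary:
    """Summarise the intra/inter distance distributions and their gap.

    ``mean_mode='pairs'`` (default) averages over pair values;
    ``'species'`` first collapses pairs to per-species(-pair) means
    (requires ``strain_table``).  The histogram uses half-open bins
    [k*w, (k+1)*w) with the final bin closed.
    """
    if mean_mode not in ("pairs", "species"):
        raise ValueError("mean_mode must be 'pairs' or 'species'")
    frame = pairs.frame
    if frame.empty:
        raise ValueError("no labelled pairs: cannot summarise the barcode gap")
    intra, inter = pairs.intra, pairs.inter

    if mean_mode == "species":
        if strain_table is None:
            raise ValueError("mean_mode='species' requires the strain table")
        intra_vals = _species_means(frame, strain_table, "intra")
        inter_vals = _species_means(frame, strain_table, "inter")
    else:
        intra_vals, inter_vals = intra, inter

    intra_mean = float(np.mean(intra_vals)) if intra_vals.size else None
    inter_mean = float(np.mean(inter_vals)) if inter_vals.size else None
    ratio = None
    if intra_mean and inter_mean is not None:  # intra_mean == 0 -> undefined
        ratio = inter_mean / intra_mean

    top = float(frame["pwd"].max())
    n_bins = max(1, math.ceil(round(top / bin_width, 12)) or 1)
    edges = np.arange(n_bins + 1) * bin_width
    hist = pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "intra": np.histogram(intra, bins=edges)[0] if intra.size else 0,
            "inter": np.histogram(inter, bins=edges)[0] if inter.size else 0,
        }
    )

    over = frame[(frame["label"] == "intra") & (frame["pwd"] > theta)]
    return GapSummary(
        intra_mean=intra_mean,
        intra_min=float(intra.min()) if intra.size else None,
        intra_max=float(intra.max()) if intra.size else None,
        inter_mean=inter_mean,
        inter_min=float(inter.min()) if inter.size else None,
        inter_max=float(inter.max()) if inter.size else None,
        ratio=ratio,
        n_intra=int(intra.size),
        n_inter=int(inter.size),
        n_omitted=pairs.n_omitted,
        histogram=hist,
        conspecific_over_theta=[
            (r.id_a, r.id_b, float(r.pwd)) for r in over.itertuples()
        ],
        mean_mode=mean_mode,
    )


@dataclass
class ClonalVariationSummary:
    """Max/min/mean/SD of all pairwise distances among one strain's clones."""

    parent_strain: str
    n_clones: int
    max: float
    min: float
    mean: float
    sd: float

    def as_row(self, ndigits: int = 3) -> dict:
        return {
            "parent_strain": self.parent_strain,
            "max": round(self.max, ndigits),
            "min": round(self.min, ndigits),
            "mean": round(self.mean, ndigits),
            "sd": round(self.sd, ndigits),
            "n": self.n_clones,
        }


def clonal_variation(
    dm: DistanceMatrix, clone_groups: CloneGroupTable, ddof: int = 0
) -> list[ClonalVariationSummary]:
    """Per-strain paralogue variation over all C(n,2) clone pairs.

    SD is the population standard deviation of the pair values by
    default (``ddof=0``); groups with fewer than two clones present in
    the matrix are skipped with a warning.  Output follows input order.
    """
    out: list[ClonalVariationSummary] = []
    for parent, clones in clone_groups.items():
        present = [c for c in clones if c in dm.ids]
        if len(present) < 2:
            warnings.warn(
                f"clone group {parent!r}: fewer than 2 clones present in the "
                "distance matrix; skipped",
                stacklevel=2,
            )
            continue
        sub = dm.submatrix(present)
        iu = np.triu_indices(len(present), k=1)
        vals = sub.values[iu]
        out.append(
            ClonalVariationSummary(
                parent_strain=parent,
                n_clones=len(present),
                max=float(vals.max()),
                min=float(vals.min()),
                mean=float(vals.mean()),
                sd=float(vals.std(ddof=ddof)),
            )
        )
    return out


def clonal_frame(summaries: list[ClonalVariationSummary], ndigits: int = 3) -> pd.DataFrame:
    return pd.DataFrame([s.as_row(ndigits) for s in summaries])


@dataclass
class EfficiencyReport:
    """Barcoding-success accounting over a status table."""

    status_counts: dict[str, int]
    #: share of each failure category among all failures, % to 2 decimals
    failure_pct: dict[str, float]
    overall_success_pct: float
    per_genus_success: dict[str, float]
    totals_by_source: dict[str, dict[str, int]]

    @property
    def n_strains(self) -> int:
        return sum(self.status_counts.values())

    @property
    def n_failures(self) -> int:
        return sum(self.status_counts.get(s, 0) for s in FAILURE_STATUSES)

    def failure_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"status": s, "count": self.status_counts.get(s, 0),
                 "pct_of_failures": self.failure_pct.get(s)}
                for s in FAILURE_STATUSES
            ]
        )

    def genus_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"genus": g, "success_pct": p} for g, p in self.per_genus_success.items()]
        )


def efficiency_report(strain_table: StrainTable) -> EfficiencyReport:
    """Tally outcomes per status, failure cause shares, and per-genus rates.

    Failure-cause percentage for category c is 100 * count(c) / total
    failures, reported to 2 decimals; per-genus success is
    100 * barcoded / total within the genus.
    """
    if len(strain_table) == 0:
        raise ValueError("empty strain table")
    counts: dict[str, int] = {}
    for row in strain_table:
        counts[row.status] = counts.get(row.status, 0) + 1
    n_fail = sum(counts.get(s, 0) for s in FAILURE_STATUSES)
    failure_pct = {
        s: round(100.0 * counts[s] / n_fail, 2)
        for s in FAILURE_STATUSES
        if counts.get(s)
    }
    total = sum(counts.values())
    success = round(100.0 * counts.get("barcoded", 0) / total, 2)

    per_genus: dict[str, list[int]] = {}
    for row in strain_table:
        genus = strain_table.genus_of(row.strain_id) or "(unassigned)"
        tot_ok = per_genus.setdefault(genus, [0, 0])
        tot_ok[0] += 1
        tot_ok[1] += int(row.status == "barcoded")
    per_genus_success = {
        g: round(100.0 * ok / tot, 2) for g, (tot, ok) in sorted(per_genus.items())
    }

    by_source: dict[str, dict[str, int]] = {}
    for row in strain_table:
        slot = by_source.setdefault(row.source, {"total": 0, "barcoded": 0})
        slot["total"] += 1
        slot["barcoded"] += int(row.status == "barcoded")

    return EfficiencyReport(
        status_counts=counts,
        failure_pct=failure_pct,
        overall_success_pct=success,
        per_genus_success=per_genus_success,
        totals_by_source=by_source,
    )
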