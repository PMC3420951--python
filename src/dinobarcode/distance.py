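"""Uncorrected pairwise distances (p-distances) from a global alignment.

The distance between two aligned sequences is the fraction of compared
columns at which they differ.  Which columns are compared is set by the
column-exclusion policy:

``complete_deletion`` (default)
    One mask for the whole alignment: a column is excluded if *any*
    record carries a gap or an ambiguity code there, so every pair is
    compared over the same site set.
``pairwise_deletion``
    Per pair: a column is compared when both sequences have an
    unambiguous A/C/G/T at it.

Ambiguity codes (N, R, Y, ...) are excluded outright rather than scored
as partial matches.  Note p-distances computed after column exclusion
need not satisfy the triangle inequality; nothing downstream assumes it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import Alignment, UNAMBIGUOUS

__all__ = [
    "POLICIES",
    "DistanceError",
    "ColumnMask",
    "DistanceMatrix",
    "build_mask",
    "p_distance",
    "distance_matrix",
]

POLICIES = ("complete_deletion", "pairwise_deletion")


class DistanceError(ValueError):
    """No comparable sites, or an invalid matrix/policy."""


@dataclass(frozen=True)
class ColumnMask:
    """Boolean per-column inclusion mask for an alignment."""

    included: np.ndarray  # bool, one per alignment column
    policy: str

    @property
    def n_included(self) -> int:
        return int(self.included.sum())


def _check_policy(policy: str) -> None:
    if policy not in POLICIES:
        raise DistanceError(f"unknown policy {policy!r}; choose from {POLICIES}")


def _encode(sequences: list[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, L) byte matrix."""
    return np.frombuffer("".join(sequences).encode("ascii"), dtype="S1").reshape(
        len(sequences), -1
    )


_GOOD = np.frombuffer(b"ACGT", dtype="S1")


def _unambiguous(chars: np.ndarray) -> np.ndarray:
    return np.isin(chars, _GOOD)


def build_mask(alignment: Alignment, policy: str = "complete_deletion") -> ColumnMask:
    """Build the column mask for an alignment under the given policy.

    Under ``pairwise_deletion`` the mask is all-inclusive; exclusion then
    happens per pair inside :func:`p_distance`.
    """
    _check_policy(policy)
    chars = _encode([r.sequence for r in alignment.records])
    if policy == "complete_deletion":
        included = _unambiguous(chars).all(axis=0)
    else:
        included = np.ones(alignment.n_columns, dtype=bool)
    mask = ColumnMask(included=included, policy=policy)
    if mask.n_included == 0:
        raise DistanceError("no comparable sites: every column is excluded")
    return mask


def p_distance(
    seq_a: str,
    seq_b: str,
    mask: ColumnMask | None = None,
    policy: str = "complete_deletion",
) -> float:
    """p-distance between two aligned sequences.

    Returns (# compared positions that differ) / (# compared positions).
    Raises :class:`DistanceError` when zero positions are comparable —
    an undefined distance is an error, never reported as 0.
    """
    if len(seq_a) != len(seq_b):
        raise DistanceError("sequences have unequal lengths; input must be aligned")
    _check_policy(policy)
    chars = _encode([seq_a.upper().replace("U", "T"), seq_b.upper().replace("U", "T")])
    if mask is not None:
        if len(mask.included) != chars.shape[1]:
            raise DistanceError("mask length does not match sequence length")
        chars = chars[:, mask.included]
    if policy == "pairwise_deletion":
        keep = _unambiguous(chars[0]) & _unambiguous(chars[1])
        chars = chars[:, keep]
    elif mask is None:
        keep = _unambiguous(chars[0]) & _unambiguous(chars[1])
        chars = chars[:, keep]
    n = chars.shape[1]
    if n == 0:
        raise DistanceError("no comparable sites between the two sequences")
    return float((chars[0] != chars[1]).sum()) / n


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of p-distances over strain/sequence ids.

    ``n_sites`` is the number of compared sites: a scalar under complete
    deletion (same site set for every pair), a per-pair integer matrix
    under pairwise deletion.  Values are kept at full precision; outputs
    round to 3 decimals only at write time.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    policy: str
    n_sites: int | np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise DistanceError("duplicate ids in distance matrix")
        v = self.values
        if v.shape != (n, n):
            raise DistanceError(f"matrix shape {v.shape} does not match {n} ids")
        if not np.allclose(v, v.T):
            raise DistanceError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise DistanceError("distance matrix has non-zero diagonal")
        if v.min() < 0 or v.max() > 1:
            raise DistanceError("p-distances must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, strain_id: str) -> int:
        return self.ids.index(strain_id)

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.index(id_a), self.index(id_b)])

    def submatrix(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.index(i) for i in ids]
        n_sites = self.n_sites
        if isinstance(n_sites, np.ndarray):
            n_sites = n_sites[np.ix_(idx, idx)]
        return DistanceMatrix(
            ids=tuple(ids),
            values=self.values[np.ix_(idx, idx)],
            policy=self.policy,
            n_sites=n_sites,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def write_tsv(self, path: str | Path, ndigits: int = 3) -> None:
        self.to_dataframe().round(ndigits).to_csv(path, sep="\t", float_format=f"%.{ndigits}f")

    def write_phylip(self, path: str | Path, ndigits: int = 6) -> None:
        """Square PHYLIP distance format (relaxed names, tab-separated)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self)}\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{x:.{ndigits}f}" for x in self.values[i])
                fh.write(f"{sid}\t{row}\n")


def distance_matrix(
    alignment: Alignment, policy: str = "complete_deletion"
) -> DistanceMatrix:
    """All pairwise p-distances from one global alignment.

    Deterministic, permutation-equivariant in the record order; requires
    at least two records.
    """
    _check_policy(policy)
    if len(alignment) < 2:
        raise DistanceError("need at least 2 sequences for a distance matrix")
    mask = build_mask(alignment, policy)
    chars = _encode([r.sequence for r in alignment.records])
    n = len(alignment)
    d = np.zeros((n, n), dtype=float)
    if policy == "complete_deletion":
        sub = chars[:, mask.included]
        for i in range(n - 1):
            diffs = (sub[i + 1:] != sub[i]).sum(axis=1)
            d[i, i + 1:] = diffs / mask.n_included
        d += d.T
        n_sites: int | np.ndarray = mask.n_included
    else:
        good = _unambiguous(chars)
        counts = np.zeros((n, n), dtype=int)
        for i in range(n - 1):
            both = good[i + 1:] & good[i]
            comp = both.sum(axis=1)
            if np.any(comp == 0):
                j = int(np.argmax(comp == 0)) + i + 1
                raise DistanceError(
                    f"no comparable sites between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r} under pairwise deletion"
                )
            diffs = ((chars[i + 1:] != chars[i]) & both).sum(axis=1)
            d[i, i + 1:] = diffs / comp
            counts[i, i + 1:] = comp
        d += d.T
        counts += counts.T
        np.fill_diagonal(counts, good.sum(axis=1))
        n_sites = counts
    return DistanceMatrix(ids=alignment.ids, values=d, policy=policy, n_sites=n_sites)
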