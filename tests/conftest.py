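"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from dinobarcode.distance import DistanceMatrix
from dinobarcode.seqio import Alignment, SequenceRecord, StrainRow, StrainTable

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("suite")


def make_alignment(seqs: dict[str, str]) -> Alignment:
    return Alignment.from_records(
        SequenceRecord(id=k, sequence=v) for k, v in seqs.items()
    )


def make_dm(ids: list[str], pairs: dict[tuple[str, str], float]) -> DistanceMatrix:
    """Distance matrix from explicit pair values (unlisted pairs get 0.5)."""
    n = len(ids)
    v = np.full((n, n), 0.5)
    np.fill_diagonal(v, 0.0)
    for (a, b), d in pairs.items():
        i, j = ids.index(a), ids.index(b)
        v[i, j] = v[j, i] = d
    return DistanceMatrix(ids=tuple(ids), values=v, policy="complete_deletion", n_sites=100)


def make_table(rows: list[dict]) -> StrainTable:
    return StrainTable(StrainRow(**r) for r in rows)


# --- independent oracles -------------------------------------------------

UNAMBIG = set("ACGT")


def brute_force_p_distance(a: str, b: str, mask=None) -> float | None:
    """Per-character comparison over positions where both chars are A/C/G/T."""
    compared = differ = 0
    for k, (x, y) in enumerate(zip(a.upper(), b.upper())):
        if mask is not None and not mask[k]:
            continue
        if x in UNAMBIG and y in UNAMBIG:
            compared += 1
            differ += x != y
    return differ / compared if compared else None


def brute_force_matrix(seqs: list[str], policy: str) -> np.ndarray | None:
    """Naive double-loop matrix under either column-exclusion policy."""
    L = len(seqs[0])
    if policy == "complete_deletion":
        mask = [all(s[k] in UNAMBIG for s in seqs) for k in range(L)]
        if not any(mask):
            return None
    else:
        mask = None
    n = len(seqs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = brute_force_p_distance(seqs[i], seqs[j], mask)
            if d is None:
                return None
            out[i, j] = out[j, i] = d
    return out


def transitive_closure_partition(dm: DistanceMatrix, theta: float, strict=False):
    """O(n^3) Floyd-Warshall-style closure of the <=theta relation."""
    n = len(dm)
    reach = (dm.values < theta) if strict else (dm.values <= theta)
    reach = reach.copy()
    np.fill_diagonal(reach, True)
    for k in range(n):
        for i in range(n):
            if reach[i, k]:
                reach[i] |= reach[k]
    seen: list[int] = []
    partition = []
    for i in range(n):
        if i in seen:
            continue
        comp = [j for j in range(n) if reach[i, j]]
        seen.extend(comp)
        partition.append([dm.ids[j] for j in comp])
    return partition


@pytest.fixture
def tiny_alignment() -> Alignment:
    return make_alignment({"a": "ACGTACGTAC", "b": "ACGAACGTAC", "c": "TCGTACGTCC"})
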