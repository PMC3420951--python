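"""Barcode-gap statistics, clonal variation, and efficiency accounting."""

import itertools

import numpy as np
import pytest

from dinobarcode.gap_qc import (
    clonal_variation,
    efficiency_report,
    gap_summary,
    label_pairs,
)
from dinobarcode.seqio import CloneGroupTable, StrainRow, StrainTable

from conftest import make_dm, make_table


def pairs_for(species: dict[str, str], dists: dict[tuple[str, str], float]):
    ids = list(species)
    dm = make_dm(ids, dists)
    table = make_table(
        [{"strain_id": s, "given_species": name} for s, name in species.items()]
    )
    return label_pairs(dm, table), dm, table


class TestLabelPairs:
    def test_two_conspecific_strains_one_intra_pair(self):
        pairs, _, _ = pairs_for({"a": "S1", "b": "S1"}, {("a", "b"): 0.01})
        assert len(pairs.intra) == 1 and len(pairs.inter) == 0

    def test_three_strains_two_species(self):
        pairs, _, _ = pairs_for(
            {"a": "A", "b": "A", "c": "B"},
            {("a", "b"): 0.01, ("a", "c"): 0.2, ("b", "c"): 0.2},
        )
        assert len(pairs.intra) == 1 and len(pairs.inter) == 2

    def test_unnamed_strains_only_counted_as_omitted(self):
        pairs, _, _ = pairs_for({"a": "A", "b": "A", "c": ""}, {("a", "b"): 0.01})
        assert len(pairs.frame) == 1
        assert pairs.n_omitted == 2


class TestGapSummary:
    def test_ratio_echoes_constructed_values(self):
        # intra all 1%, inter all 34% -> mean ratio exactly 34
        species = {f"a{i}": "A" for i in range(2)} | {f"b{i}": "B" for i in range(2)}
        dists = {("a0", "a1"): 0.01, ("b0", "b1"): 0.01}
        for x in ("a0", "a1"):
            for y in ("b0", "b1"):
                dists[(x, y)] = 0.34
        pairs, _, _ = pairs_for(species, dists)
        s = gap_summary(pairs)
        assert s.ratio == pytest.approx(34.0)

    def test_hand_computed_means(self):
        species = {"a": "A", "b": "A", "c": "A", "d": "B"}
        dists = {("a", "b"): 0.0, ("a", "c"): 0.02, ("b", "c"): 0.02,
                 ("a", "d"): 0.05, ("b", "d"): 0.05, ("c", "d"): 0.05}
        pairs, _, _ = pairs_for(species, dists)
        s = gap_summary(pairs)
        assert s.intra_mean == pytest.approx(np.mean([0.0, 0.02, 0.02]))
        assert s.inter_mean == pytest.approx(0.05)
        assert s.intra_min == 0.0 and s.intra_max == 0.02

    def test_two_value_hand_case(self):
        pairs, _, _ = pairs_for(
            {"a": "A", "b": "A", "c": "B", "d": "B"},
            {("a", "b"): 0.0, ("c", "d"): 0.02, ("a", "c"): 0.05,
             ("a", "d"): 0.05, ("b", "c"): 0.05, ("b", "d"): 0.05},
        )
        s = gap_summary(pairs)
        assert s.intra_mean == pytest.approx(0.01)
        assert s.inter_mean == pytest.approx(0.05)
        assert s.ratio == pytest.approx(5.0)

    def test_conspecific_pair_over_theta_listed(self):
        pairs, _, _ = pairs_for({"a": "A", "b": "A"}, {("a", "b"): 0.037})
        s = gap_summary(pairs, theta=0.02)
        assert s.conspecific_over_theta == [("a", "b", 0.037)]

    def test_histogram_counts_sum_to_labelled_pairs(self):
        rng = np.random.default_rng(11)
        ids = [f"s{i}" for i in range(8)]
        species = {s: ("A" if i < 4 else "B") for i, s in enumerate(ids)}
        dists = {}
        for x, y in itertools.combinations(ids, 2):
            same = species[x] == species[y]
            dists[(x, y)] = float(rng.uniform(0, 0.02) if same else rng.uniform(0.1, 0.4))
        pairs, _, _ = pairs_for(species, dists)
        s = gap_summary(pairs)
        assert int(s.histogram["intra"].sum() + s.histogram["inter"].sum()) == len(pairs.frame)
        # no value lands outside the final (closed) bin
        assert s.histogram["bin_right"].iloc[-1] >= pairs.frame["pwd"].max()

    def test_zero_intra_mean_gives_undefined_ratio(self):
        pairs, _, _ = pairs_for(
            {"a": "A", "b": "A", "c": "B"},
            {("a", "b"): 0.0, ("a", "c"): 0.2, ("b", "c"): 0.2},
        )
        assert gap_summary(pairs).ratio is None

    def test_no_labelled_pairs_is_error(self):
        pairs, _, _ = pairs_for({"a": "", "b": ""}, {("a", "b"): 0.01})
        with pytest.raises(ValueError):
            gap_summary(pairs)

    def test_species_mean_mode_collapses_pairs_first(self):
        # species A has 2 intra pairs (0.0, 0.02), species B has 1 (0.04):
        # pair mode mean = 0.02; species mode mean = (0.01 + 0.04)/2 = 0.025
        species = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
        dists = {("a1", "a2"): 0.0, ("a1", "a3"): 0.02, ("a2", "a3"): 0.04,
                 ("b1", "b2"): 0.04}
        for x in ("a1", "a2", "a3"):
            for y in ("b1", "b2"):
                dists[(x, y)] = 0.3
        pairs, _, table = pairs_for(species, dists)
        s_pairs = gap_summary(pairs)
        s_species = gap_summary(pairs, mean_mode="species", strain_table=table)
        assert s_pairs.intra_mean == pytest.approx(np.mean([0.0, 0.02, 0.04, 0.04]))
        assert s_species.intra_mean == pytest.approx(np.mean([0.02, 0.04]))


class TestClonalVariation:
    def test_two_clones_at_0004(self):
        dm = make_dm(["c1", "c2"], {("c1", "c2"): 0.004})
        (s,) = clonal_variation(dm, CloneGroupTable({"P": ["c1", "c2"]}))
        assert (s.max, s.min, s.mean, s.sd, s.n_clones) == (0.004, 0.004, 0.004, 0.0, 2)

    def test_identical_clones_all_zero(self):
        dm = make_dm(["c1", "c2"], {("c1", "c2"): 0.0})
        (s,) = clonal_variation(dm, CloneGroupTable({"P": ["c1", "c2"]}))
        assert s.max == s.min == s.mean == s.sd == 0.0

    def test_three_clones_hand_computation(self):
        dm = make_dm(["c1", "c2", "c3"],
                     {("c1", "c2"): 0.01, ("c1", "c3"): 0.02, ("c2", "c3"): 0.03})
        (s,) = clonal_variation(dm, CloneGroupTable({"P": ["c1", "c2", "c3"]}))
        assert (s.max, s.min) == (0.03, 0.01)
        assert s.mean == pytest.approx(0.02)
        assert s.sd == pytest.approx(np.std([0.01, 0.02, 0.03]))

    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(5)
        ids = [f"c{i}" for i in range(6)]
        dists = {p: float(rng.uniform(0, 0.02)) for p in itertools.combinations(ids, 2)}
        dm = make_dm(ids, dists)
        (s,) = clonal_variation(dm, CloneGroupTable({"P": ids}))
        vals = [dm.get(a, b) for a, b in itertools.combinations(ids, 2)]
        assert s.mean == pytest.approx(np.mean(vals))
        assert s.sd == pytest.approx(np.std(vals))
        assert s.max == max(vals) and s.min == min(vals)

    def test_single_clone_group_skipped_with_warning(self):
        dm = make_dm(["c1", "c2"], {("c1", "c2"): 0.0})
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = clonal_variation(dm, CloneGroupTable({"P": ["c1", "zzz"]}))
        assert out == []


def status_table(n_amp, n_seq, n_low, n_ok, genus="Karenia"):
    rows = []
    for status, n in (("amplification_failed", n_amp), ("sequencing_failed", n_seq),
                      ("low_quality", n_low), ("barcoded", n_ok)):
        rows += [StrainRow(f"{status}-{i}", genus=genus, status=status)
                 for i in range(n)]
    return StrainTable(rows)


class TestEfficiency:
    def test_failure_percentages_from_printed_counts(self):
        report = efficiency_report(status_table(335, 136, 47, 151))
        assert report.failure_pct == {
            "amplification_failed": 64.67,
            "sequencing_failed": 26.25,
            "low_quality": 9.07,
        }

    def test_failure_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = rng.integers(1, 400, size=3)
            report = efficiency_report(status_table(*n, 10))
            assert sum(report.failure_pct.values()) == pytest.approx(100, abs=0.02)

    def test_all_barcoded_degenerate_case(self):
        report = efficiency_report(status_table(0, 0, 0, 5))
        assert report.failure_pct == {}
        assert report.overall_success_pct == 100.0

    def test_per_genus_success_rate(self):
        table = StrainTable([
            StrainRow("a", genus="Karenia", status="barcoded"),
            StrainRow("b", genus="Karenia", status="amplification_failed"),
            StrainRow("c", genus="Pfiesteria", status="amplification_failed"),
        ])
        report = efficiency_report(table)
        assert report.per_genus_success == {"Karenia": 50.0, "Pfiesteria": 0.0}

    def test_totals_by_source(self):
        rows = [StrainRow(f"s{i}", status="barcoded", source="this_study")
                for i in range(3)]
        rows += [StrainRow(f"g{i}", status="barcoded", source="database")
                 for i in range(2)]
        report = efficiency_report(StrainTable(rows))
        assert report.totals_by_source == {
            "this_study": {"total": 3, "barcoded": 3},
            "database": {"total": 2, "barcoded": 2},
        }

    def test_empty_table_is_error(self):
        with pytest.raises(ValueError):
            efficiency_report(StrainTable([]))
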