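import random

import pytest

from haplopop.haplotype_catalog import (
    CatalogConflictError,
    Individual,
    UnknownIndividualError,
    assemble_individuals,
    build_catalog,
    combine_calls,
    tabulate,
)
from haplopop.seq_io import COI, COII, LocusSpec, PopulationMap, SequenceRecord


def _seq(n=657, seed=0):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def _mutate(seq, pos, base=None):
    base = base or next(b for b in "ACGT" if b != seq[pos])
    return seq[:pos] + base + seq[pos + 1 :]


def _refs(names_seqs, locus=COI):
    return [SequenceRecord(name, locus.name, seq) for name, seq in names_seqs]


class TestBuildCatalog:
    def test_distinct_references_build_directly(self):
        seqs = [_seq(seed=i) for i in range(3)]
        cat = build_catalog(_refs(zip(["H1", "H3", "H8"], seqs)), COI)
        assert len(cat) == 3
        assert cat.sequence("H3") == seqs[1]

    def test_identical_sequences_with_two_names_conflict(self):
        s = _seq()
        with pytest.raises(CatalogConflictError):
            build_catalog(_refs([("H1", s), ("H99", s)]), COI)

    def test_one_name_two_sequences_conflict(self):
        with pytest.raises(CatalogConflictError):
            build_catalog(_refs([("H1", _seq(seed=1)), ("H1", _seq(seed=2))]), COI)

    def test_exact_duplicates_collapse(self):
        seqs = [_seq(seed=i) for i in range(4)]
        entries = list(zip(["H1", "H2", "H3", "H4"], seqs)) + [("H2", seqs[1])]
        cat = build_catalog(_refs(entries), COI)
        assert len(cat) == 4

    def test_short_reference_excluded_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            cat = build_catalog(
                _refs([("H1", _seq(seed=1)), ("N22", _seq(651, seed=2))]), COI
            )
        assert len(cat) == 1 and "N22" not in cat
        assert any("N22" in r.message for r in caplog.records)

    def test_novel_counter_continues_published_series(self):
        cat = build_catalog(_refs([("H1", _seq(seed=1)), ("N5", _seq(seed=2))]), COI)
        call = cat.call(SequenceRecord("x", "COI", _seq(seed=3)))
        assert call.haplotype_name == "N6"


class TestCalling:
    @pytest.fixture()
    def catalog(self):
        return build_catalog(
            _refs([("H1", _seq(seed=1)), ("H3", _seq(seed=2))]), COI
        )

    def test_identical_to_reference_keeps_published_name(self, catalog):
        call = catalog.call(SequenceRecord("x", "COI", _seq(seed=1)))
        assert (call.haplotype_name, call.status) == ("H1", "known")

    def test_one_site_off_reference_mints_first_novel_name(self, catalog):
        variant = _mutate(_seq(seed=1), 10)
        call = catalog.call(SequenceRecord("x", "COI", variant))
        assert (call.haplotype_name, call.status) == ("N1", "novel")

    def test_same_novel_sequence_gets_same_name_twice(self, catalog):
        variant = _mutate(_seq(seed=1), 10)
        first = catalog.call(SequenceRecord("x", "COI", variant))
        second = catalog.call(SequenceRecord("y", "COI", variant))
        assert first.haplotype_name == second.haplotype_name == "N1"
        assert second.status == "novel"

    def test_locus_mismatch_is_an_error(self, catalog):
        with pytest.raises(ValueError, match="locus"):
            catalog.call(SequenceRecord("x", "COII", _seq(518)))

    def test_unqced_record_rejected(self, catalog):
        with pytest.raises(ValueError, match="QC"):
            catalog.call(SequenceRecord("x", "COI", "N" + _seq(seed=1)[1:]))

    def test_catalog_growth_equals_distinct_novel_sequences(self, catalog):
        base = _seq(seed=1)
        variants = [_mutate(base, p) for p in (3, 5, 7)] * 2
        before = len(catalog)
        for i, v in enumerate(variants):
            catalog.call(SequenceRecord(f"i{i}", "COI", v))
        assert len(catalog) == before + 3

    def test_name_partition_invariant_under_input_order(self):
        base = _seq(seed=1)
        variants = {f"i{j}": _mutate(base, p) for j, p in enumerate([3, 5, 3, 9, 5])}
        orders = [list(variants), list(reversed(variants))]
        partitions = []
        for order in orders:
            cat = build_catalog(_refs([("H1", base)]), COI)
            calls = {i: cat.call(SequenceRecord(i, "COI", variants[i])) for i in order}
            groups = {}
            for ind, call in calls.items():
                groups.setdefault(call.haplotype_name, set()).add(ind)
            partitions.append(frozenset(frozenset(g) for g in groups.values()))
        assert partitions[0] == partitions[1]


class TestCombineAndTabulate:
    def _individual(self, i, coi, coii, country="Serbia", region="Senta"):
        return Individual(f"i{i}", country, region, coi_name=coi, coii_name=coii)

    def test_combined_name_is_concatenation(self):
        inds = [self._individual(1, "H1", "h1"), self._individual(2, "N47", "h3")]
        assert combine_calls(inds) == 2
        assert [i.combined_name for i in inds] == ["H1h1", "N47h3"]

    def test_missing_locus_blocks_combination(self):
        inds = [self._individual(1, "H1", None)]
        assert combine_calls(inds) == 0
        assert inds[0].combined_name is None

    def test_distinct_combined_names_match_distinct_pairs(self):
        pairs = [("H1", "h1"), ("H1", "h3"), ("H3", "h1"), ("H1", "h1")]
        inds = [self._individual(i, c1, c2) for i, (c1, c2) in enumerate(pairs)]
        combine_calls(inds)
        assert len({i.combined_name for i in inds}) == len(set(pairs))

    def test_monomorphic_population_tabulates_to_100_percent(self):
        inds = [self._individual(i, "H1", "h1", "USA", "Maryland") for i in range(24)]
        combine_calls(inds)
        table = tabulate(inds, level="country")
        assert table.counts == {"USA": {"H1h1": 24}}
        assert table.percentages() == {"USA": {"H1h1": 100.0}}

    def test_two_haplotype_split_percentages(self):
        inds = [
            self._individual(i, "H1" if i < 5 else "H3", "h1" if i < 5 else "h3")
            for i in range(9)
        ]
        combine_calls(inds)
        pct = tabulate(inds, level="region").percentages()
        assert pct == {"Senta": {"H1h1": 55.6, "H3h3": 44.4}}

    def test_empty_individual_list_gives_empty_table(self):
        assert tabulate([], level="country").counts == {}

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            tabulate([], level="continent")


def test_assemble_requires_popmap_entry():
    popmap = PopulationMap({"a": ("China", "Beijing")})
    cat = build_catalog(_refs([("H1", _seq(seed=1))]), COI)
    call_a = cat.call(SequenceRecord("a", "COI", _seq(seed=1)))
    call_b = cat.call(SequenceRecord("b", "COI", _seq(seed=1)))
    assert assemble_individuals([call_a], [], popmap)[0].country == "China"
    with pytest.raises(UnknownIndividualError):
        assemble_individuals([call_a, call_b], [], popmap)


def test_single_locus_individual_is_recorded_not_an_error():
    popmap = PopulationMap({"a": ("China", "Beijing"), "b": ("China", "Beijing")})
    coi_cat = build_catalog(_refs([("H1", _seq(seed=1))]), COI)
    coii_cat = build_catalog(
        _refs([("h1", _seq(518, seed=4))], locus=COII), COII
    )
    coi_calls = [
        coi_cat.call(SequenceRecord(i, "COI", _seq(seed=1))) for i in ("a", "b")
    ]
    coii_calls = [coii_cat.call(SequenceRecord("a", "COII", _seq(518, seed=4)))]
    inds = assemble_individuals(coi_calls, coii_calls, popmap)
    assert combine_calls(inds) == 1
    by_id = {i.individual_id: i for i in inds}
    assert by_id["a"].combined_name == "H1h1"
    assert by_id["b"].coii_name is None and by_id["b"].combined_name is None
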