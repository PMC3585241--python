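"""Strategy executors and the three-rule validity checker."""

import itertools

import pytest

from attasm.planner import build_merge_tree, count_ops
from attasm.seqmodel import molecules_equal
from attasm.strategies import (
    DRAS,
    SRAS,
    TRAS,
    LINEAR_TRAS,
    StrategyError,
    build_dras_host,
    build_dras_unit,
    build_sras_host,
    build_sras_unit,
    build_tras_unit,
    dras_swap,
    get_template,
    mutant_templates,
    payload_order,
    required_parities,
    run_assembly,
    shipped_templates,
    sras_cycle,
    sras_extract,
    tras_merge,
    validate_strategy,
)


def orf(tag, n=90):
    import hashlib

    h = hashlib.sha256(tag.encode()).hexdigest()
    return "ATG" + "".join("ACGT"[int(c, 16) % 4] for c in h * 4)[:n] + "TAA"


@pytest.fixture
def sras_host():
    return build_sras_host()


class TestSrasCycle:
    def test_integration_then_excision_leaves_kan_sensitive_host(self, sras_host):
        h1 = sras_cycle(sras_host, build_sras_unit("LuxC", orf("C"), 1))
        chrom = h1.chromosome
        assert payload_order(chrom) == ["LuxC"]
        assert not any(f.kind == "marker" for f in chrom.features)
        assert h1.episomes == []  # excised backbone cured away

    def test_second_cycle_needs_opposite_parity(self, sras_host):
        h1 = sras_cycle(sras_host, build_sras_unit("P1", orf("1"), 1))
        with pytest.raises(StrategyError, match="parity"):
            sras_cycle(h1, build_sras_unit("P2", orf("2"), 1))
        h2 = sras_cycle(h1, build_sras_unit("P2", orf("2"), 2))
        assert payload_order(h2.chromosome) == ["P2", "P1"]

    def test_both_io_orders_give_identical_chromosomes(self, sras_host):
        unit = build_sras_unit("LuxC", orf("C"), 1)
        ends_first = sras_cycle(sras_host, unit, "ends_first")
        breakers_first = sras_cycle(sras_host, unit, "breakers_first")
        assert molecules_equal(ends_first.chromosome, breakers_first.chromosome)


class TestSrasExtract:
    def test_extracted_plasmid_mirrors_chromosomal_order(self, sras_host):
        h = sras_cycle(sras_host, build_sras_unit("P1", orf("1"), 1))
        h = sras_cycle(h, build_sras_unit("P2", orf("2"), 2))
        plasmid, post = sras_extract(h)
        assert plasmid.topology == "circular"
        assert payload_order(plasmid) == ["P2", "P1"]
        assert plasmid.id == "pUnitP2P1"
        # replicable only in pir+ context
        assert any(
            f.kind == "origin" and f.name == "R6Kgamma" for f in plasmid.features
        )
        # post-excision host keeps an attB Phi80 junction, not the region
        assert payload_order(post.chromosome) == []

    def test_extraction_of_unassembled_host_errors(self, sras_host):
        with pytest.raises(StrategyError, match="no assembled payloads"):
            sras_extract(sras_host)


class TestDras:
    def test_swap_appends_payload_and_swaps_marker(self):
        host = build_dras_host()
        h1 = dras_swap(host, build_dras_unit("P1", orf("1"), 1))
        markers = [f.name for f in h1.chromosome.features if f.kind == "marker"]
        assert markers == ["cat"]
        assert payload_order(h1.chromosome, DRAS) == ["P1"]

    def test_same_marker_unit_rejected(self):
        host = build_dras_host()  # kan host
        unit = build_dras_unit("P1", orf("1"), 2)  # parity 2 -> kan unit
        with pytest.raises(StrategyError, match="same-marker"):
            dras_swap(host, unit)

    def test_two_swaps_restore_original_marker(self):
        host = build_dras_host()
        h1 = dras_swap(host, build_dras_unit("P1", orf("1"), 1))
        h2 = dras_swap(h1, build_dras_unit("P2", orf("2"), 2))
        markers = [f.name for f in h2.chromosome.features if f.kind == "marker"]
        assert markers == ["kan"]
        assert payload_order(h2.chromosome, DRAS) == ["P2", "P1"]


class TestTrasMerge:
    def u(self, name, lm, rm, vl, vr, template=TRAS):
        return build_tras_unit(name, orf(name), lm, rm, vl, vr, template=template)

    def test_right_extension(self):
        m = tras_merge(self.u("DNA1", "cat", "gen", "2", "1"),
                       self.u("DNA2", "gen", "kan", "1", "2"))
        assert m.id == "C-DNA1DNA2-K"
        markers = {f.name for f in m.features if f.kind == "marker"}
        assert markers == {"cat", "kan"}  # junction gen consumed
        assert [f.name for f in sorted(
            (f for f in m.features if f.kind == "payload"), key=lambda f: f.start
        )] == ["DNA1", "DNA2"]

    def test_left_extension(self):
        m = tras_merge(self.u("DNA1", "cat", "gen", "2", "1"),
                       self.u("DNA2", "kan", "cat", "1", "2"), direction="left")
        assert m.id == "K-DNA2DNA1-G"

    def test_no_shared_junction_marker_errors(self):
        with pytest.raises(StrategyError, match="shared junction marker"):
            tras_merge(self.u("DNA1", "cat", "gen", "2", "1"),
                       self.u("DNA2", "cat", "kan", "1", "2"))

    def test_fusion_intermediate_has_all_three_markers(self):
        # the merged product is screened out of an intermediate that carried
        # cat, gen and kan; the by-product circle keeps gen only
        m = tras_merge(self.u("DNA1", "cat", "gen", "2", "1"),
                       self.u("DNA2", "gen", "kan", "1", "2"))
        assert {f.name for f in m.features if f.kind == "marker"} == {"cat", "kan"}

    def test_linear_units_exchange_directly(self):
        left = self.u("DNA1", "cat", "gen", "2", "1", template=LINEAR_TRAS)
        right = self.u("DNA2", "gen", "kan", "1", "2", template=LINEAR_TRAS)
        m = tras_merge(left, right, template=LINEAR_TRAS)
        assert m.topology == "linear"
        assert m.id == "C-DNA1DNA2-K"
        assert any(f.name == "N15_linear" for f in m.features if f.kind == "origin")


class TestRunAssembly:
    def test_sras_five_units_balanced_tree(self):
        names = ["D", "C", "E", "B", "A"]
        tree = build_merge_tree(names)
        units = [
            build_sras_unit(n, orf(n), p)
            for n, p in zip(names, required_parities(tree))
        ]
        construct, log = run_assembly(SRAS, units, tree)
        assert payload_order(construct) == names
        assert log.category_totals() == count_ops(SRAS, tree)

    def test_single_unit_empty_log(self):
        tree = build_merge_tree(1)
        unit = build_tras_unit("DNA1", orf("1"), "cat", "gen", "2", "1")
        construct, log = run_assembly(TRAS, [unit], tree)
        assert construct is unit
        assert log.entries == []

    def test_tras_four_units_three_electroporations(self):
        markers = ["cat", "gen", "kan", "cat", "gen"]
        vs = ["2", "1", "2", "1", "2"]
        units = [
            build_tras_unit(f"DNA{i+1}", orf(str(i)), markers[i], markers[i + 1],
                            vs[i], vs[i + 1])
            for i in range(4)
        ]
        tree = build_merge_tree(4)
        construct, log = run_assembly(TRAS, units, tree)
        totals = log.category_totals()
        assert totals["electroporation"] == 3
        assert totals == count_ops(TRAS, tree)
        assert payload_order(construct, TRAS) == [f"DNA{i+1}" for i in range(4)]

    def test_unit_count_must_match_leaves(self):
        with pytest.raises(StrategyError, match="units supplied"):
            run_assembly(SRAS, [], build_merge_tree(2))

    def test_cost_only_template_rejected(self):
        with pytest.raises(StrategyError, match="no.*schedule"):
            run_assembly(get_template("BIOBRICK"), [], build_merge_tree(1))


@pytest.mark.parametrize("n_units", [2, 3, 4, 5])
def test_sras_payload_order_any_leaf_count(n_units):
    names = [f"G{i}" for i in range(n_units)]
    tree = build_merge_tree(names)
    units = [
        build_sras_unit(n, orf(n, 30), p)
        for n, p in zip(names, required_parities(tree))
    ]
    construct, _ = run_assembly(SRAS, units, tree)
    assert payload_order(construct) == names


def test_sras_order_correct_for_all_120_permutations():
    """Exhaustive small-instance check: any permutation of five payloads
    assembles in exactly the requested order."""
    base = {n: orf(n, 24) for n in "VWXYZ"}
    for perm in itertools.permutations("VWXYZ"):
        names = list(perm)
        tree = build_merge_tree(names)
        units = [
            build_sras_unit(n, base[n], p)
            for n, p in zip(names, required_parities(tree))
        ]
        construct, _ = run_assembly(SRAS, units, tree)
        assert payload_order(construct) == names


def test_sras_final_product_scar_structure():
    """No marker features between payloads; each merge leaves one attB scar."""
    names = ["D", "C", "E", "B", "A"]
    tree = build_merge_tree(names)
    units = [
        build_sras_unit(n, orf(n), p) for n, p in zip(names, required_parities(tree))
    ]
    construct, _ = run_assembly(SRAS, units, tree)
    assert not any(f.kind == "marker" for f in construct.features)
    from attasm.io_fixtures import _junction_report

    report = _junction_report(construct, SRAS)
    assert len(report) == len(names) - 1
    assert all(r.state == "B" for r in report)


class TestValidateStrategy:
    def test_shipped_templates_pass(self):
        for name, t in shipped_templates().items():
            if not t.has_schedule:
                continue
            report = validate_strategy(t)
            assert report.valid, f"{name}: {report.failing()}"

    def test_cost_only_templates_not_checkable(self):
        with pytest.raises(StrategyError, match="not checkable"):
            validate_strategy(get_template("GIBSON"))

    @pytest.mark.parametrize(
        "mutant,expected",
        [
            ("symmetric_ends", "rule1"),
            ("inert_breaker", "rule2"),
            ("missing_origin", "rule3"),
        ],
    )
    def test_each_mutant_fails_exactly_one_rule(self, mutant, expected):
        report = validate_strategy(mutant_templates()[mutant])
        assert report.failing() == [expected]
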