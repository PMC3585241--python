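"""The reaction engine: compatibility algebra, splicing, conservation laws."""

import numpy as np
import pytest

from attasm.recombinase import (
    CRE,
    HK022_INT,
    HK022_INT_XIS,
    LAMBDA_INT,
    LAMBDA_INT_XIS,
    Enzyme,
    IncompatibleEventError,
    ReactionEvent,
    compatible,
    enumerate_events,
    recombine,
)
from attasm.seqmodel import DnaMolecule, Feature, molecules_equal

ATT_B1_CORE = "ACAAGTTTGTACAAAAAAGCAGGCT"
ATT_B2_CORE = "ACCACTTTGTACAAGAAAGCTGGGT"
ATT_B_HK022_CORE = "AACCTTTTTCACCTAAAGTGCACC"


def circle(lib, mol_id, site_specs, spacing=25):
    """Circular molecule with the given (system, variant, state) sites."""
    seq, sites, pos = [], [], 0
    for spec in site_specs:
        s = lib.site(spec[0], spec[1], spec[2], start=pos)
        sites.append(s)
        seq.append(s.site_seq())
        pad = "T" * spacing
        seq.append(pad)
        pos = s.end + spacing
    return DnaMolecule(mol_id, "circular", "".join(seq), sites=sites)


class TestCompatible:
    def test_bxp_needs_int(self, lib):
        b = lib.site("HK022", state="B")
        p = lib.site("HK022", state="P")
        assert compatible(b, p, HK022_INT) == "BxP"
        assert compatible(b, p, Enzyme("HK022", has_int=False)) is None

    def test_cross_system_incompatible(self, lib):
        assert (
            compatible(lib.site("lambda", "1", "B"), lib.site("HK022", state="P"), HK022_INT)
            is None
        )

    def test_lxr_needs_int_and_xis(self, lib):
        l = lib.site("HK022", state="L")
        r = lib.site("HK022", state="R")
        assert compatible(l, r, HK022_INT) is None
        assert compatible(l, r, HK022_INT_XIS) == "LxR"

    def test_variant_pairs_enumerated(self, lib):
        """attL1 reacts only with attR1; every cross-variant pair is inert."""
        for va in ("1", "2"):
            for vb in ("1", "2"):
                l = lib.site("lambda", va, "L")
                r = lib.site("lambda", vb, "R")
                got = compatible(l, r, LAMBDA_INT_XIS)
                assert got == ("LxR" if va == vb else None)

    def test_symmetric_pairs(self, lib):
        a, b = lib.site("P1-lox"), lib.site("P1-lox")
        assert compatible(a, b, CRE) == "symmetric"
        assert compatible(a, b, LAMBDA_INT) is None

    def test_same_state_pairs_inert(self, lib):
        assert compatible(lib.site("HK022", state="B"), lib.site("HK022", state="B"),
                          HK022_INT) is None


class TestRecombine:
    def test_integration_then_excision_scar(self, lib):
        """BxP integrates a plasmid; intramolecular LxR excises it again,
        leaving the printed HK022 attB core on the chromosome."""
        plas = circle(lib, "plas", [("HK022", "", "P")])
        chrom = circle(lib, "chrom", [("HK022", "", "B")])
        chrom.features.append(Feature("origin", "chromosomal", chrom.sites[0].end + 2,
                                      chrom.sites[0].end + 10))
        (ev,) = enumerate_events([plas, chrom], {HK022_INT})
        (fused,) = recombine(ev, [plas, chrom])
        states = sorted(s.state for s in fused.sites)
        assert states == ["L", "R"]
        (ev2,) = enumerate_events([fused], {HK022_INT_XIS})
        prods = recombine(ev2, [fused])
        assert len(prods) == 2
        b_sites = [s for m in prods for s in m.sites if s.state == "B"]
        assert len(b_sites) == 1
        assert b_sites[0].core == ATT_B_HK022_CORE

    @pytest.mark.parametrize(
        "variant,core",
        [("1", ATT_B1_CORE), ("2", ATT_B2_CORE)],
    )
    def test_lambda_variant_excision_cores(self, lib, variant, core):
        mol = circle(lib, "m", [("lambda", variant, "L"), ("lambda", variant, "R")])
        (ev,) = enumerate_events([mol], {LAMBDA_INT_XIS})
        prods = recombine(ev, [mol])
        b = [s for m in prods for s in m.sites if s.state == "B"]
        p = [s for m in prods for s in m.sites if s.state == "P"]
        assert len(b) == 1 and len(p) == 1
        assert b[0].core == core

    def test_lox_direct_repeat_partitions_circle(self, lib):
        lox1 = lib.site("P1-lox", start=10)
        lox2 = lib.site("P1-lox", start=60)
        seq = "A" * 10 + lox1.site_seq() + "G" * (60 - lox1.end) + lox2.site_seq()
        seq += "C" * (100 - len(seq))
        mol = DnaMolecule("m", "circular", seq, sites=[lox1, lox2])
        (ev,) = enumerate_events([mol], {CRE})
        prods = recombine(ev, [mol])
        assert sorted(len(p) for p in prods) == sorted([50, 50]) or sum(
            len(p) for p in prods
        ) == 100
        assert sum(len(p) for p in prods) == 100
        # symmetric sites persist on both products
        assert all(p.sites and p.sites[-1].state == "symmetric" for p in prods)

    def test_linear_exchange(self, lib):
        a = lib.site("lambda", "1", "L", start=20)
        b = lib.site("lambda", "1", "R", start=30)
        molA = DnaMolecule("A", "linear", "A" * 20 + a.site_seq() + "G" * 40, sites=[a])
        molB = DnaMolecule("B", "linear", "C" * 30 + b.site_seq() + "T" * 10, sites=[b])
        (ev,) = enumerate_events([molA, molB], {LAMBDA_INT_XIS})
        assert ev.mode == "linear_exchange"
        p1, p2 = recombine(ev, [molA, molB])
        assert len(p1) + len(p2) == len(molA) + len(molB)
        assert {p1.topology, p2.topology} == {"linear"}
        assert {s.state for m in (p1, p2) for s in m.sites} == {"B", "P"}

    def test_integration_into_linear(self, lib):
        c = lib.site("lambda", "1", "P", start=5)
        l = lib.site("lambda", "1", "B", start=40)
        circ = DnaMolecule("C", "circular", "A" * 5 + c.site_seq() + "G" * 30, sites=[c])
        lin = DnaMolecule("L", "linear", "C" * 40 + l.site_seq() + "T" * 20, sites=[l])
        (ev,) = enumerate_events([circ, lin], {LAMBDA_INT})
        assert ev.mode == "integration_into_linear"
        (prod,) = recombine(ev, [circ, lin])
        assert prod.topology == "linear"
        assert len(prod) == len(circ) + len(lin)
        assert sorted(s.state for s in prod.sites) == ["L", "R"]

    def test_inversion_preserves_sites_and_length(self, lib):
        import dataclasses

        f = lib.site("P1-lox", start=10)
        r = dataclasses.replace(lib.site("P1-lox"), orientation=-1, start=70)
        seq = "A" * 10 + f.site_seq() + "G" * (70 - f.end)
        from attasm.seqmodel import revcomp

        seq += revcomp(r.site_seq()) + "C" * 10
        mol = DnaMolecule("m", "circular", seq, sites=[f, r])
        (ev,) = enumerate_events([mol], {CRE})
        assert ev.mode == "inversion"
        (prod,) = recombine(ev, [mol])
        assert len(prod) == len(mol)
        assert len(prod.sites) == 2
        assert {s.orientation for s in prod.sites} == {1, -1}
        # still enumerable: inversion is reversible
        assert len(enumerate_events([prod], {CRE})) == 1

    def test_incompatible_event_reports(self, lib):
        b = circle(lib, "x", [("HK022", "", "B")])
        p = circle(lib, "y", [("HK022", "", "P")])
        ev = ReactionEvent(Enzyme("HK022", has_int=False), "x", 0, "y", 0, "fusion")
        with pytest.raises(IncompatibleEventError, match="needs Int"):
            recombine(ev, [b, p])


class TestEnumerate:
    def test_single_integration_event(self, lib):
        host = circle(lib, "host", [("HK022", "", "B")])
        unit = circle(lib, "unit", [("HK022", "", "P")])
        assert len(enumerate_events([host, unit], {HK022_INT})) == 1

    def test_empty_enzymes(self, lib):
        host = circle(lib, "host", [("HK022", "", "B")])
        assert enumerate_events([host], set()) == []

    def test_three_lox_gives_three_pairs(self, lib):
        mol = circle(lib, "m", [("P1-lox", "", "symmetric")] * 3)
        assert len(enumerate_events([mol], {CRE})) == 3

    def test_deterministic_order(self, lib):
        mols = [
            circle(lib, "b", [("P1-lox", "", "symmetric")]),
            circle(lib, "a", [("P1-lox", "", "symmetric")] * 2),
        ]
        evs = enumerate_events(mols, {CRE})
        assert [(e.mol_a, e.mol_b) for e in evs] == [("a", "a"), ("a", "b"), ("a", "b")]

    def test_antiparallel_att_pair_skipped(self, lib):
        import dataclasses

        l = lib.site("lambda", "1", "L", start=10)
        r = dataclasses.replace(lib.site("lambda", "1", "R"), orientation=-1, start=80)
        from attasm.seqmodel import revcomp

        seq = "A" * 10 + l.site_seq() + "G" * (80 - l.end) + revcomp(r.site_seq()) + "C" * 5
        mol = DnaMolecule("m", "circular", seq, sites=[l, r])
        assert enumerate_events([mol], {LAMBDA_INT_XIS}) == []


class TestEngineProperties:
    """Conservation, count law, reversibility, junction inactivation."""

    N_RANDOM = 500

    def _random_pair(self, rng, lib, k):
        system, variant = [("HK022", ""), ("lambda", "1"), ("lambda", "2"),
                           ("Phi80", ""), ("P1-lox", "")][k % 5]
        if system == "P1-lox":
            sa = sb = "symmetric"
        else:
            sa, sb = [("B", "P"), ("L", "R")][k % 2]
        pad_a = int(rng.integers(10, 60))
        pad_b = int(rng.integers(10, 60))
        topo = ["circular", "circular", "linear"][k % 3]
        a = lib.site(system, variant, sa, start=pad_a)
        b = lib.site(system, variant, sb, start=pad_b)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        molA = DnaMolecule("A", topo, base[:pad_a] + a.site_seq() + base[pad_a:pad_a + 40], sites=[a])
        molB = DnaMolecule("B", topo, base[60:60 + pad_b] + b.site_seq() + base[:30], sites=[b])
        return molA, molB

    def test_conservation_and_count_law(self, rng, lib):
        enzymes = {HK022_INT, HK022_INT_XIS, LAMBDA_INT_XIS, CRE,
                   Enzyme("Phi80", True, True)}
        delta_by_mode = {"fusion": -1, "excision": 1, "inversion": 0,
                         "linear_exchange": 0, "integration_into_linear": -1}
        checked = 0
        k = 0
        while checked < self.N_RANDOM:
            molA, molB = self._random_pair(rng, lib, k)
            k += 1
            events = enumerate_events([molA, molB], enzymes)
            for ev in events:
                prods = recombine(ev, [molA, molB])
                consumed = len({ev.mol_a, ev.mol_b})
                assert sum(len(p) for p in prods) == sum(
                    len(m) for m in (molA, molB) if m.id in {ev.mol_a, ev.mol_b}
                )
                assert len(prods) - consumed == delta_by_mode[ev.mode]
                checked += 1

    def test_bxp_lxr_roundtrip_identity(self, rng, lib):
        """Integration followed by excision across its own junctions restores
        the inputs up to rotation."""
        done = 0
        k = 0
        while done < 100:
            system, variant = [("HK022", ""), ("lambda", "1"), ("Phi80", "")][k % 3]
            k += 1
            pad_a, pad_b = int(rng.integers(8, 50)), int(rng.integers(8, 50))
            base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 160)])
            a = lib.site(system, variant, "B", start=pad_a)
            b = lib.site(system, variant, "P", start=pad_b)
            molA = DnaMolecule("A", "circular", base[:pad_a] + a.site_seq() + base[pad_a:pad_a + 35], sites=[a])
            molB = DnaMolecule("B", "circular", base[50:50 + pad_b] + b.site_seq() + base[:25], sites=[b])
            (ev,) = enumerate_events([molA, molB], {Enzyme(system, True, False)})
            (fused,) = recombine(ev, [molA, molB])
            (ev2,) = enumerate_events([fused], {Enzyme(system, True, True)})
            back = recombine(ev2, [fused])
            assert len(back) == 2
            matched = 0
            for orig in (molA, molB):
                for prod in back:
                    if molecules_equal(orig, prod):
                        matched += 1
                        break
            assert matched == 2
            done += 1

    def test_bxp_junction_inactive_under_int(self, lib):
        """After BxP the former junction cannot re-enumerate with Int only:
        active ends become inactive after the assembly reaction."""
        plas = circle(lib, "plas", [("HK022", "", "P")])
        chrom = circle(lib, "chrom", [("HK022", "", "B")])
        (ev,) = enumerate_events([plas, chrom], {HK022_INT})
        prods = recombine(ev, [plas, chrom])
        assert enumerate_events(prods, {HK022_INT}) == []

    def test_symmetric_sites_stay_reactive(self, lib):
        """loxP sites are unchanged by recombination and still enumerable:
        topology breakers must be reactive throughout."""
        a = circle(lib, "a", [("P1-lox", "", "symmetric")])
        b = circle(lib, "b", [("P1-lox", "", "symmetric")])
        (ev,) = enumerate_events([a, b], {CRE})
        (fused,) = recombine(ev, [a, b])
        assert [s.state for s in fused.sites] == ["symmetric", "symmetric"]
        assert len(enumerate_events([fused], {CRE})) == 1
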