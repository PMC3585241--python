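"""Host-cell simulation: replication logic, screening algebra, PCR."""

import numpy as np
import pytest

from attasm.cellsim import (
    CellState,
    PcrError,
    Population,
    conjugate,
    counter_select,
    induce,
    pcr_predict,
    replicable,
    select,
    transform,
)
from attasm.recombinase import HK022_INT
from attasm.seqmodel import DnaMolecule, Feature


def make_chrom(lib, site_state=None):
    sites = [lib.site("HK022", state=site_state, start=10)] if site_state else []
    seq = "A" * 10 + (sites[0].site_seq() if sites else "") + "G" * 60
    feats = [Feature("origin", "chromosomal", len(seq) - 20, len(seq) - 5)]
    return DnaMolecule("chrom", "circular", seq, feats, sites)


def make_plasmid(lib, ori="R6Kgamma", marker="kan", site_state="P", mol_id="plas"):
    sites = [lib.site("HK022", state=site_state, start=5)] if site_state else []
    seq = "C" * 5 + (sites[0].site_seq() if sites else "") + "T" * 80
    feats = []
    pos = len(seq) - 70
    if marker:
        feats.append(Feature("marker", marker, pos, pos + 20))
    if ori:
        feats.append(Feature("origin", ori, pos + 25, pos + 40))
    return DnaMolecule(mol_id, "circular", seq, feats, sites)


class TestReplicable:
    def test_r6k_requires_pir(self, lib):
        chrom = make_chrom(lib)
        plas = make_plasmid(lib)
        pir_neg = CellState(chrom, [plas], pir_positive=False)
        pir_pos = CellState(chrom.copy(), [plas.copy()], pir_positive=True)
        assert not replicable(pir_neg, plas)
        assert replicable(pir_pos, pir_pos.episomes[0])

    def test_chromosome_always_replicable(self, lib):
        cell = CellState(make_chrom(lib), [])
        assert replicable(cell, cell.chromosome)

    def test_standard_origin(self, lib):
        plas = make_plasmid(lib, ori="standard")
        cell = CellState(make_chrom(lib), [plas])
        assert replicable(cell, plas)


class TestTransformConjugate:
    def test_transform_adds_episome(self, lib):
        cell = CellState(make_chrom(lib), [])
        out = transform(cell, make_plasmid(lib))
        assert len(out.episomes) == 1
        assert len(cell.episomes) == 0  # input untouched

    def test_bare_linear_fragment_rejected(self, lib):
        frag = DnaMolecule("frag", "linear", "ACGT" * 20)
        with pytest.raises(ValueError, match="not maintainable"):
            transform(CellState(make_chrom(lib), []), frag)

    def test_n15_linear_accepted(self, lib):
        frag = DnaMolecule(
            "n15", "linear", "ACGT" * 20, [Feature("origin", "N15_linear", 0, 10)]
        )
        out = transform(CellState(make_chrom(lib), []), frag)
        assert out.episomes[0].id == "n15"

    def test_conjugate_moves_episome(self, lib):
        donor = CellState(make_chrom(lib), [make_plasmid(lib)])
        recipient = CellState(make_chrom(lib).copy("chrom2"), [])
        out = conjugate(donor, recipient)
        assert [m.id for m in out.episomes] == ["plas"]


class TestInduce:
    def test_two_outcomes_for_single_event(self, lib):
        cell = CellState(make_chrom(lib, "B"), [make_plasmid(lib, site_state="P")])
        outcomes = induce(cell, {HK022_INT})
        assert len(outcomes) == 2
        # integrated outcome first, unreacted cell last
        assert outcomes[0].episomes == []
        assert any(f.kind == "marker" for f in outcomes[0].chromosome.features)
        assert len(outcomes[-1].episomes) == 1

    def test_no_sites_single_outcome(self, lib):
        cell = CellState(make_chrom(lib), [])
        assert len(induce(cell, {HK022_INT})) == 1

    def test_two_integrable_units_three_outcomes(self, lib):
        cell = CellState(
            make_chrom(lib, "B"),
            [make_plasmid(lib, mol_id="u1"), make_plasmid(lib, mol_id="u2")],
        )
        assert len(induce(cell, {HK022_INT})) == 3


class TestSelection:
    def _pop(self, lib):
        chrom_kan = make_chrom(lib).copy("c1")
        chrom_kan.features.append(Feature("marker", "kan", 0, 8))
        cells = [
            CellState(chrom_kan, []),  # kan on chromosome
            CellState(make_chrom(lib).copy("c2"), [make_plasmid(lib)]),  # kan on R6K, pir-
            CellState(make_chrom(lib).copy("c3"), [make_plasmid(lib)], pir_positive=True),
            CellState(make_chrom(lib).copy("c4"), []),  # no marker
        ]
        return Population(cells)

    def test_selection_requires_replicable_marker(self, lib):
        pop = self._pop(lib)
        kept = select(pop, "kan")
        assert len(kept) == 2  # chromosomal kan and pir+ R6K kan survive

    def test_partition_and_idempotence(self, lib, rng):
        pop = self._pop(lib)
        for drug in ("kan", "cat", "gen"):
            kept = select(pop, drug)
            dropped = counter_select(pop, drug)
            assert len(kept) + len(dropped) == len(pop)
            assert {id(c) for c in kept.cells} | {id(c) for c in dropped.cells} == {
                id(c) for c in pop.cells
            }
            assert len(select(kept, drug)) == len(kept)
            assert len(counter_select(dropped, drug)) == len(dropped)

    def test_empty_population(self, lib):
        empty = Population([])
        assert len(select(empty, "kan")) == 0
        assert len(counter_select(empty, "kan")) == 0

    def test_unknown_drug_rejected(self, lib):
        with pytest.raises(ValueError):
            select(Population([]), "amp")


class TestPcr:
    def test_amplicon_with_single_scar(self, lib):
        site = lib.site("HK022", state="B", start=40)
        seq = "ACGTACGTGGATCCTTGACA" + "A" * 20 + site.site_seq() + "T" * 20 + "CATGGATGCCGTAGCTTGCA"
        mol = DnaMolecule("m", "circular", seq, sites=[site])
        fwd = seq[:18]
        from attasm.seqmodel import revcomp

        rev = revcomp(seq[-18:])
        amp = pcr_predict(mol, fwd, rev)
        assert amp == seq
        assert amp.count(site.core) == 1

    def test_absent_primer_errors_with_count(self, lib):
        mol = DnaMolecule("m", "linear", "ACGT" * 30)
        with pytest.raises(PcrError) as exc:
            pcr_predict(mol, "GGGGGGGGGGGG", "ACGTACGTACGT")
        assert exc.value.count == 0

    def test_multiple_binding_sites_error(self):
        mol = DnaMolecule("m", "linear", "ACGTACGTACGTACGT" * 4)
        with pytest.raises(PcrError):
            pcr_predict(mol, "ACGTACGTACG", "TTTTTTTTT")

    def test_wrap_around_amplicon(self):
        from attasm.seqmodel import revcomp

        mol = DnaMolecule("m", "circular", "GATTACAGATTACAGGCGCG" + "ACGTTGCAACGGTTAACCGG" * 2)
        fwd = mol.sequence[30:42]
        rev_rc_region = mol.sequence[5:15]  # upstream of fwd: amplicon wraps
        amp = pcr_predict(mol, fwd, revcomp(rev_rc_region))
        assert amp.startswith(fwd)
        assert amp.endswith(rev_rc_region)
        assert len(amp) == (15 - 30) % len(mol)
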