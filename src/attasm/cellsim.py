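"""Host-cell simulation: transformation, conditional replication, helper
induction, antibiotic selection / counter-selection, and PCR prediction.

A cell is one chromosome plus episomes, a pir genotype and a set of resident
recombinases. Selection is all-or-none per cell: a drug screen keeps exactly
the cells carrying that marker on a molecule the cell can replicate (the
R6Kgamma origin replicates only in pir+ hosts, which is what makes extracted
assembly plasmids screenable). Induction of helper enzymes yields one outcome
cell per feasible single recombination event plus the unreacted cell; the
screened, stepwise protocol then chooses among outcomes deterministically.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

from .recombinase import Enzyme, ReactionEvent, enumerate_events, recombine
from .seqmodel import DnaMolecule

__all__ = [
    "CellState",
    "Population",
    "replicable",
    "transform",
    "conjugate",
    "induce",
    "select",
    "counter_select",
    "PcrError",
    "pcr_predict",
]


@dataclass
class CellState:
    """One bacterial cell: chromosome, episomes, pir status, enzymes."""

    chromosome: DnaMolecule
    episomes: list[DnaMolecule] = field(default_factory=list)
    pir_positive: bool = False
    resident_enzymes: frozenset[Enzyme] = frozenset()

    def __post_init__(self) -> None:
        ids = [self.chromosome.id] + [m.id for m in self.episomes]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule ids within a cell must be unique")

    def molecules(self) -> list[DnaMolecule]:
        return [self.chromosome] + list(self.episomes)

    def copy(self) -> "CellState":
        return CellState(
            self.chromosome.copy(),
            [m.copy() for m in self.episomes],
            self.pir_positive,
            self.resident_enzymes,
        )


@dataclass
class Population:
    """A multiset of colonies; screening acts on whole cells."""

    cells: list[CellState] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cells)


def replicable(cell: CellState, mol: DnaMolecule) -> bool:
    """Can the cell maintain this molecule?

    True for the chromosome itself, for standard or N15-linear origins, and
    for R6Kgamma origins in a pir+ host.
    """
    if mol.id == cell.chromosome.id:
        return True
    for f in mol.features:
        if f.kind != "origin":
            continue
        if f.name in ("standard", "N15_linear", "chromosomal"):
            return True
        if f.name == "R6Kgamma" and cell.pir_positive:
            return True
    return False


def _maintainable_entry(mol: DnaMolecule) -> bool:
    # a bare linear fragment without N15 hairpin telomeres is degraded
    if mol.circular:
        return True
    return any(f.kind == "origin" and f.name == "N15_linear" for f in mol.features)


def transform(cell: CellState, mol: DnaMolecule) -> CellState:
    """Electroporate a molecule into the cell (no replication check at entry;
    selection enforces maintenance)."""
    if not _maintainable_entry(mol):
        raise ValueError(
            f"cannot transform {mol.id!r}: linear fragment without N15 telomeres "
            "is not maintainable"
        )
    out = cell.copy()
    entry = mol.copy()
    existing = {m.id for m in out.molecules()}
    if entry.id in existing:
        k = itertools.count(2)
        new_id = entry.id
        while new_id in existing:
            new_id = f"{mol.id}#{next(k)}"
        entry.id = new_id
    out.episomes.append(entry)
    return out


def conjugate(donor: CellState, recipient: CellState, mol_id: str | None = None) -> CellState:
    """Transfer a mobilisable episome from donor to recipient."""
    candidates = donor.episomes if mol_id is None else [
        m for m in donor.episomes if m.id == mol_id
    ]
    if not candidates:
        raise ValueError(f"donor has no episome {mol_id!r} to conjugate")
    return transform(recipient, candidates[0])


def _rebuild_cell(cell: CellState, event: ReactionEvent) -> CellState:
    mols = cell.molecules()
    consumed = {event.mol_a, event.mol_b}
    products = recombine(event, [m for m in mols if m.id in consumed])
    keep = [m.copy() for m in mols if m.id not in consumed]
    # the chromosome is whichever product (or survivor) carries the
    # chromosomal origin feature
    def is_chrom(m: DnaMolecule) -> bool:
        return any(f.kind == "origin" and f.name == "chromosomal" for f in m.features)

    pool = keep + products
    chrom = [m for m in pool if is_chrom(m)]
    if len(chrom) != 1:
        raise ValueError(
            f"event leaves {len(chrom)} chromosomal-origin molecules; expected 1"
        )
    episomes = [m for m in pool if m is not chrom[0]]
    return CellState(chrom[0], episomes, cell.pir_positive, cell.resident_enzymes)


def induce(cell: CellState, enzymes: set[Enzyme] | list[Enzyme]) -> list[CellState]:
    """Outcome cells after inducing helper enzymes.

    One outcome per feasible single recombination event, in the deterministic
    order of ``enumerate_events``, followed by the unreacted cell. Strategies
    iterate induction when a design requires sequential reactions.
    """
    events = enumerate_events(cell.molecules(), enzymes)
    outcomes = [_rebuild_cell(cell, ev) for ev in events]
    outcomes.append(cell.copy())
    return outcomes


def _has_selectable_marker(cell: CellState, drug: str) -> bool:
    for mol in cell.molecules():
        if not replicable(cell, mol):
            continue
        if any(f.kind == "marker" and f.name == drug for f in mol.features):
            return True
    return False


def select(pop: Population, drug: str) -> Population:
    """Keep cells resistant to the drug (marker on a replicable molecule)."""
    if drug not in ("kan", "cat", "gen"):
        raise ValueError(f"unknown drug {drug!r}")
    return Population([c for c in pop.cells if _has_selectable_marker(c, drug)])


def counter_select(pop: Population, drug: str) -> Population:
    """Replica screen: keep exactly the cells sensitive to the drug."""
    if drug not in ("kan", "cat", "gen"):
        raise ValueError(f"unknown drug {drug!r}")
    return Population([c for c in pop.cells if not _has_selectable_marker(c, drug)])


class PcrError(ValueError):
    def __init__(self, primer: str, count: int, which: str):
        super().__init__(
            f"{which} primer {primer!r} has {count} binding site(s); need exactly 1"
        )
        self.count = count


def _find_all(template: str, probe: str, circular: bool) -> list[int]:
    hay = template + (template[: len(probe) - 1] if circular else "")
    hits, i = [], hay.find(probe)
    while i != -1:
        hits.append(i)
        i = hay.find(probe, i + 1)
    return hits


def pcr_predict(mol: DnaMolecule, fwd: str, rev: str) -> str:
    """Predicted amplicon (inclusive of both primer footprints).

    Primers must match exactly (case-insensitive), once each: the forward
    primer on the forward strand, the reverse primer on the reverse strand.
    Supports circular templates where the amplicon wraps the origin.
    """
    from .seqmodel import revcomp

    seq = mol.sequence.upper()
    f, r = fwd.upper(), rev.upper()
    fhits = _find_all(seq, f, mol.circular)
    if len(fhits) != 1:
        raise PcrError(fwd, len(fhits), "forward")
    rhits = _find_all(seq, revcomp(r), mol.circular)
    if len(rhits) != 1:
        raise PcrError(rev, len(rhits), "reverse")
    start = fhits[0]
    end = rhits[0] + len(r)
    if end <= start:
        if not mol.circular:
            raise PcrError(rev, 0, "reverse (downstream of forward)")
        end += len(seq)
    if end - start > len(seq):
        raise PcrError(rev, 0, "reverse (primers do not converge)")
    return mol.seg(start, end)
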