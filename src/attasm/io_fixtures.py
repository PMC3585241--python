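"""GenBank/FASTA I/O, run configuration, synthetic unit libraries and the
in silico five-gene demonstration.

Recombination sites are encoded in GenBank flat files as ``misc_recomb``
features whose qualifiers carry the system/variant/state/orientation and the
arm/core strings, so a write/read round trip reproduces the canonical
molecule bit-exactly. Payload genes, markers and origins map to standard
gene/CDS/rep_origin features.

The fixture generator emulates the published unit-plasmid design: a payload
open reading frame flanked by reactive-end att sites, a kan marker, an
R6Kgamma conditional origin and a topology breaker, with parity alternating
between the attR and attP unit versions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .cellsim import CellState, Population
from .planner import MergeNode, MergeTree, build_merge_tree
from .recombinase import enumerate_events
from .seqmodel import (
    DnaMolecule,
    Feature,
    RecombSite,
    SiteFamily,
    canonicalize,
    find_sites,
)
from .sitelib import SiteLibrary, default_library
from .strategies import (
    SRAS,
    EventLog,
    StrategyTemplate,
    _sras_run,
    build_dras_unit,
    build_sras_host,
    build_sras_unit,
    build_tras_unit,
    get_template,
    payload_order,
    required_parities,
)

logger = logging.getLogger("attasm")

__all__ = [
    "FixtureSpec",
    "parse_config",
    "read_genbank",
    "write_genbank",
    "read_fasta",
    "write_fasta",
    "random_orf",
    "make_unit_library",
    "make_tras_chain",
    "TRAS_SIX_VECTOR_SCHEME",
    "lux_demo",
    "save_population",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic unit library; the seed fully determines
    every output byte."""

    n_units: int = 5
    payload_length: int = 1200
    gc_fraction: float = 0.5
    seed: int = 0
    decorate_t7: bool = False
    strategy: str = "SRAS"

    def __post_init__(self) -> None:
        if self.payload_length < 30:
            raise ValueError("payload_length must be >= 30")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


_BOOL = {"true": True, "false": False, "1": True, "0": False, "yes": True, "no": False}


def parse_config(text: str) -> FixtureSpec:
    """Parse a flat key = value configuration into a FixtureSpec.

    Unknown keys are errors; '#' starts a comment.
    """
    fields = {f.name: f.type for f in dataclasses.fields(FixtureSpec)}
    kwargs: dict = {}
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"config line {lineno}: expected 'key = value'")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in fields:
            raise ValueError(f"config line {lineno}: unknown key {key!r}")
        if key in ("n_units", "payload_length", "seed"):
            kwargs[key] = int(value)
        elif key == "gc_fraction":
            kwargs[key] = float(value)
        elif key == "decorate_t7":
            try:
                kwargs[key] = _BOOL[value.lower()]
            except KeyError:
                raise ValueError(f"config line {lineno}: bad boolean {value!r}")
        else:
            kwargs[key] = value
    return FixtureSpec(**kwargs)


# ---------------------------------------------------------------------------
# GenBank round trip
# ---------------------------------------------------------------------------

_KIND_TO_GB = {
    "payload": "gene",
    "marker": "CDS",
    "origin": "rep_origin",
    "promoter": "promoter",
    "terminator": "terminator",
    "landing_pad": "misc_feature",
}
_GB_TO_KIND = {v: k for k, v in _KIND_TO_GB.items()}


def _location(start: int, end: int, n: int, strand: int):
    if end <= n:
        return SimpleLocation(start, end, strand)
    # span wraps the origin of a circular record: encode as a join
    return CompoundLocation(
        [SimpleLocation(start, n, strand), SimpleLocation(0, end - n, strand)]
    )


def _mol_to_record(mol: DnaMolecule) -> SeqRecord:
    rec = SeqRecord(
        Seq(mol.sequence),
        id=mol.id[:20] or "mol",
        name=(mol.id[:16] or "mol"),
        description="",
        annotations={"molecule_type": "DNA", "topology": mol.topology},
    )
    n = len(mol)
    for f in mol.features:
        rec.features.append(
            SeqFeature(
                _location(f.start, f.end, n, f.strand),
                type=_KIND_TO_GB[f.kind],
                qualifiers={"label": [f.name], "assembly_kind": [f.kind]},
            )
        )
    for s in mol.sites:
        rec.features.append(
            SeqFeature(
                _location(s.start, s.end, n, s.orientation),
                type="misc_recomb",
                qualifiers={
                    "recombination_system": [s.family.system],
                    "variant": [s.family.variant or "."],
                    "site_state": [s.state],
                    "left_arm": [s.left_arm],
                    "core": [s.core],
                    "right_arm": [s.right_arm],
                    "label": [f"att{s.state}_{s.family}" if not s.family.symmetric else str(s.family)],
                },
            )
        )
    return rec


def _record_to_mol(rec: SeqRecord) -> DnaMolecule:
    topology = rec.annotations.get("topology", "linear")
    n = len(rec.seq)
    features: list[Feature] = []
    sites: list[RecombSite] = []
    for f in rec.features:
        loc = f.location
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start), reverse=True)
            start = int(parts[0].start)
            end = start + sum(len(p) for p in parts)
            strand = parts[0].strand or 1
        else:
            start, end, strand = int(loc.start), int(loc.end), loc.strand or 1
        if f.type == "misc_recomb":
            q = f.qualifiers
            if "recombination_system" not in q:
                continue  # foreign recombination annotation without our tags
            variant = q.get("variant", ["."])[0]
            sites.append(
                RecombSite(
                    family=SiteFamily(
                        q["recombination_system"][0],
                        "" if variant == "." else variant,
                    ),
                    state=q["site_state"][0],
                    orientation=strand,
                    start=start,
                    left_arm=q["left_arm"][0],
                    core=q["core"][0],
                    right_arm=q["right_arm"][0],
                )
            )
        elif f.type in _GB_TO_KIND:
            kind = f.qualifiers.get("assembly_kind", [_GB_TO_KIND[f.type]])[0]
            name = f.qualifiers.get("label", [f.type])[0]
            features.append(Feature(kind, name, start, end, strand))
    return DnaMolecule(rec.id, topology, str(rec.seq), features, sites)


def write_genbank(mols: list[DnaMolecule] | DnaMolecule, path: str | Path) -> None:
    if isinstance(mols, DnaMolecule):
        mols = [mols]
    SeqIO.write([_mol_to_record(m) for m in mols], str(path), "genbank")


def read_genbank(path: str | Path) -> list[DnaMolecule]:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed GenBank record: {exc}") from exc
    if not records:
        raise ValueError(f"{path}: no GenBank records found")
    return [_record_to_mol(r) for r in records]


# ---------------------------------------------------------------------------
# FASTA + sidecar annotation table
# ---------------------------------------------------------------------------

def write_fasta(
    mols: list[DnaMolecule], fasta_path: str | Path, sidecar_path: str | Path
) -> None:
    """Bare sequences as FASTA plus a TSV sidecar with the annotations."""
    records = [
        SeqRecord(Seq(m.sequence), id=m.id, description=f"topology={m.topology}")
        for m in mols
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    lines = ["id\tkind\tstart\tend\tstrand\tlabels"]
    for m in mols:
        for f in m.features:
            lines.append(f"{m.id}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\tname={f.name}")
        for s in m.sites:
            labels = (
                f"system={s.family.system};variant={s.family.variant};state={s.state};"
                f"left_arm={s.left_arm};core={s.core};right_arm={s.right_arm}"
            )
            lines.append(f"{m.id}\tsite\t{s.start}\t{s.end}\t{s.orientation}\t{labels}")
    Path(sidecar_path).write_text("\n".join(lines) + "\n")


def read_fasta(fasta_path: str | Path, sidecar_path: str | Path) -> list[DnaMolecule]:
    seqs = {}
    topo = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq)
        topo[rec.id] = "circular" if "topology=circular" in rec.description else "linear"
    feats: dict[str, list[Feature]] = {k: [] for k in seqs}
    sites: dict[str, list[RecombSite]] = {k: [] for k in seqs}
    text = Path(sidecar_path).read_text()
    for lineno, line in enumerate(text.splitlines()[1:], 2):
        if not line.strip():
            continue
        mid, kind, start, end, strand, labels = line.split("\t")
        lab = dict(kv.split("=", 1) for kv in labels.split(";") if kv)
        if mid not in seqs:
            raise ValueError(f"sidecar line {lineno}: unknown molecule {mid!r}")
        if kind == "site":
            sites[mid].append(
                RecombSite(
                    SiteFamily(lab["system"], lab.get("variant", "")),
                    lab["state"],
                    int(strand),
                    int(start),
                    lab["left_arm"],
                    lab["core"],
                    lab["right_arm"],
                )
            )
        else:
            feats[mid].append(Feature(kind, lab["name"], int(start), int(end), int(strand)))
    return [
        DnaMolecule(mid, topo[mid], seqs[mid], feats[mid], sites[mid]) for mid in seqs
    ]


# ---------------------------------------------------------------------------
# synthetic payloads and unit libraries
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


def random_orf(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """A random open reading frame: ATG, non-stop codons at the requested GC
    content, and a TAA stop. Length is rounded down to a codon multiple."""
    n_codons = max(length // 3, 4) - 2
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    bases = np.array(list("ACGT"))
    codons: list[str] = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(bases, size=3, p=p))
        if c not in _STOPS:
            codons.append(c)
    return "ATG" + "".join(codons) + "TAA"


#: the six Bi-Swap vector types X-DNA-Y: three markers x two directions
TRAS_SIX_VECTOR_SCHEME = (
    ("cat", "gen"),
    ("gen", "kan"),
    ("kan", "cat"),
    ("gen", "cat"),
    ("kan", "gen"),
    ("cat", "kan"),
)


def _payloads(spec: FixtureSpec, names: list[str] | None = None) -> list[tuple[str, str]]:
    rng = np.random.default_rng(spec.seed)
    names = names or [f"Syn{i+1}" for i in range(spec.n_units)]
    out = []
    for name in names:
        # lengths jitter by up to 25% to mimic a natural gene set
        length = int(spec.payload_length * (1.0 + 0.25 * rng.random()))
        out.append((name, random_orf(rng, length, spec.gc_fraction)))
    return out


def make_unit_library(
    spec: FixtureSpec,
    tree: MergeTree | None = None,
    names: list[str] | None = None,
    lib: SiteLibrary | None = None,
) -> tuple[list[DnaMolecule], CellState]:
    """Deterministic unit plasmids plus the matching assembly host.

    SRAS/DRAS units alternate parity (attR/attP versions) — or follow the
    merge tree's required parities when one is given. TRAS units follow the
    six-vector marker scheme (three markers x two directions).
    """
    lib = lib or default_library()
    template = get_template(spec.strategy)
    payloads = _payloads(spec, names)
    units: list[DnaMolecule] = []
    if spec.strategy in ("SRAS",):
        if tree is not None:
            parities = required_parities(tree)
        else:
            parities = [(i % 2) + 1 for i in range(spec.n_units)]
        for (name, seq), parity in zip(payloads, parities):
            u = build_sras_unit(name, seq, parity, lib, template)
            if spec.decorate_t7:
                u = _decorate_t7(u)
            units.append(u)
        host = build_sras_host(lib, template)
    elif spec.strategy == "DRAS":
        from .strategies import build_dras_host

        for i, (name, seq) in enumerate(payloads):
            units.append(build_dras_unit(name, seq, i + 1, lib, template))
        host = build_dras_host(lib, template)
    elif spec.strategy in ("TRAS", "TRAS_conj", "LINEAR_TRAS"):
        for i, (name, seq) in enumerate(payloads):
            left, right = TRAS_SIX_VECTOR_SCHEME[i % 6]
            units.append(build_tras_unit(name, seq, left, right, "2", "1", lib, template))
        host = build_sras_host(lib, SRAS, host_id="SCREEN_HOST")
    else:
        raise ValueError(f"no sequence-level library for strategy {spec.strategy!r}")
    return units, host


def make_tras_chain(
    spec: FixtureSpec,
    names: list[str] | None = None,
    lib: SiteLibrary | None = None,
) -> list[DnaMolecule]:
    """TRAS units with rotating chain-compatible flanks (C-G, G-K, K-C, ...)
    and alternating junction end variants, mergeable in order."""
    lib = lib or default_library()
    template = get_template(spec.strategy if spec.strategy.startswith(("TRAS", "LINEAR")) else "TRAS")
    payloads = _payloads(spec, names)
    cycle = ("cat", "gen", "kan")

    def jv(j: int) -> str:  # junction end variant alternates
        return "1" if j % 2 == 1 else "2"

    units = []
    for i, (name, seq) in enumerate(payloads, start=1):
        units.append(
            build_tras_unit(
                name, seq, cycle[(i - 1) % 3], cycle[i % 3], jv(i - 1), jv(i), lib, template
            )
        )
    return units


def _decorate_t7(unit: DnaMolecule) -> DnaMolecule:
    """Optionally flank the payload with a T7 promoter/terminator cassette
    (not a necessary part of the assembly unit)."""
    out = unit.copy()
    pay = [f for f in out.features if f.kind == "payload"]
    if not pay:
        return out
    f = pay[0]
    prom = "TAATACGACTCACTATAGGG"
    term = "TAGCATAACCCCTTGGGGCCTCTAAACGGGTCTTGAGGGGTTTTTTG"
    n = len(out)
    seq = out.sequence[: f.start] + prom + out.sequence[f.start : f.end] + term + out.sequence[f.end :]
    shift_at = f.start
    d_prom = len(prom)
    d_term = len(term)

    def shift(pos: int) -> int:
        if pos < shift_at:
            return pos
        if pos <= f.end:
            return pos + d_prom
        return pos + d_prom + d_term

    feats = [
        Feature(g.kind, g.name, shift(g.start), shift(g.start) + (g.end - g.start), g.strand)
        for g in out.features
    ]
    feats.append(Feature("promoter", "T7", f.start, f.start + d_prom))
    feats.append(
        Feature("terminator", "T7term", f.end + d_prom, f.end + d_prom + d_term)
    )
    sites = [
        dataclasses.replace(s, start=shift(s.start) if s.start < n else s.start)
        for s in out.sites
    ]
    return DnaMolecule(out.id, out.topology, seq, feats, sites)


# ---------------------------------------------------------------------------
# the five-gene in silico demonstration
# ---------------------------------------------------------------------------

@dataclass
class JunctionReport:
    """One inter-payload junction of the final chromosome: the diagnostic
    scar left by the merge that created it."""

    left: str
    right: str
    system: str
    state: str
    core: str
    n_sites: int  # total sites in the junction interval (flank leftovers)


def _junction_report(chrom: DnaMolecule, template: StrategyTemplate) -> list[JunctionReport]:
    from .strategies import _region_order

    anat = _region_order(chrom, template)
    n = len(chrom)
    origin = anat.phi_left.start if anat.phi_left else 0

    def key(p: int) -> int:
        return (p - origin) % n

    pays = anat.payloads
    reports = []
    for left, right in zip(pays, pays[1:]):
        inside = [
            s
            for s in chrom.sites
            if key(left.end) <= key(s.start) and key(s.end) <= key(right.start)
        ]
        inside.sort(key=lambda s: key(s.start))
        # the diagnostic scar: the breaker-system attB if the junction came
        # from a plasmid merge, else the single reactive-end attB scar
        breaker = [s for s in inside if s.family.system == template.breaker_system and s.state == "B"]
        scar = breaker[0] if breaker else inside[0]
        reports.append(
            JunctionReport(
                left.name, right.name, scar.family.system, scar.state, scar.core, len(inside)
            )
        )
    return reports


def lux_demo(
    seed: int = 0, payload_length: int = 1200, lib: SiteLibrary | None = None
) -> tuple[CellState, EventLog, list[JunctionReport]]:
    """Re-execute the five-gene demonstration on synthetic payloads.

    Two host strains assemble payloads D,C (two cycles) and E,B,A (three
    cycles); the D-C region is extracted as a plasmid and integrated into the
    second strain by HK022 attP x attB recombination, then the extraction
    backbone is excised. The final chromosome carries the payloads in the
    order D, C, E, B, A with one diagnostic att scar per merge junction.
    """
    lib = lib or default_library()
    spec = FixtureSpec(n_units=5, payload_length=payload_length, seed=seed)
    names = ["LuxD", "LuxC", "LuxE", "LuxB", "LuxA"]
    # plan shape: (D,C) branch, (E,B,A) branch, final plasmid integration
    dc = MergeNode(children=[MergeNode(leaf=0), MergeNode(leaf=1)])
    abe = MergeNode(children=[MergeNode(leaf=2), MergeNode(leaf=3), MergeNode(leaf=4)])
    root = MergeNode(children=[dc, abe])
    tree = MergeTree(names, root)
    units, _ = make_unit_library(spec, tree=tree, names=names, lib=lib)
    log = EventLog()
    host = _sras_run(SRAS, units, tree, log, lib)
    report = _junction_report(host.chromosome, SRAS)
    logger.info(
        "lux demo complete: payload order %s", payload_order(host.chromosome)
    )
    return host, log, report


# ---------------------------------------------------------------------------
# population snapshots
# ---------------------------------------------------------------------------

def save_population(pop: Population, directory: str | Path) -> None:
    """Write each cell's molecules as GenBank plus a manifest TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = ["cell_id\tmolecule_ids\tpir_positive\tenzymes"]
    for i, cell in enumerate(pop.cells):
        cid = f"cell{i:04d}"
        write_genbank(cell.molecules(), directory / f"{cid}.gb")
        enz = ";".join(sorted(str(e) for e in cell.resident_enzymes))
        mids = ";".join(m.id for m in cell.molecules())
        lines.append(f"{cid}\t{mids}\t{int(cell.pir_positive)}\t{enz}")
    (directory / "manifest.tsv").write_text("\n".join(lines) + "\n")
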