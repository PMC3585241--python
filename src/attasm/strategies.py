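"""Executable assembly strategies and the three-rule validity checker.

Encodes the single-, double- and triple-selective-marker recombination
assembly systems as screened, stepwise protocols over the recombination
engine:

* SRAS (In/Out-Extract): a unit plasmid integrates into the host chromosome
  at its reactive ends (mutated lambda attL/attR pairs), the vector backbone
  is excised at the topology breakers (HK022 att sites), and kanamycin
  selection then counter-selection leave the unique screened recombinant.
  Assembled regions pop out as plasmids by Phi80 attL x attR recombination,
  replicable only in pir+ hosts via their R6Kgamma origin.
* DRAS (Swap-Extract): reactive-end recombination and frt topology breaking
  occur concurrently; recombinants are screened by substitution of the
  antibiotic marker (kan <-> cat).
* Bi-Swap TRAS: junction-marker exchange between unit plasmids, no host
  integration; circular inputs pass through a fusion intermediate carrying
  all three markers that is resolved at loxP and removed by counter-selection.
  The linear variant (N15 hairpin plasmids) exchanges arms directly.

Every design must obey three rules: (1) reactive ends become inactive after
assembly, (2) topology breakers stay reactive throughout, and (3) assembled
products have the same structure as assembly units so another round can
proceed. ``validate_strategy`` checks all three by executing a two-unit
assembly on synthetic payloads.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

from .cellsim import (
    CellState,
    Population,
    counter_select,
    replicable,
    select,
    transform,
)
from .planner import CATEGORIES, MergeNode, MergeTree, OpLedger
from .recombinase import (
    CRE,
    FLP,
    HK022_INT,
    HK022_INT_XIS,
    LAMBDA_INT_XIS,
    PHI80_INT_XIS,
    Enzyme,
    ReactionEvent,
    enumerate_events,
    recombine,
)
from .seqmodel import DnaMolecule, Feature, RecombSite, find_sites
from .sitelib import SiteLibrary, default_library

__all__ = [
    "StrategyError",
    "StrategyTemplate",
    "RuleResult",
    "RuleReport",
    "EventLog",
    "LogEntry",
    "get_template",
    "shipped_templates",
    "mutant_templates",
    "build_sras_host",
    "build_sras_unit",
    "build_dras_host",
    "build_dras_unit",
    "build_tras_unit",
    "sras_cycle",
    "sras_extract",
    "sras_integrate_plasmid",
    "dras_swap",
    "tras_merge",
    "run_assembly",
    "validate_strategy",
    "required_parities",
]


class StrategyError(ValueError):
    """An assembly phase could not proceed; message carries the diagnosis."""


# ---------------------------------------------------------------------------
# deterministic pseudo-sequences for markers, origins and spacers
# ---------------------------------------------------------------------------

def _pseudo_seq(label: str, n: int) -> str:
    out: list[str] = []
    h = hashlib.sha256(label.encode()).digest()
    while len(out) < n:
        out.extend("ACGT"[b & 3] for b in h)
        h = hashlib.sha256(h).digest()
    return "".join(out[:n])


_MARKER_LEN = 36
_ORI_LEN = 24
_SPACER = "TTAC"


class _MolBuilder:
    def __init__(self, mol_id: str, topology: str):
        self.id = mol_id
        self.topology = topology
        self.seq: list[str] = []
        self.pos = 0
        self.features: list[Feature] = []
        self.sites: list[RecombSite] = []

    def spacer(self, seq: str = _SPACER) -> "_MolBuilder":
        self.seq.append(seq)
        self.pos += len(seq)
        return self

    def site(self, proto: RecombSite) -> "_MolBuilder":
        s = replace(proto, start=self.pos)
        self.seq.append(s.forward_seq())
        self.pos += s.length
        self.sites.append(s)
        self.spacer()
        return self

    def feature(self, kind: str, name: str, seq: str, strand: int = 1) -> "_MolBuilder":
        self.features.append(Feature(kind, name, self.pos, self.pos + len(seq), strand))
        self.seq.append(seq)
        self.pos += len(seq)
        self.spacer()
        return self

    def marker(self, name: str) -> "_MolBuilder":
        return self.feature("marker", name, _pseudo_seq(f"marker:{name}", _MARKER_LEN))

    def origin(self, name: str) -> "_MolBuilder":
        return self.feature("origin", name, _pseudo_seq(f"origin:{name}", _ORI_LEN))

    def payload(self, name: str, seq: str) -> "_MolBuilder":
        return self.feature("payload", name, seq)

    def build(self) -> DnaMolecule:
        return DnaMolecule(self.id, self.topology, "".join(self.seq), self.features, self.sites)


# ---------------------------------------------------------------------------
# strategy templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategyTemplate:
    """A named assembly design: layouts, schedule, screening and costs.

    ``op_costs`` maps cost bases (leaf, node, merge, internal_node,
    extraction, nonfinal_extraction, plasmid_side_internal) to per-category
    operation counts; the planner multiplies them by merge-tree statistics.
    GIBSON and BIOBRICK carry cost tables only (no sequence-level schedule).
    """

    name: str
    arity: int = 2
    # sequence-level machinery (None for cost-only templates)
    end_system: str | None = None  # reactive-end recombination system
    end_variants: tuple[str, ...] = ("1", "2")
    breaker_system: str | None = None
    breaker_states_supplied: frozenset[str] = frozenset({"R", "P"})
    extraction_system: str | None = None
    marker_cycle: tuple[str, ...] = ("kan",)
    topology: str = "circular"
    ex_has_origin: bool = True
    unit_layout: tuple[str, ...] = ()
    product_schema: tuple[tuple, ...] = ()
    reaction_schedule: tuple[str, ...] = ()
    screening_plan: tuple[str, ...] = ()
    op_costs: dict = field(default_factory=dict, hash=False)

    @property
    def has_schedule(self) -> bool:
        return self.end_system is not None

    @property
    def ends_symmetric(self) -> bool:
        from .seqmodel import SYMMETRIC_SYSTEMS

        return self.end_system in SYMMETRIC_SYSTEMS

    def end_enzyme(self) -> Enzyme:
        if self.ends_symmetric:
            return Enzyme(self.end_system, True, False)
        return Enzyme(self.end_system, True, True)


def _sras_product_schema() -> tuple[tuple, ...]:
    return (
        ("site", "lambda", frozenset({"L"})),
        ("marker", None),
        ("origin", "R6Kgamma"),
        ("site", "HK022", frozenset({"R", "P"})),
        ("site", "lambda", frozenset({"R"})),
        ("payload", None),
    )


_TEMPLATES: dict[str, StrategyTemplate] = {}


def _register(t: StrategyTemplate) -> StrategyTemplate:
    _TEMPLATES[t.name] = t
    return t


SRAS = _register(
    StrategyTemplate(
        name="SRAS",
        end_system="lambda",
        breaker_system="HK022",
        breaker_states_supplied=frozenset({"R", "P"}),
        extraction_system="Phi80",
        marker_cycle=("kan",),
        unit_layout=(
            "attL<v> reactive end",
            "kan marker",
            "R6Kgamma origin",
            "attR/attP HK022 topology breaker",
            "attR<v'> next-round end",
            "payload",
        ),
        product_schema=_sras_product_schema(),
        reaction_schedule=("integrate", "select", "excise", "counter_select", "extract"),
        screening_plan=("select kan", "counter-select kan"),
        # liquid/electroporation/plate coefficients beyond the PCR and
        # plasmid-extraction entries are calibrated bookkeeping, not derived
        # from the per-node/per-merge model (see methods note)
        op_costs={
            "leaf": {"plasmid_extraction": 1},
            "merge": {
                "pcr_verification": 2,
                "incubation_liquid": 5,
                "electroporation": 5,
                "incubation_plate": 9,
            },
            "plasmid_side_internal": {
                "incubation_liquid": 2,
                "electroporation": 1,
                "incubation_plate": 1,
            },
            "extraction": {"plasmid_extraction": 1},
            "nonfinal_extraction": {"pcr_verification": 1},
        },
    )
)

DRAS = _register(
    StrategyTemplate(
        name="DRAS",
        end_system="lambda",
        breaker_system="FLP-frt",
        breaker_states_supplied=frozenset({"symmetric"}),
        extraction_system="Phi80",
        marker_cycle=("kan", "cat"),
        unit_layout=(
            "attL<v> reactive end",
            "R6Kgamma origin",
            "frt topology breaker",
            "marker (alternating kan/cat)",
            "attR<v'> next-round end",
            "payload",
        ),
        product_schema=(
            ("site", "FLP-frt", frozenset({"symmetric"})),
            ("marker", None),
            ("site", "lambda", frozenset({"R"})),
            ("payload", None),
            ("origin", None),
        ),
        reaction_schedule=("swap", "select", "counter_select", "extract"),
        screening_plan=("select new marker", "counter-select old marker"),
        op_costs={
            "leaf": {"plasmid_extraction": 1},
            "merge": {
                "pcr_verification": 2,
                "incubation_liquid": 2,
                "electroporation": 2,
                "incubation_plate": 3,
            },
            "extraction": {"plasmid_extraction": 1},
            "nonfinal_extraction": {"pcr_verification": 1},
        },
    )
)

_TRAS_SCHEMA = (
    ("site", "P1-lox", frozenset({"symmetric"})),
    ("marker", None),
    ("site", "lambda", frozenset({"R"})),
    ("payload", None),
    ("site", "lambda", frozenset({"L"})),
    ("marker", None),
    ("origin", None),
)

TRAS = _register(
    StrategyTemplate(
        name="TRAS",
        end_system="lambda",
        breaker_system="P1-lox",
        breaker_states_supplied=frozenset({"symmetric"}),
        marker_cycle=("cat", "gen", "kan"),
        unit_layout=(
            "loxP topology breaker",
            "left flank marker",
            "attR<v> reactive end",
            "payload",
            "attL<v'> reactive end",
            "right flank marker",
            "standard origin",
        ),
        product_schema=_TRAS_SCHEMA,
        reaction_schedule=("co-transform", "fuse", "resolve", "screen"),
        screening_plan=("select flank markers", "counter-select junction marker"),
        op_costs={
            "node": {"incubation_liquid": 1, "plasmid_extraction": 1},
            "merge": {"electroporation": 1, "pcr_verification": 1, "incubation_plate": 1},
        },
    )
)

TRAS_CONJ = _register(
    replace(
        TRAS,
        name="TRAS_conj",
        reaction_schedule=("conjugate", "fuse", "resolve", "screen"),
        op_costs={
            "node": {"incubation_liquid": 1},
            "merge": {"conjugation": 1, "pcr_verification": 1, "incubation_plate": 1},
        },
    )
)

LINEAR_TRAS = _register(
    replace(
        TRAS,
        name="LINEAR_TRAS",
        topology="linear",
        breaker_system=None,  # linear ends are the topology breakers
        breaker_states_supplied=frozenset(),
        unit_layout=(
            "N15 hairpin end (topology breaker)",
            "left flank marker",
            "attR<v> reactive end",
            "payload",
            "attL<v'> reactive end",
            "right flank marker",
            "N15 hairpin end",
        ),
        product_schema=(
            ("marker", None),
            ("site", "lambda", frozenset({"R"})),
            ("payload", None),
            ("site", "lambda", frozenset({"L"})),
            ("marker", None),
        ),
        reaction_schedule=("co-transform", "exchange", "screen"),
        op_costs={
            "node": {"incubation_liquid": 1, "plasmid_extraction": 1},
            "merge": {"electroporation": 1, "pcr_verification": 1, "incubation_plate": 1},
        },
    )
)

GIBSON = _register(
    StrategyTemplate(
        name="GIBSON",
        arity=4,
        op_costs={
            "node": {
                "incubation_liquid": 1,
                "plasmid_extraction": 1,
                "digestion": 1,
                "dna_extraction": 1,
            },
            "internal_node": {
                "gibson_assembly": 1,
                "electroporation": 1,
                "pcr_verification": 1,
                "incubation_plate": 1,
            },
        },
    )
)

BIOBRICK = _register(
    StrategyTemplate(
        name="BIOBRICK",
        op_costs={
            "node": {
                "incubation_liquid": 1,
                "plasmid_extraction": 1,
                "digestion": 1,
                "dna_extraction": 1,
            },
            "merge": {
                "ligation": 1,
                "electroporation": 1,
                "pcr_verification": 1,
                "incubation_plate": 1,
            },
        },
    )
)


def get_template(name: str) -> StrategyTemplate:
    try:
        return _TEMPLATES[name]
    except KeyError:
        raise KeyError(f"unknown strategy template {name!r}; have {sorted(_TEMPLATES)}")


def shipped_templates() -> dict[str, StrategyTemplate]:
    return dict(_TEMPLATES)


def mutant_templates() -> dict[str, StrategyTemplate]:
    """Three documented rule-breaking mutants of the SRAS design.

    * symmetric_ends: loxP reactive ends stay reactive after assembly
      (breaks Rule 1).
    * inert_breaker: every unit supplies an attR breaker, so after one cycle
      the chromosomal attB breaker has no reaction partner (breaks Rule 2).
    * missing_origin: the extraction vector carries no origin, so the
      extracted product no longer has the unit structure (breaks Rule 3).
    """
    return {
        "symmetric_ends": replace(
            SRAS,
            name="SRAS_symmetric_ends",
            end_system="P1-lox",
            end_variants=("", ""),
            product_schema=(
                ("site", "P1-lox", frozenset({"symmetric"})),
                ("marker", None),
                ("origin", "R6Kgamma"),
                ("site", "HK022", frozenset({"R", "P"})),
                ("site", "P1-lox", frozenset({"symmetric"})),
                ("payload", None),
            ),
        ),
        "inert_breaker": replace(
            SRAS, name="SRAS_inert_breaker", breaker_states_supplied=frozenset({"R"})
        ),
        "missing_origin": replace(SRAS, name="SRAS_missing_origin", ex_has_origin=False),
    }


# ---------------------------------------------------------------------------
# fixture molecule builders
# ---------------------------------------------------------------------------

def _end_site(t: StrategyTemplate, lib: SiteLibrary, state: str, variant: str) -> RecombSite:
    if t.ends_symmetric:
        return lib.site(t.end_system)
    return lib.site(t.end_system, variant, state)


def build_sras_host(
    lib: SiteLibrary | None = None,
    template: StrategyTemplate = SRAS,
    host_id: str = "HOST",
) -> CellState:
    """Fresh assembly host: chromosome with the TARGET landing region.

    Region layout (left to right): attL_Phi80 extraction site, topology
    breaker in the attL state, reactive end attR (variant 1), attR_Phi80.
    """
    lib = lib or default_library()
    b = _MolBuilder(host_id, "circular")
    b.spacer("GG")
    b.site(lib.site(template.extraction_system, state="L"))
    if template.breaker_system and template.name.startswith("SRAS"):
        b.site(lib.site(template.breaker_system, state="L"))
    b.site(_end_site(template, lib, "R", template.end_variants[0]))
    b.site(lib.site(template.extraction_system, state="R"))
    b.feature("landing_pad", "target_flank", _pseudo_seq("host:flank", 40))
    b.origin("chromosomal")
    chrom = b.build()
    return CellState(chromosome=chrom, pir_positive=False)


def build_sras_unit(
    payload_name: str,
    payload_seq: str,
    parity: int,
    lib: SiteLibrary | None = None,
    template: StrategyTemplate = SRAS,
    marker: str = "kan",
) -> DnaMolecule:
    """SRAS unit plasmid of the given parity (1 = attR-breaker version,
    2 = attP-breaker version), carrying one payload."""
    lib = lib or default_library()
    v = template.end_variants[(parity - 1) % 2]
    v_next = template.end_variants[parity % 2]
    breaker_state = "R" if parity % 2 == 1 else "P"
    if breaker_state not in template.breaker_states_supplied:
        supplied = sorted(template.breaker_states_supplied)
        breaker_state = supplied[0] if supplied else breaker_state
    b = _MolBuilder(f"pUnit{payload_name}", "circular")
    b.site(_end_site(template, lib, "L", v))
    b.marker(marker)
    b.origin("R6Kgamma")
    if template.breaker_system:
        b.site(lib.site(template.breaker_system, state=breaker_state))
    b.site(_end_site(template, lib, "R", v_next))
    b.payload(payload_name, payload_seq)
    return b.build()


def _build_sras_ex(
    source_x_state: str,
    dest_variant: str,
    shipped_breaker: str | None,
    lib: SiteLibrary,
    template: StrategyTemplate = SRAS,
) -> DnaMolecule:
    """Extraction vector matched to the source host breaker state and to the
    destination host's reactive-end variant (and breaker state if the natural
    junction would mismatch)."""
    reactor = "R" if source_x_state == "L" else "P"
    b = _MolBuilder("pUnitEx" + reactor, "circular")
    b.site(lib.site(template.breaker_system, state=reactor))
    b.site(_end_site(template, lib, "L", dest_variant))
    b.marker("kan")
    if template.ex_has_origin:
        b.origin("R6Kgamma")
    if shipped_breaker:
        b.site(lib.site(template.breaker_system, state=shipped_breaker))
    return b.build()


def build_dras_host(
    lib: SiteLibrary | None = None,
    template: StrategyTemplate = DRAS,
    host_id: str = "DRAS_HOST",
) -> CellState:
    lib = lib or default_library()
    b = _MolBuilder(host_id, "circular")
    b.spacer("GG")
    b.site(lib.site(template.extraction_system, state="L"))
    b.site(lib.site(template.breaker_system))
    b.marker(template.marker_cycle[0])
    b.site(_end_site(template, lib, "R", template.end_variants[0]))
    b.site(lib.site(template.extraction_system, state="R"))
    b.feature("landing_pad", "target_flank", _pseudo_seq("dras:flank", 40))
    b.origin("chromosomal")
    return CellState(chromosome=b.build(), pir_positive=False)


def build_dras_unit(
    payload_name: str,
    payload_seq: str,
    parity: int,
    lib: SiteLibrary | None = None,
    template: StrategyTemplate = DRAS,
) -> DnaMolecule:
    """DRAS unit: the marker alternates with parity so every swap is
    screenable (kan-host takes a cat-unit and vice versa)."""
    lib = lib or default_library()
    v = template.end_variants[(parity - 1) % 2]
    v_next = template.end_variants[parity % 2]
    marker = template.marker_cycle[parity % len(template.marker_cycle)]
    b = _MolBuilder(f"pDRASUnit{payload_name}", "circular")
    b.site(_end_site(template, lib, "L", v))
    b.origin("R6Kgamma")
    b.site(lib.site(template.breaker_system))
    b.marker(marker)
    b.site(_end_site(template, lib, "R", v_next))
    b.payload(payload_name, payload_seq)
    return b.build()


def build_tras_unit(
    payload_name: str,
    payload_seq: str,
    left_marker: str,
    right_marker: str,
    left_variant: str,
    right_variant: str,
    lib: SiteLibrary | None = None,
    template: StrategyTemplate = TRAS,
) -> DnaMolecule:
    """Bi-Swap TRAS unit X-DNA-Y: payload flanked by an attR reactive end on
    the marker-X side and an attL end on the marker-Y side."""
    lib = lib or default_library()
    if left_marker == right_marker:
        raise StrategyError("TRAS unit flank markers must differ")
    linear = template.topology == "linear"
    b = _MolBuilder(f"{left_marker[0].upper()}-{payload_name}-{right_marker[0].upper()}",
                    "linear" if linear else "circular")
    if linear:
        b.origin("N15_linear")
    else:
        b.site(lib.site(template.breaker_system))
    b.marker(left_marker)
    b.site(_end_site(template, lib, "R", left_variant))
    b.payload(payload_name, payload_seq)
    b.site(_end_site(template, lib, "L", right_variant))
    b.marker(right_marker)
    if not linear:
        b.origin("standard")
    return b.build()


# ---------------------------------------------------------------------------
# chromosome anatomy helpers
# ---------------------------------------------------------------------------

@dataclass
class _Anatomy:
    phi_left: RecombSite | None
    breaker: RecombSite | None  # chromosomal topology-breaker site (X)
    end: RecombSite | None  # chromosomal reactive end (E)
    payloads: list[Feature]
    marker: Feature | None  # resident marker (DRAS)


def _region_order(chrom: DnaMolecule, template: StrategyTemplate) -> _Anatomy:
    """Locate the assembly region's machinery sites, reading rightwards from
    the left extraction site (or from the chromosome start if none)."""
    n = len(chrom)
    phi = None
    if template.extraction_system:
        phis = find_sites(chrom, system=template.extraction_system, state="L")
        phi = phis[0] if phis else None
    origin = phi.start if phi is not None else 0

    def key(start: int) -> int:
        return (start - origin) % n

    breaker = None
    if template.breaker_system:
        cands = [
            s
            for s in chrom.sites
            if s.family.system == template.breaker_system
            and (s.family.symmetric or s.state in ("B", "L"))
        ]
        breaker = min(cands, key=lambda s: key(s.start)) if cands else None
    end = None
    ends = [
        s
        for s in chrom.sites
        if s.family.system == template.end_system
        and (s.family.symmetric or s.state == "R")
    ]
    if ends:
        end = min(ends, key=lambda s: key(s.start))
    payloads = sorted(
        (f for f in chrom.features if f.kind == "payload"), key=lambda f: key(f.start)
    )
    markers = sorted(
        (f for f in chrom.features if f.kind == "marker"), key=lambda f: key(f.start)
    )
    return _Anatomy(phi, breaker, end, payloads, markers[0] if markers else None)


def payload_order(mol: DnaMolecule, template: StrategyTemplate | None = None) -> list[str]:
    """Payload names in region order (left to right from the extraction site
    for chromosomes, or from the canonical start otherwise)."""
    template = template or SRAS
    return [f.name for f in _region_order(mol, template).payloads]


def _unit_anatomy(unit: DnaMolecule, template: StrategyTemplate):
    """(reactive end, breaker, next-end, marker name) of a unit plasmid."""
    if template.ends_symmetric:
        lam = find_sites(unit, system=template.end_system)
        u_end = lam[0] if lam else None
        u_next = lam[1] if len(lam) > 1 else None
    else:
        lam = find_sites(unit, system=template.end_system)
        ls = [s for s in lam if s.state == "L"]
        rs = [s for s in lam if s.state == "R"]
        u_end = ls[0] if ls else None
        u_next = rs[0] if rs else None
    breaker = None
    if template.breaker_system:
        br = find_sites(unit, system=template.breaker_system)
        breaker = br[0] if br else None
    markers = [f for f in unit.features if f.kind == "marker"]
    return u_end, breaker, u_next, (markers[0].name if markers else None)


# ---------------------------------------------------------------------------
# screened protocol steps
# ---------------------------------------------------------------------------

def _cure(cell: CellState) -> CellState:
    """Drop episomes the cell cannot replicate (segregational loss)."""
    cell.episomes = [m for m in cell.episomes if replicable(cell, m)]
    return cell


def _site_index(mol: DnaMolecule, site: RecombSite) -> int:
    for i, s in enumerate(mol.sites):
        if s is site:
            return i
    raise ValueError("site not on molecule")


def _match_site(mol: DnaMolecule, proto: RecombSite) -> RecombSite:
    """Re-find a site on a copied molecule by family/state/start."""
    for s in mol.sites:
        if (s.family, s.state, s.start) == (proto.family, proto.state, proto.start):
            return s
    raise StrategyError(f"site {proto.family}:{proto.state}@{proto.start} vanished")


def _apply_designated(
    cell: CellState,
    enzyme: Enzyme,
    ref_a: tuple[str, RecombSite],
    ref_b: tuple[str, RecombSite],
) -> CellState:
    """Induce an enzyme and keep the screened outcome: the single event
    between the two designated sites."""
    from .cellsim import induce

    mols = {m.id: m for m in cell.molecules()}
    ia = _site_index(mols[ref_a[0]], ref_a[1])
    ib = _site_index(mols[ref_b[0]], ref_b[1])
    events = enumerate_events(cell.molecules(), {enzyme})
    for k, ev in enumerate(events):
        if ev.touches(ref_a[0], ia) and ev.touches(ref_b[0], ib):
            return induce(cell, {enzyme})[k]
    raise StrategyError(
        f"designated reaction {ref_a[0]}@{ref_a[1].family}:{ref_a[1].state} x "
        f"{ref_b[0]}@{ref_b[1].family}:{ref_b[1].state} is not feasible under {enzyme}"
    )


def _breaker_excision_enzyme(states: set[str], system: str) -> Enzyme:
    if states == {"L", "R"}:
        return Enzyme(system, True, True)
    if states == {"B", "P"}:
        return Enzyme(system, True, False)
    if states == {"symmetric"}:
        return Enzyme(system, True, False)
    raise StrategyError(f"breaker pair {sorted(states)} of {system} cannot recombine")


def sras_cycle(
    host: CellState,
    unit: DnaMolecule,
    mode: str = "ends_first",
    template: StrategyTemplate = SRAS,
) -> CellState:
    """One In/Out cycle: integrate a unit, excise its backbone, screen.

    ``ends_first`` integrates at the reactive ends and excises at the
    topology breakers; ``breakers_first`` does the converse. Both orders
    yield canonically identical chromosomes. Raises StrategyError for a
    wrong-parity unit (no compatible integration site).
    """
    if mode not in ("ends_first", "breakers_first"):
        raise ValueError(f"unknown mode {mode!r}")
    anat = _region_order(host.chromosome, template)
    u_end, u_breaker, _, u_marker = _unit_anatomy(unit, template)
    if anat.end is None or u_end is None:
        raise StrategyError("host or unit lacks a reactive end")
    if not template.ends_symmetric and u_end.family.variant != anat.end.family.variant:
        raise StrategyError(
            f"wrong-parity unit: host end is variant {anat.end.family.variant!r}, "
            f"unit end is variant {u_end.family.variant!r}"
        )
    if template.breaker_system:
        if anat.breaker is None or u_breaker is None:
            raise StrategyError("missing topology breaker")
        b_states = {anat.breaker.state, u_breaker.state}
        if not anat.breaker.family.symmetric and b_states not in ({"B", "P"}, {"L", "R"}):
            raise StrategyError(
                f"wrong-parity unit: chromosomal breaker att{anat.breaker.state} "
                f"cannot recombine with unit breaker att{u_breaker.state}"
            )

    cell = transform(host, unit)
    unit_id = cell.episomes[-1].id
    umol = cell.episomes[-1]
    chrom_id = cell.chromosome.id
    end_enz = template.end_enzyme()
    chrom_end = _match_site(cell.chromosome, anat.end)
    u_end2 = _match_site(umol, u_end)
    chrom_brk = _match_site(cell.chromosome, anat.breaker)
    u_brk2 = _match_site(umol, u_breaker)

    if mode == "ends_first":
        first = (end_enz, (chrom_id, chrom_end), (unit_id, u_end2))
    else:
        b_states = {anat.breaker.state, u_breaker.state}
        brk_enz = _breaker_excision_enzyme(
            b_states if not anat.breaker.family.symmetric else {"symmetric"},
            template.breaker_system,
        )
        first = (brk_enz, (chrom_id, chrom_brk), (unit_id, u_brk2))
    cell = _apply_designated(cell, *first)
    # integration selection: the marker must sit on a replicable molecule
    pop = select(Population([cell]), u_marker or "kan")
    if not pop.cells:
        raise StrategyError("integrant not selectable: marker not on a replicable molecule")
    cell = _cure(pop.cells[0])

    # backbone excision via the other site class, now intramolecular
    chrom = cell.chromosome
    if mode == "ends_first":
        from .seqmodel import SYMMETRIC_SYSTEMS

        if template.breaker_system in SYMMETRIC_SYSTEMS:
            pair = find_sites(chrom, system=template.breaker_system)[:2]
            states = {"symmetric"}
        else:
            brks = find_sites(chrom, system=template.breaker_system)
            pairable = {"B": "P", "P": "B", "L": "R", "R": "L"}
            pair = None
            for i, s in enumerate(brks):
                for t2 in brks[i + 1:]:
                    if t2.state == pairable.get(s.state):
                        pair = [s, t2]
                        break
                if pair:
                    break
            if pair is None:
                raise StrategyError(
                    "topology breakers cannot recombine: no complementary pair "
                    f"among {[s.state for s in brks]}"
                )
            states = {pair[0].state, pair[1].state}
        enz = _breaker_excision_enzyme(states, template.breaker_system)
    else:
        if template.ends_symmetric:
            pair = find_sites(chrom, system=template.end_system)[:2]
        else:
            lams = [
                s
                for s in find_sites(chrom, system=template.end_system)
                if s.family.variant == anat.end.family.variant
            ]
            ls = [s for s in lams if s.state == "L"]
            rs = [s for s in lams if s.state == "R"]
            if not ls or not rs:
                raise StrategyError("no excisable reactive-end pair after integration")
            pair = [ls[0], rs[0]]
        enz = template.end_enzyme()
    cell = _apply_designated(cell, enz, (chrom.id, pair[0]), (chrom.id, pair[1]))
    pop = counter_select(Population([cell]), u_marker or "kan")
    if not pop.cells:
        raise StrategyError("backbone excision not counter-selectable")
    return _cure(pop.cells[0])


def sras_extract(
    host: CellState,
    dest_variant: str | None = None,
    dest_breaker_state: str | None = None,
    lib: SiteLibrary | None = None,
    template: StrategyTemplate = SRAS,
) -> tuple[DnaMolecule, CellState]:
    """Pop the assembled region out of the chromosome as a plasmid.

    Integrates a matched extraction vector at the chromosomal breaker (it
    contributes the kan marker, R6Kgamma origin and the destination-matched
    reactive end), then excises between the Phi80 attL/attR pair. The
    returned plasmid is replicable only in a pir+ host.
    """
    lib = lib or default_library()
    anat = _region_order(host.chromosome, template)
    if anat.phi_left is None or not find_sites(
        host.chromosome, system=template.extraction_system, state="R"
    ):
        raise StrategyError("chromosome lacks the Phi80 attL/attR extraction pair")
    if not anat.payloads:
        raise StrategyError("nothing to extract: no assembled payloads on this host")
    if anat.breaker is None:
        raise StrategyError("chromosome lacks a topology breaker for the extraction vector")

    if dest_variant is None:
        dest_variant = anat.end.family.variant if anat.end is not None else "1"
    natural = "P" if anat.breaker.state == "L" else "R"
    shipped = None
    if dest_breaker_state is not None and dest_breaker_state != natural:
        shipped = dest_breaker_state
    ex = _build_sras_ex(anat.breaker.state, dest_variant, shipped, lib, template)

    cell = transform(host, ex)
    ex_id = cell.episomes[-1].id
    exmol = cell.episomes[-1]
    reactor = find_sites(exmol, system=template.breaker_system)[0]
    chrom_brk = _match_site(cell.chromosome, anat.breaker)
    enz = _breaker_excision_enzyme({anat.breaker.state, reactor.state}, template.breaker_system)
    cell = _apply_designated(cell, enz, (cell.chromosome.id, chrom_brk), (ex_id, reactor))
    pop = select(Population([cell]), "kan")
    if not pop.cells:
        raise StrategyError("extraction-vector integrant not selectable")
    cell = _cure(pop.cells[0])

    phis = find_sites(cell.chromosome, system=template.extraction_system)
    pl = [s for s in phis if s.state == "L"]
    pr = [s for s in phis if s.state == "R"]
    if not pl or not pr:
        raise StrategyError("Phi80 pair lost before extraction")
    phi_enz = Enzyme(template.extraction_system, True, True)
    cell = _apply_designated(
        cell, phi_enz, (cell.chromosome.id, pl[0]), (cell.chromosome.id, pr[0])
    )
    plasmids = [
        m for m in cell.episomes if any(f.kind == "payload" for f in m.features)
    ]
    if len(plasmids) != 1:
        raise StrategyError("extraction did not yield a unique payload plasmid")
    plasmid = plasmids[0].copy("pUnit" + "".join(payload_order(plasmids[0], template)))
    post = _cure(cell)
    return plasmid, post


def sras_integrate_plasmid(
    host: CellState,
    plasmid: DnaMolecule,
    template: StrategyTemplate = SRAS,
) -> CellState:
    """Breakers-first In/Out cycle with an extracted assembly plasmid as the
    unit: integrate at the HK022 breaker pair, excise the kan/ori backbone at
    the matched reactive-end pair, screen as usual."""
    anat = _region_order(host.chromosome, template)
    if anat.breaker is None or anat.end is None:
        raise StrategyError("destination host lacks breaker/end machinery")
    needed = {"B": "P", "L": "R"}[anat.breaker.state]
    cands = [
        s
        for s in find_sites(plasmid, system=template.breaker_system)
        if s.state == needed
    ]
    if not cands:
        raise StrategyError(
            f"plasmid carries no att{needed} {template.breaker_system} site for this host"
        )
    cell = transform(host, plasmid)
    pid = cell.episomes[-1].id
    pmol = cell.episomes[-1]
    reactor = _match_site(pmol, cands[0])
    chrom_brk = _match_site(cell.chromosome, anat.breaker)
    enz = _breaker_excision_enzyme({anat.breaker.state, needed}, template.breaker_system)
    cell = _apply_designated(cell, enz, (cell.chromosome.id, chrom_brk), (pid, reactor))
    pop = select(Population([cell]), "kan")
    if not pop.cells:
        raise StrategyError("plasmid integrant not selectable")
    cell = _cure(pop.cells[0])

    chrom = cell.chromosome
    lams = [
        s
        for s in find_sites(chrom, system=template.end_system)
        if s.family.variant == anat.end.family.variant
    ]
    ls = [s for s in lams if s.state == "L"]
    rs = [s for s in lams if s.state == "R"]
    if not ls or not rs:
        raise StrategyError(
            "no matched reactive-end pair to excise the extraction backbone "
            f"(need attL{anat.end.family.variant} x attR{anat.end.family.variant})"
        )
    cell = _apply_designated(
        cell, template.end_enzyme(), (chrom.id, ls[0]), (chrom.id, rs[0])
    )
    pop = counter_select(Population([cell]), "kan")
    if not pop.cells:
        raise StrategyError("extraction backbone not counter-selectable")
    return _cure(pop.cells[0])


def dras_swap(
    host: CellState, unit: DnaMolecule, template: StrategyTemplate = DRAS
) -> CellState:
    """Swap-Extract step: append the unit payload and substitute the marker.

    Reactive-end recombination and frt topology breaking occur concurrently;
    the recombinant is screened by selecting the incoming marker and
    counter-selecting the resident one.
    """
    anat = _region_order(host.chromosome, template)
    u_end, u_breaker, _, u_marker = _unit_anatomy(unit, template)
    if anat.marker is None or u_marker is None:
        raise StrategyError("host and unit must each carry a marker")
    if anat.marker.name == u_marker:
        raise StrategyError(
            f"same-marker unit ({u_marker}): marker swap is not screenable"
        )
    if anat.end is None or u_end is None or anat.breaker is None or u_breaker is None:
        raise StrategyError("missing reactive end or frt breaker")
    if u_end.family.variant != anat.end.family.variant:
        raise StrategyError(
            f"wrong-parity unit: host end variant {anat.end.family.variant!r} vs "
            f"unit {u_end.family.variant!r}"
        )
    old_marker = anat.marker.name
    cell = transform(host, unit)
    uid = cell.episomes[-1].id
    umol = cell.episomes[-1]
    cell = _apply_designated(
        cell,
        template.end_enzyme(),
        (cell.chromosome.id, _match_site(cell.chromosome, anat.end)),
        (uid, _match_site(umol, u_end)),
    )
    frts = find_sites(cell.chromosome, system=template.breaker_system)
    if len(frts) < 2:
        raise StrategyError("frt pair missing after fusion")
    cell = _apply_designated(
        cell, FLP, (cell.chromosome.id, frts[0]), (cell.chromosome.id, frts[1])
    )
    pop = select(Population([cell]), u_marker)
    pop = counter_select(pop, old_marker)
    if not pop.cells:
        raise StrategyError("marker swap not screenable on this recombinant")
    return _cure(pop.cells[0])


# ---------------------------------------------------------------------------
# TRAS merges
# ---------------------------------------------------------------------------

def _tras_flanks(mol: DnaMolecule, template: StrategyTemplate):
    """(left marker, eL site, eR site, right marker) of a TRAS unit/block."""
    ends = find_sites(mol, system=template.end_system)
    rs = [s for s in ends if s.state == "R"]
    ls = [s for s in ends if s.state == "L"]
    if not rs or not ls:
        raise StrategyError(f"{mol.id}: not a TRAS unit (needs attR and attL ends)")
    e_l, e_r = rs[0], ls[-1]
    n = len(mol)
    markers = [f for f in mol.features if f.kind == "marker"]

    def before(site: RecombSite) -> Feature:
        return min(markers, key=lambda f: (site.start - f.end) % max(n, 1))

    def after(site: RecombSite) -> Feature:
        return min(markers, key=lambda f: (f.start - site.end) % max(n, 1))

    return before(e_l), e_l, e_r, after(e_r)


def tras_merge(
    left: DnaMolecule,
    right: DnaMolecule,
    direction: str = "right",
    template: StrategyTemplate = TRAS,
) -> DnaMolecule:
    """Bi-Swap merge: X-DNA1-G + G-DNA2-K -> X-DNA1DNA2-K.

    ``direction="left"`` treats the first argument as the anchor being
    extended on its left arm (operands are exchanged). The shared flank
    marker is consumed from the junction; circular inputs pass through a
    fusion intermediate carrying all three markers, resolved at loxP and
    removed by counter-selection; linear (N15) inputs exchange arms directly.
    """
    if direction not in ("right", "left"):
        raise ValueError(f"unknown direction {direction!r}")
    if direction == "left":
        left, right = right, left
    lm_l, _, e_r_left, rm_l = _tras_flanks(left, template)
    lm_r, e_l_right, _, rm_r = _tras_flanks(right, template)
    if rm_l.name != lm_r.name:
        raise StrategyError(
            f"mismatched flanks: {left.id} ends in {rm_l.name}, {right.id} "
            f"starts with {lm_r.name}; no shared junction marker"
        )
    trio = {lm_l.name, rm_l.name, rm_r.name}
    if len(trio) != 3:
        raise StrategyError(
            f"markers {sorted([lm_l.name, rm_l.name, rm_r.name])} are not all "
            "distinct across the pair; the product is not screenable"
        )
    if e_r_left.family.variant != e_l_right.family.variant:
        raise StrategyError(
            f"mismatched flanks: junction end variants "
            f"{e_r_left.family.variant!r} vs {e_l_right.family.variant!r}"
        )
    enz = template.end_enzyme()
    ev = ReactionEvent(
        enz,
        *(
            (left.id, _site_index(left, e_r_left), right.id, _site_index(right, e_l_right))
            if (left.id, e_r_left.start) <= (right.id, e_l_right.start)
            else (right.id, _site_index(right, e_l_right), left.id, _site_index(left, e_r_left))
        ),
        mode="fusion" if left.circular else "linear_exchange",
    )
    products = recombine(ev, [left, right])
    junction_marker = rm_l.name
    if left.circular:
        inter = products[0]
        present = {f.name for f in inter.features if f.kind == "marker"}
        if not trio <= present:
            raise StrategyError(
                f"fusion intermediate lacks a marker: has {sorted(present)}"
            )
        lox = find_sites(inter, system=template.breaker_system)
        if len(lox) != 2:
            raise StrategyError("fusion intermediate must carry exactly two loxP sites")
        ev2 = ReactionEvent(
            CRE, inter.id, _site_index(inter, lox[0]), inter.id,
            _site_index(inter, lox[1]), mode="excision",
        )
        products = recombine(ev2, [inter])
    keep = [
        m
        for m in products
        if {f.name for f in m.features if f.kind == "marker"}
        == {lm_l.name, rm_r.name}
    ]
    if len(keep) != 1:
        raise StrategyError("screening did not identify a unique merged product")
    out = keep[0]
    out.id = f"{lm_l.name[0].upper()}-" + "".join(
        f.name for f in sorted(
            (f for f in out.features if f.kind == "payload"), key=lambda f: f.start
        )
    ) + f"-{rm_r.name[0].upper()}"
    assert junction_marker not in {f.name for f in out.features if f.kind == "marker"}
    return out


# ---------------------------------------------------------------------------
# event log
# ---------------------------------------------------------------------------

@dataclass
class LogEntry:
    step: int
    phase: str
    category: str
    mols_in: tuple[str, ...]
    mols_out: tuple[str, ...]


class EventLog:
    """Protocol trace with one entry per priced wet-lab operation."""

    def __init__(self) -> None:
        self.entries: list[LogEntry] = []

    def charge(
        self,
        table: dict[str, int],
        phase: str,
        mols_in: tuple[str, ...] = (),
        mols_out: tuple[str, ...] = (),
    ) -> None:
        for category in CATEGORIES:
            for _ in range(table.get(category, 0)):
                self.entries.append(
                    LogEntry(len(self.entries) + 1, phase, category, mols_in, mols_out)
                )

    def category_totals(self) -> OpLedger:
        ledger = OpLedger()
        for e in self.entries:
            ledger.add(e.category)
        return ledger

    def to_tsv(self) -> str:
        lines = ["step\tphase\tcategory\tmolecules_in\tmolecules_out"]
        for e in self.entries:
            lines.append(
                f"{e.step}\t{e.phase}\t{e.category}\t{','.join(e.mols_in)}\t{','.join(e.mols_out)}"
            )
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# whole-plan execution
# ---------------------------------------------------------------------------

def required_parities(tree: MergeTree) -> list[int]:
    """SRAS unit parity (1 or 2) per leaf, in leaf order, for a merge tree.

    Mirrors the executor: each host integrates its chromosome-side lineage
    first, then prepends the other children right-to-left; parity alternates
    with the host's cycle count.
    """
    parities = [0] * tree.n_leaves

    def rec(node: MergeNode) -> int:
        if node.is_leaf:
            parities[node.leaf] = 1
            return 1
        cs = node.chromosome_side % len(node.children)
        cycles = rec(node.children[cs])
        others = [c for i, c in enumerate(node.children) if i != cs]
        for child in reversed(others):
            if child.is_leaf:
                cycles += 1
                parities[child.leaf] = 2 - (cycles % 2)
            else:
                rec(child)
                cycles += 1
        return cycles

    rec(tree.root)
    return parities


def _sras_run(
    template: StrategyTemplate,
    units: list[DnaMolecule],
    tree: MergeTree,
    log: EventLog,
    lib: SiteLibrary,
    trace: list | None = None,
) -> CellState:
    costs = template.op_costs
    leaf_cost = costs.get("leaf", {})
    merge_cost = costs.get("merge", {})
    psn_cost = costs.get("plasmid_side_internal", {})
    ext_cost = costs.get("extraction", {})
    nonfinal_cost = costs.get("nonfinal_extraction", {})

    def note(cell: CellState, label: str) -> None:
        if trace is not None:
            trace.append((label, cell.chromosome.copy()))

    def rec(node: MergeNode) -> CellState:
        if node.is_leaf:
            host = build_sras_host(lib, template, host_id=f"HOST{node.leaf}")
            unit = units[node.leaf]
            log.charge(leaf_cost, "unit_prep", (unit.id,), (unit.id,))
            host = sras_cycle(host, unit, "ends_first", template)
            note(host, f"deposit:{unit.id}")
            return host
        cs = node.chromosome_side % len(node.children)
        host = rec(node.children[cs])
        others = [c for i, c in enumerate(node.children) if i != cs]
        for child in reversed(others):
            if child.is_leaf:
                unit = units[child.leaf]
                log.charge(leaf_cost, "unit_prep", (unit.id,), (unit.id,))
                host = sras_cycle(host, unit, "ends_first", template)
                log.charge(
                    merge_cost, "merge", (host.chromosome.id, unit.id), (host.chromosome.id,)
                )
                note(host, f"merge:{unit.id}")
            else:
                src = rec(child)
                anat = _region_order(host.chromosome, template)
                dest_v = anat.end.family.variant if anat.end is not None else "1"
                dest_b = {"B": "P", "L": "R"}.get(anat.breaker.state) if anat.breaker else None
                plasmid, _ = sras_extract(src, dest_v, dest_b, lib, template)
                log.charge(ext_cost, "extract", (src.chromosome.id,), (plasmid.id,))
                log.charge(psn_cost, "extract", (src.chromosome.id,), (plasmid.id,))
                log.charge(nonfinal_cost, "extract_verify", (plasmid.id,), (plasmid.id,))
                host = sras_integrate_plasmid(host, plasmid, template)
                log.charge(
                    merge_cost, "merge", (host.chromosome.id, plasmid.id), (host.chromosome.id,)
                )
                note(host, f"merge:{plasmid.id}")
        return host

    host = rec(tree.root)
    if not tree.root.is_leaf:
        # final extraction of the complete assembly, on a sampled colony
        final_plasmid, _ = sras_extract(host.copy(), None, None, lib, template)
        log.charge(ext_cost, "final_extract", (host.chromosome.id,), (final_plasmid.id,))
    return host


def _tras_run(
    template: StrategyTemplate,
    units: list[DnaMolecule],
    tree: MergeTree,
    log: EventLog,
) -> DnaMolecule:
    costs = template.op_costs
    node_cost = costs.get("node", {})
    merge_cost = costs.get("merge", {})

    def rec(node: MergeNode) -> DnaMolecule:
        if node.is_leaf:
            unit = units[node.leaf]
            log.charge(node_cost, "unit_prep", (unit.id,), (unit.id,))
            return unit
        if len(node.children) != 2:
            raise StrategyError("TRAS merges are pairwise; use a binary merge tree")
        left = rec(node.children[0])
        right = rec(node.children[1])
        direction = "right" if node.chromosome_side % 2 == 0 else "right"
        merged = tras_merge(left, right, direction, template)
        log.charge(merge_cost, "merge", (left.id, right.id), (merged.id,))
        log.charge(node_cost, "clone", (merged.id,), (merged.id,))
        return merged

    return rec(tree.root)


def _dras_run(
    template: StrategyTemplate,
    units: list[DnaMolecule],
    tree: MergeTree,
    log: EventLog,
    lib: SiteLibrary,
) -> CellState:
    costs = template.op_costs
    leaf_cost = costs.get("leaf", {})
    merge_cost = costs.get("merge", {})
    order = tree.root.leaf_indices()
    host = build_dras_host(lib, template)
    for k, idx in enumerate(reversed(order)):
        unit = units[idx]
        log.charge(leaf_cost, "unit_prep", (unit.id,), (unit.id,))
        host = dras_swap(host, unit, template)
        if k > 0:
            log.charge(merge_cost, "merge", (host.chromosome.id, unit.id), (host.chromosome.id,))
    return host


def run_assembly(
    template: StrategyTemplate,
    units: list[DnaMolecule],
    tree: MergeTree,
    lib: SiteLibrary | None = None,
    _trace: list | None = None,
) -> tuple[DnaMolecule, EventLog]:
    """Execute every merge of the tree; returns (final construct, EventLog).

    The final construct is the assembled chromosome (integrating strategies)
    or the merged unit plasmid (swap strategies); its payloads appear in the
    tree's left-to-right leaf order. The EventLog records each priced
    operation with its ledger category.
    """
    if not template.has_schedule:
        raise StrategyError(
            f"template {template.name} carries operation costs only; it has no "
            "sequence-level reaction schedule"
        )
    if len(units) != tree.n_leaves:
        raise StrategyError(
            f"{len(units)} units supplied for a {tree.n_leaves}-leaf merge tree"
        )
    lib = lib or default_library()
    log = EventLog()
    if tree.n_leaves == 1 and template.name.startswith(("TRAS", "LINEAR")):
        return units[0], log
    if template.name.startswith(("TRAS", "LINEAR")):
        construct = _tras_run(template, units, tree, log)
        return construct, log
    if template.name.startswith("DRAS"):
        host = _dras_run(template, units, tree, log, lib)
        return host.chromosome, log
    host = _sras_run(template, units, tree, log, lib, _trace)
    return host.chromosome, log


# ---------------------------------------------------------------------------
# the three-rule validity checker
# ---------------------------------------------------------------------------

@dataclass
class RuleResult:
    passed: bool
    trace: list[str] = field(default_factory=list)


@dataclass
class RuleReport:
    rule1: RuleResult
    rule2: RuleResult
    rule3: RuleResult

    @property
    def valid(self) -> bool:
        return self.rule1.passed and self.rule2.passed and self.rule3.passed

    def failing(self) -> list[str]:
        return [
            name
            for name, r in (("rule1", self.rule1), ("rule2", self.rule2), ("rule3", self.rule3))
            if not r.passed
        ]


def _element_list(mol: DnaMolecule) -> list[tuple]:
    elems: list[tuple[int, tuple]] = []
    for s in mol.sites:
        elems.append((s.start, ("site", s.family.system, s.state)))
    for f in mol.features:
        if f.kind in ("marker", "origin", "payload"):
            elems.append((f.start, (f.kind, f.name)))
    elems.sort(key=lambda x: x[0])
    return [e for _, e in elems]


def _matches(elem: tuple, want: tuple) -> bool:
    if want[0] == "site":
        if elem[0] != "site" or elem[1] != want[1]:
            return False
        return elem[2] in want[2]
    if elem[0] != want[0]:
        return False
    return want[1] is None or elem[1] == want[1]


def _schema_match(mol: DnaMolecule, schema: tuple[tuple, ...], circular: bool) -> bool:
    """Does the schema appear, in order, among the molecule's elements
    (extra inert elements allowed)?"""
    elems = _element_list(mol)
    if not schema:
        return True
    rotations = range(len(elems)) if circular and elems else [0]
    for r in rotations:
        seq = elems[r:] + (elems[:r] if circular else [])
        it = iter(seq)
        if all(any(_matches(e, w) for e in it) for w in schema):
            return True
    return False


def _mini_units(template: StrategyTemplate, lib: SiteLibrary) -> list[DnaMolecule]:
    pl = [_pseudo_seq(f"validate:payload{i}", 60) for i in (1, 2)]
    if template.name.startswith(("TRAS", "LINEAR")):
        cyc = template.marker_cycle
        return [
            build_tras_unit("Syn1", pl[0], cyc[0], cyc[1], "2", "1", lib, template),
            build_tras_unit("Syn2", pl[1], cyc[1], cyc[2], "1", "2", lib, template),
        ]
    if template.name.startswith("DRAS"):
        return [
            build_dras_unit("Syn1", pl[0], 1, lib, template),
            build_dras_unit("Syn2", pl[1], 2, lib, template),
        ]
    return [
        build_sras_unit("Syn1", pl[0], 1, lib, template),
        build_sras_unit("Syn2", pl[1], 2, lib, template),
    ]


def validate_strategy(
    template: StrategyTemplate, lib: SiteLibrary | None = None
) -> RuleReport:
    """Execute a two-unit assembly on synthetic payloads and check the three
    design rules.

    Rule 1: no former reactive-end junction is re-enumerable under the
    integrating enzyme on the final product. Rule 2: topology breakers stay
    reactive (a supplied partner state exists) at every intermediate.
    Rule 3: the product, after extraction, structurally matches the unit
    layout schema. Cost-only templates (GIBSON, BIOBRICK) are not checkable.
    """
    if not template.has_schedule:
        raise StrategyError(
            f"template {template.name} has no sequence-level schedule; "
            "rules are not checkable"
        )
    lib = lib or default_library()
    units = _mini_units(template, lib)
    intermediates: list[tuple[str, DnaMolecule]] = []
    failures: list[str] = []
    product: DnaMolecule | None = None
    extracted: DnaMolecule | None = None

    from .planner import build_merge_tree

    tree = build_merge_tree([f.name for u in units for f in u.features if f.kind == "payload"])

    if template.name.startswith(("TRAS", "LINEAR")):
        for u in units:
            intermediates.append(("unit", u))
        try:
            product = tras_merge(units[0], units[1], "right", template)
            intermediates.append(("merged", product))
            extracted = product  # swap strategies need no extraction step
        except StrategyError as exc:
            failures.append(f"merge failed: {exc}")
    else:
        trace: list = []
        try:
            if template.name.startswith("DRAS"):
                host = build_dras_host(lib, template)
                host = dras_swap(host, units[0], template)
                intermediates.append(("swap1", host.chromosome.copy()))
                host = dras_swap(host, units[1], template)
                intermediates.append(("swap2", host.chromosome.copy()))
                product = host.chromosome
            else:
                host = build_sras_host(lib, template)
                host = sras_cycle(host, units[0], "ends_first", template)
                intermediates.append(("cycle1", host.chromosome.copy()))
                host = sras_cycle(host, units[1], "ends_first", template)
                intermediates.append(("cycle2", host.chromosome.copy()))
                product = host.chromosome
        except StrategyError as exc:
            failures.append(f"assembly halted: {exc}")
            product = intermediates[-1][1] if intermediates else None
        if product is not None and template.extraction_system:
            try:
                src = CellState(product.copy(), [], False)
                if template.name.startswith("DRAS"):
                    extracted = _dras_extract(src, lib, template)
                else:
                    extracted, _ = sras_extract(src, None, None, lib, template)
            except StrategyError as exc:
                failures.append(f"extraction failed: {exc}")

    # Rule 1 -------------------------------------------------------------
    r1 = RuleResult(True)
    if product is None:
        r1 = RuleResult(False, ["no product to examine"] + failures)
    else:
        enz = template.end_enzyme()
        junction_states = {"symmetric"} if template.ends_symmetric else {"B"}
        mols = [product]
        events = enumerate_events(mols, {enz})
        bad = []
        for ev in events:
            for mid, idx in ((ev.mol_a, ev.site_a), (ev.mol_b, ev.site_b)):
                s = {m.id: m for m in mols}[mid].sites[idx]
                if s.family.system == template.end_system and s.state in junction_states:
                    bad.append(f"{ev.mode} touching former junction {s.family}:{s.state}@{s.start}")
        if bad:
            r1 = RuleResult(False, sorted(set(bad)))
        else:
            r1.trace.append("no reactive-end junction re-enumerable on the product")

    # Rule 2 -------------------------------------------------------------
    r2 = RuleResult(True)
    complement = {"B": "P", "P": "B", "L": "R", "R": "L", "symmetric": "symmetric"}
    if template.breaker_system is None:
        r2.trace.append("linear ends are inherently reactive topology breakers")
    else:
        for label, mol in intermediates:
            brks = find_sites(mol, system=template.breaker_system)
            ok = any(
                complement[s.state] in template.breaker_states_supplied
                or s.family.symmetric
                for s in brks
            )
            if not ok:
                r2.passed = False
                r2.trace.append(
                    f"{label}: breaker states {[s.state for s in brks]} have no "
                    f"supplied partner in {sorted(template.breaker_states_supplied)}"
                )
            else:
                r2.trace.append(f"{label}: breaker reactive")
    if failures and not r2.passed:
        r2.trace.extend(failures)

    # Rule 3 -------------------------------------------------------------
    if extracted is None:
        r3 = RuleResult(False, ["no extracted product"] + failures)
    elif _schema_match(extracted, template.product_schema, extracted.circular):
        r3 = RuleResult(True, [f"product {extracted.id} matches the unit schema"])
    else:
        r3 = RuleResult(
            False,
            [
                f"product {extracted.id} does not match the unit schema; "
                f"elements: {_element_list(extracted)}"
            ],
        )
    return RuleReport(r1, r2, r3)


def _dras_extract(
    host: CellState, lib: SiteLibrary, template: StrategyTemplate
) -> DnaMolecule:
    """Phi80 extraction for DRAS: an frt extraction vector contributes the
    origin, then the Phi80 pair pops the region out."""
    b = _MolBuilder("pDRASEx", "circular")
    b.site(lib.site(template.breaker_system))
    b.marker("gen")
    if template.ex_has_origin:
        b.origin("R6Kgamma")
    ex = b.build()
    cell = transform(host, ex)
    ex_id = cell.episomes[-1].id
    exmol = cell.episomes[-1]
    frt_c = find_sites(cell.chromosome, system=template.breaker_system)
    frt_e = find_sites(exmol, system=template.breaker_system)
    if not frt_c or not frt_e:
        raise StrategyError("missing frt sites for DRAS extraction")
    cell = _apply_designated(
        cell, FLP, (cell.chromosome.id, frt_c[0]), (ex_id, frt_e[0])
    )
    phis = find_sites(cell.chromosome, system=template.extraction_system)
    pl = [s for s in phis if s.state == "L"]
    pr = [s for s in phis if s.state == "R"]
    if not pl or not pr:
        raise StrategyError("Phi80 pair missing for DRAS extraction")
    cell = _apply_designated(
        cell,
        Enzyme(template.extraction_system, True, True),
        (cell.chromosome.id, pl[0]),
        (cell.chromosome.id, pr[0]),
    )
    plasmids = [m for m in cell.episomes if any(f.kind == "payload" for f in m.features)]
    if not plasmids:
        raise StrategyError("DRAS extraction yielded no payload plasmid")
    return plasmids[0]
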