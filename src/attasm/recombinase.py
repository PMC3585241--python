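"""Site-specific recombination engine.

Implements the binary attachment-site algebra (attB + attP -> attL + attR and
its Int/Xis-dependent reverse) and the symmetric Cre/loxP and FLP/frt systems,
as crossover splicing at the midpoint of the shared site core. Topology
determines the outcome mode:

* two circles fuse into one (2 -> 1),
* an intramolecular direct-repeat pair excises a circle (1 -> 2),
* an intramolecular inverted-repeat pair (symmetric systems) inverts (1 -> 1),
* two linear molecules exchange arms (2 -> 2),
* a circle integrates into a linear molecule (2 -> 1).

Base count is conserved by construction. Reactive sites must be on the
forward strand and parallel; anti-parallel attachment-site pairs are reported
incompatible rather than modelled, matching designs that use parallel pairs
only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seqmodel import DnaMolecule, Feature, RecombSite, revcomp

__all__ = [
    "Enzyme",
    "ReactionEvent",
    "IncompatibleEventError",
    "compatible",
    "compatibility_report",
    "recombine",
    "enumerate_events",
    "LAMBDA_INT",
    "LAMBDA_INT_XIS",
    "HK022_INT",
    "HK022_INT_XIS",
    "PHI80_INT_XIS",
    "CRE",
    "FLP",
]


@dataclass(frozen=True)
class Enzyme:
    """A resident recombinase. BxP needs Int; LxR needs Int and Xis.

    Symmetric systems (Cre, FLP) are modelled as a single recombinase via
    ``has_int``; ``has_xis`` is ignored for them.
    """

    system: str
    has_int: bool = True
    has_xis: bool = False

    def __str__(self) -> str:
        parts = [self.system]
        if self.has_int:
            parts.append("int")
        if self.has_xis:
            parts.append("xis")
        return "+".join(parts)


# helper enzymes of the experimental toolkit
LAMBDA_INT = Enzyme("lambda", True, False)
LAMBDA_INT_XIS = Enzyme("lambda", True, True)
HK022_INT = Enzyme("HK022", True, False)
#: the HK022-lambda chimera Int+Xis, catalysing HK022 attL x attR
HK022_INT_XIS = Enzyme("HK022", True, True)
PHI80_INT_XIS = Enzyme("Phi80", True, True)
CRE = Enzyme("P1-lox", True, False)
FLP = Enzyme("FLP-frt", True, False)


def compatible(a: RecombSite, b: RecombSite, e: Enzyme) -> str | None:
    """Reaction class of a site pair under an enzyme, or None.

    BxP requires same system/variant/core and Int; LxR additionally Xis;
    symmetric sites react whenever their recombinase is present.
    """
    if e is None or a.family.system != b.family.system:
        return None
    if e.system != a.family.system:
        return None
    if a.family.symmetric:
        if b.family.symmetric and a.family == b.family and e.has_int:
            return "symmetric"
        return None
    if a.family.variant != b.family.variant:
        return None
    if a.core.upper() != b.core.upper():
        return None
    states = {a.state, b.state}
    if states == {"B", "P"}:
        return "BxP" if e.has_int else None
    if states == {"L", "R"}:
        return "LxR" if (e.has_int and e.has_xis) else None
    return None


def compatibility_report(a: RecombSite, b: RecombSite, e: Enzyme) -> str:
    """Human-readable reason why a pair does or does not react."""
    if a.family.system != b.family.system:
        return f"cross-system pair {a.family} x {b.family}: incompatible"
    if not a.family.symmetric and a.family.variant != b.family.variant:
        return f"variant mismatch {a.family} x {b.family}: incompatible"
    if e is None or e.system != a.family.system:
        return f"no enzyme for system {a.family.system}"
    if a.family.symmetric:
        return f"{a.family} symmetric pair under {e}: reactive"
    states = {a.state, b.state}
    if states == {"B", "P"} and not e.has_int:
        return f"att{a.state} x att{b.state} needs Int; {e} lacks it"
    if states == {"L", "R"} and not (e.has_int and e.has_xis):
        return f"attL x attR needs Int and Xis; {e} insufficient"
    if states not in ({"B", "P"}, {"L", "R"}):
        return f"att{a.state} x att{b.state}: no reaction in the att algebra"
    return f"att{a.state} x att{b.state} under {e}: reactive"


@dataclass(frozen=True)
class ReactionEvent:
    """One feasible recombination between two site references.

    Sites are referenced as (molecule id, index into that molecule's site
    list). ``mode`` is fully determined by topology, co-molecularity and
    relative orientation.
    """

    enzyme: Enzyme
    mol_a: str
    site_a: int
    mol_b: str
    site_b: int
    mode: str  # fusion | excision | inversion | linear_exchange | integration_into_linear

    def touches(self, mol_id: str, site_index: int) -> bool:
        return (self.mol_a, self.site_a) == (mol_id, site_index) or (
            self.mol_b,
            self.site_b,
        ) == (mol_id, site_index)


class IncompatibleEventError(ValueError):
    def __init__(self, report: str):
        super().__init__(report)
        self.report = report


_JUNCTION_STATE = {
    ("B", "P"): "L",
    ("P", "B"): "R",
    ("L", "R"): "B",
    ("R", "L"): "P",
    ("symmetric", "symmetric"): "symmetric",
}


def _half(core: str) -> int:
    # crossover at the core midpoint; odd cores give the extra base left
    return (len(core) + 1) // 2


def _cut(site: RecombSite) -> int:
    """Crossover position in molecule coordinates (unreduced)."""
    h = _half(site.core)
    if site.orientation > 0:
        return site.start + len(site.left_arm) + h
    return site.start + len(site.right_arm) + (len(site.core) - h)


def _junction(left: RecombSite, right: RecombSite, start: int) -> RecombSite:
    """Site formed where ``left``'s left arm meets ``right``'s right arm."""
    state = _JUNCTION_STATE[(left.state, right.state)]
    return RecombSite(
        family=left.family,
        state=state,
        orientation=1,
        start=start,
        left_arm=left.left_arm,
        core=left.core,
        right_arm=right.right_arm,
    )


def _window_annots(
    mol: DnaMolecule,
    lo: int,
    w_len: int,
    offset: int,
    exclude: tuple[RecombSite, ...],
) -> tuple[list[Feature], list[RecombSite]]:
    """Annotations fully inside window [lo, lo+w_len), remapped by offset.

    Annotations straddling a crossover cut are dropped (the reacting sites
    are rebuilt explicitly as junction sites by the caller).
    """
    n = len(mol)
    feats: list[Feature] = []
    sites: list[RecombSite] = []
    excl = {id(s) for s in exclude}
    for f in mol.features:
        length = f.end - f.start
        rel = (f.start - lo) % n if n else 0
        if rel + length <= w_len:
            feats.append(Feature(f.kind, f.name, offset + rel, offset + rel + length, f.strand))
    for s in mol.sites:
        if id(s) in excl:
            continue
        rel = (s.start - lo) % n if n else 0
        if rel + s.length <= w_len:
            ns = RecombSite(
                s.family, s.state, s.orientation, offset + rel, s.left_arm, s.core, s.right_arm
            )
            sites.append(ns)
    return feats, sites


def _mol(
    mol_id: str,
    topology: str,
    sequence: str,
    feats: list[Feature],
    sites: list[RecombSite],
) -> DnaMolecule:
    n = len(sequence)
    for s in sites:
        s.start %= n
    return DnaMolecule(mol_id, topology, sequence, feats, sites)


def _fuse(A: DnaMolecule, a: RecombSite, B: DnaMolecule, b: RecombSite) -> list[DnaMolecule]:
    na, nb = len(A), len(B)
    ca, cb = _cut(a) % na, _cut(b) % nb
    seq = A.seg(ca, ca + na) + B.seg(cb, cb + nb)
    fa, sa = _window_annots(A, ca, na, 0, (a,))
    fb, sb = _window_annots(B, cb, nb, na, (b,))
    h = _half(a.core)
    seam = _junction(a, b, na - len(a.left_arm) - h)
    wrap = _junction(b, a, na + nb - len(b.left_arm) - h)
    return [_mol(f"{A.id}+{B.id}", "circular", seq, fa + fb, sa + sb + [seam, wrap])]


def _excise(M: DnaMolecule, a: RecombSite, b: RecombSite) -> list[DnaMolecule]:
    n = len(M)
    ca, cb = _cut(a) % n, _cut(b) % n
    if ca == cb:
        raise IncompatibleEventError("coincident crossover points")
    h = _half(a.core)
    if M.circular:
        d = (cb - ca) % n
        f1, s1 = _window_annots(M, ca, d, 0, (a, b))
        j1 = _junction(b, a, d - len(b.left_arm) - h)
        p1 = _mol(f"{M.id}.x1", "circular", M.seg(ca, ca + d), f1, s1 + [j1])
        f2, s2 = _window_annots(M, cb, n - d, 0, (a, b))
        j2 = _junction(a, b, (n - d) - len(a.left_arm) - h)
        p2 = _mol(f"{M.id}.x2", "circular", M.seg(cb, cb + n - d), f2, s2 + [j2])
        return [p2, p1]
    # linear molecule: deletion plus an excised circle
    if ca > cb:
        a, b, ca, cb = b, a, cb, ca
        h = _half(a.core)
    fc, sc = _window_annots(M, ca, cb - ca, 0, (a, b))
    jc = _junction(b, a, (cb - ca) - len(b.left_arm) - h)
    circle = _mol(f"{M.id}.x1", "circular", M.sequence[ca:cb], fc, sc + [jc])
    fl, sl = _window_annots(M, 0, ca, 0, (a, b))
    fr, sr = _window_annots(M, cb, n - cb, ca, (a, b))
    jl = _junction(a, b, ca - len(a.left_arm) - h)
    lin = _mol(
        f"{M.id}.x2", "linear", M.sequence[:ca] + M.sequence[cb:], fl + fr, sl + sr + [jl]
    )
    return [lin, circle]


def _invert(M: DnaMolecule, a: RecombSite, b: RecombSite) -> list[DnaMolecule]:
    # symmetric-system inverted repeat; sites persist, segment between the
    # crossover points is reverse-complemented in place
    n = len(M)
    fwd, rev = (a, b) if a.orientation > 0 else (b, a)
    c1, c2 = _cut(fwd) % n, _cut(rev) % n
    if c1 > c2:
        # wrap-around segment on a circle: rotate view so c1 < c2
        if not M.circular:
            raise IncompatibleEventError("inverted pair out of order on linear molecule")
        rot = M.copy()
        shift = c1
        rot.sequence = M.seg(shift, shift + n)
        for f in rot.features:
            length = f.end - f.start
            f.start = (f.start - shift) % n
            f.end = f.start + length
        for s in rot.sites:
            s.start = (s.start - shift) % n
        fwd2 = next(s for s in rot.sites if s.start == (fwd.start - shift) % n)
        rev2 = next(s for s in rot.sites if s.start == (rev.start - shift) % n)
        out = _invert(rot, fwd2, rev2)
        out[0].id = M.id
        return out
    h = _half(fwd.core)
    seq = M.sequence[:c1] + revcomp(M.sequence[c1:c2]) + M.sequence[c2:]
    feats: list[Feature] = []
    sites: list[RecombSite] = []
    for f in M.features:
        if f.end <= c1 or f.start >= c2:
            feats.append(Feature(f.kind, f.name, f.start, f.end, f.strand))
        elif c1 <= f.start and f.end <= c2:
            ns = c1 + (c2 - f.end)
            feats.append(Feature(f.kind, f.name, ns, ns + (f.end - f.start), -f.strand))
        # features straddling a cut are dropped
    for s in M.sites:
        if s is fwd or s is rev:
            continue
        if s.end <= c1 or s.start >= c2:
            sites.append(
                RecombSite(s.family, s.state, s.orientation, s.start, s.left_arm, s.core, s.right_arm)
            )
        elif c1 <= s.start and s.end <= c2:
            ns = c1 + (c2 - s.end)
            sites.append(
                RecombSite(s.family, s.state, -s.orientation, ns, s.left_arm, s.core, s.right_arm)
            )
    s1 = RecombSite(
        fwd.family, fwd.state, 1, c1 - len(fwd.left_arm) - h, fwd.left_arm, fwd.core, rev.right_arm
    )
    s2_start = c2 - (len(fwd.core) - h) - len(fwd.right_arm)
    s2 = RecombSite(
        rev.family, rev.state, -1, s2_start, rev.left_arm, rev.core, fwd.right_arm
    )
    return [_mol(M.id, M.topology, seq, feats, sites + [s1, s2])]


def _linear_exchange(
    A: DnaMolecule, a: RecombSite, B: DnaMolecule, b: RecombSite
) -> list[DnaMolecule]:
    ca, cb = _cut(a), _cut(b)
    h = _half(a.core)
    f1a, s1a = _window_annots(A, 0, ca, 0, (a, b))
    f1b, s1b = _window_annots(B, cb, len(B) - cb, ca, (a, b))
    j1 = _junction(a, b, ca - len(a.left_arm) - h)
    p1 = _mol(
        f"{A.id}+{B.id}", "linear", A.sequence[:ca] + B.sequence[cb:], f1a + f1b, s1a + s1b + [j1]
    )
    f2b, s2b = _window_annots(B, 0, cb, 0, (a, b))
    f2a, s2a = _window_annots(A, ca, len(A) - ca, cb, (a, b))
    j2 = _junction(b, a, cb - len(b.left_arm) - h)
    p2 = _mol(
        f"{B.id}+{A.id}", "linear", B.sequence[:cb] + A.sequence[ca:], f2b + f2a + [], s2b + s2a + [j2]
    )
    return [p1, p2]


def _integrate_linear(
    C: DnaMolecule, a: RecombSite, L: DnaMolecule, b: RecombSite
) -> list[DnaMolecule]:
    nc = len(C)
    ca, cb = _cut(a) % nc, _cut(b)
    h = _half(a.core)
    seq = L.sequence[:cb] + C.seg(ca, ca + nc) + L.sequence[cb:]
    fl1, sl1 = _window_annots(L, 0, cb, 0, (b,))
    fc, sc = _window_annots(C, ca, nc, cb, (a,))
    fl2, sl2 = _window_annots(L, cb, len(L) - cb, cb + nc, (b,))
    j1 = _junction(b, a, cb - len(b.left_arm) - h)
    j2 = _junction(a, b, cb + nc - len(a.left_arm) - h)
    return [
        _mol(f"{L.id}::{C.id}", "linear", seq, fl1 + fc + fl2, sl1 + sc + sl2 + [j1, j2])
    ]


def _orientation_ok(a: RecombSite, b: RecombSite, same_molecule: bool) -> bool:
    if a.orientation > 0 and b.orientation > 0:
        return True
    if same_molecule and a.family.symmetric and a.orientation != b.orientation:
        return True  # inverted repeat, symmetric systems only
    return False


def classify_mode(
    a: RecombSite, mol_a: DnaMolecule, b: RecombSite, mol_b: DnaMolecule
) -> str:
    if mol_a.id == mol_b.id:
        return "excision" if a.orientation == b.orientation else "inversion"
    if mol_a.circular and mol_b.circular:
        return "fusion"
    if not mol_a.circular and not mol_b.circular:
        return "linear_exchange"
    return "integration_into_linear"


def enumerate_events(
    molecules: list[DnaMolecule], enzymes: set[Enzyme] | list[Enzyme]
) -> list[ReactionEvent]:
    """Every feasible site pair under the resident enzymes, in stable order.

    Events never auto-apply; callers (strategy executors) pick the screened
    outcome. Ordering is by (molecule id, site start) of the lexicographically
    smaller endpoint, then the larger one.
    """
    enz = sorted(enzymes, key=lambda e: (e.system, e.has_xis, e.has_int))
    by_id = {m.id: m for m in molecules}
    if len(by_id) != len(molecules):
        raise ValueError("molecule ids must be unique")
    refs = [
        (m.id, i, s)
        for m in sorted(molecules, key=lambda m: m.id)
        for i, s in enumerate(m.sites)
    ]
    events: list[ReactionEvent] = []
    for x in range(len(refs)):
        ida, ia, sa = refs[x]
        for y in range(x + 1, len(refs)):
            idb, ib, sb = refs[y]
            same = ida == idb
            if not _orientation_ok(sa, sb, same):
                continue
            klass = None
            chosen = None
            for e in enz:
                klass = compatible(sa, sb, e)
                if klass:
                    chosen = e
                    break
            if not klass:
                continue
            mode = classify_mode(sa, by_id[ida], sb, by_id[idb])
            ea, eb = (ida, ia), (idb, ib)
            if (idb, sb.start, ib) < (ida, sa.start, ia):
                ea, eb = eb, ea
            events.append(ReactionEvent(chosen, ea[0], ea[1], eb[0], eb[1], mode))
    events.sort(
        key=lambda ev: (ev.mol_a, by_id[ev.mol_a].sites[ev.site_a].start, ev.mol_b,
                        by_id[ev.mol_b].sites[ev.site_b].start)
    )
    return events


def recombine(
    event: ReactionEvent, molecules: list[DnaMolecule]
) -> list[DnaMolecule]:
    """Apply one recombination event; returns the product molecules.

    The input molecules referenced by the event are consumed; all other
    molecules are untouched (and not returned). Raises
    IncompatibleEventError with a diagnostic report for infeasible events.
    """
    by_id = {m.id: m for m in molecules}
    try:
        A, B = by_id[event.mol_a], by_id[event.mol_b]
        a, b = A.sites[event.site_a], B.sites[event.site_b]
    except (KeyError, IndexError) as exc:
        raise IncompatibleEventError(f"dangling site reference: {exc}") from exc
    klass = compatible(a, b, event.enzyme)
    if not klass:
        raise IncompatibleEventError(compatibility_report(a, b, event.enzyme))
    same = A.id == B.id
    if not _orientation_ok(a, b, same):
        raise IncompatibleEventError(
            "unsupported site orientations (anti-parallel att pair or "
            "reverse-strand pair); flip the molecule instead"
        )
    mode = classify_mode(a, A, b, B)
    if mode != event.mode:
        raise IncompatibleEventError(
            f"event mode {event.mode!r} does not match topology-derived {mode!r}"
        )
    # order the two reacting sites so that the lower-coordinate one is "a";
    # products are independent of the labelling but junction naming is stable
    if same:
        if mode == "excision":
            if (b.start, b.end) < (a.start, a.end):
                a, b = b, a
            return _excise(A, a, b)
        return _invert(A, a, b)
    if mode == "fusion":
        return _fuse(A, a, B, b)
    if mode == "linear_exchange":
        return _linear_exchange(A, a, B, b)
    # integration into linear: normalise so the circle is first
    if A.circular:
        return _integrate_linear(A, a, B, b)
    return _integrate_linear(B, b, A, a)
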