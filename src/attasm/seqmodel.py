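"""Core data model: DNA molecules, annotated features and recombination sites.

Coordinates are 0-based, half-open. On circular molecules a span may wrap the
origin, in which case ``end`` exceeds the molecule length and is reduced
modulo the length on access. The molecule sequence is always the forward
strand; reverse-orientation sites store their arm/core strings in site
orientation (i.e. already reverse-complemented).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "SYMMETRIC_SYSTEMS",
    "ATT_SYSTEMS",
    "ATT_STATES",
    "MARKER_NAMES",
    "ORIGIN_NAMES",
    "SiteFamily",
    "RecombSite",
    "Feature",
    "DnaMolecule",
    "revcomp",
    "canonicalize",
    "find_sites",
]

#: recombination systems whose sites are unchanged by recombination (Rule 2
#: substrates: Cre/loxP and FLP/frt)
SYMMETRIC_SYSTEMS = frozenset({"P1-lox", "FLP-frt"})

#: phage attachment-site systems with the binary B + P = L + R algebra
ATT_SYSTEMS = frozenset({"lambda", "HK022", "Phi80"})

ATT_STATES = frozenset({"B", "P", "L", "R"})

#: constitutively expressed antibiotic-resistance markers used for screening
MARKER_NAMES = frozenset({"kan", "cat", "gen"})

ORIGIN_NAMES = frozenset({"standard", "R6Kgamma", "chromosomal", "N15_linear"})

FEATURE_KINDS = frozenset(
    {"payload", "marker", "origin", "promoter", "terminator", "landing_pad"}
)

_COMPLEMENT = str.maketrans("ACGTRYKMSWBDHVN", "TGCAYRMKSWVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an (IUPAC, uppercase) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SiteFamily:
    """A recombination system plus variant label.

    ``variant`` distinguishes e.g. the two mutated lambda attachment-site
    pairs ("1", "2"); it is "" for systems with a unique site.
    """

    system: str
    variant: str = ""

    def __post_init__(self) -> None:
        if self.system not in ATT_SYSTEMS | SYMMETRIC_SYSTEMS:
            raise ValueError(f"unknown recombination system: {self.system!r}")

    @property
    def symmetric(self) -> bool:
        return self.system in SYMMETRIC_SYSTEMS

    def __str__(self) -> str:  # e.g. "lambda-1", "HK022"
        return f"{self.system}-{self.variant}" if self.variant else self.system


@dataclass
class RecombSite:
    """An annotated recombination site on a molecule.

    ``state`` is one of B/P/L/R for att systems and "symmetric" for loxP/frt.
    ``start`` is the molecule coordinate of the first base of the site
    (left arm first in molecule orientation).
    """

    family: SiteFamily
    state: str
    orientation: int  # +1 forward, -1 reverse
    start: int
    left_arm: str
    core: str
    right_arm: str

    def __post_init__(self) -> None:
        if self.family.symmetric:
            if self.state != "symmetric":
                raise ValueError(
                    f"{self.family} admits only the symmetric state, got {self.state!r}"
                )
        elif self.state not in ATT_STATES:
            raise ValueError(f"invalid att state {self.state!r} for {self.family}")
        if not self.core:
            raise ValueError("site core must be non-empty")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be +1 or -1")

    @property
    def length(self) -> int:
        return len(self.left_arm) + len(self.core) + len(self.right_arm)

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def site_seq(self) -> str:
        """Full site sequence in site orientation."""
        return self.left_arm + self.core + self.right_arm

    def forward_seq(self) -> str:
        """Full site sequence on the molecule's forward strand."""
        s = self.site_seq()
        return s if self.orientation > 0 else revcomp(s)


@dataclass
class Feature:
    """A non-site annotation (payload gene, marker, origin, ...)."""

    kind: str
    name: str
    start: int
    end: int
    strand: int = 1

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "marker" and self.name not in MARKER_NAMES:
            raise ValueError(f"marker name must be one of {sorted(MARKER_NAMES)}")
        if self.kind == "origin" and self.name not in ORIGIN_NAMES:
            raise ValueError(f"origin name must be one of {sorted(ORIGIN_NAMES)}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class DnaMolecule:
    """A linear or circular DNA molecule with features and recombination sites."""

    id: str
    topology: str  # "circular" | "linear"
    sequence: str
    features: list[Feature] = field(default_factory=list)
    sites: list[RecombSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"invalid topology {self.topology!r}")
        self.sequence = self.sequence.upper()
        n = len(self.sequence)
        for s in self.sites:
            if not 0 <= s.start < max(n, 1):
                s.start %= n
        if self.topology == "linear":
            for s in self.sites:
                if s.end > n:
                    raise ValueError(f"site span {s.span} outside linear molecule")
            for f in self.features:
                if f.end > n:
                    raise ValueError(f"feature span {f.span} outside linear molecule")
        self._check_site_overlap()

    def _check_site_overlap(self) -> None:
        n = len(self.sequence)
        occupied: set[int] = set()
        for s in self.sites:
            pos = {p % n for p in range(s.start, s.end)} if n else set()
            if occupied & pos:
                raise ValueError(f"overlapping recombination sites on {self.id!r}")
            occupied |= pos

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"

    def seg(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps the origin on circular molecules."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if not self.circular:
            raise ValueError("span exceeds linear molecule")
        start %= n
        end = start + (end - start)
        return (self.sequence * 2)[start:end]

    def copy(self, new_id: str | None = None) -> "DnaMolecule":
        return DnaMolecule(
            id=new_id or self.id,
            topology=self.topology,
            sequence=self.sequence,
            features=[replace(f) for f in self.features],
            sites=[replace(s) for s in self.sites],
        )


def _min_rotation(s: str) -> int:
    """Index of the lexicographically smallest rotation (Booth's algorithm)."""
    n = len(s)
    if n == 0:
        return 0
    ss = s + s
    f = [-1] * len(ss)
    k = 0
    for j in range(1, len(ss)):
        sj = ss[j]
        i = f[j - k - 1]
        while i != -1 and sj != ss[k + i + 1]:
            if sj < ss[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != ss[k + i + 1]:
            if sj < ss[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonicalize(mol: DnaMolecule) -> DnaMolecule:
    """Rotate a circular molecule to its lexicographically smallest rotation.

    Feature and site coordinates are shifted consistently; linear molecules
    are returned unchanged (as a copy). Idempotent, so rotational variants of
    the same circle compare equal after canonicalization.
    """
    out = mol.copy()
    if not mol.circular or len(mol) == 0:
        out.features.sort(key=lambda f: (f.start, f.end, f.name))
        out.sites.sort(key=lambda s: s.start)
        return out
    n = len(mol)
    r = _min_rotation(mol.sequence)
    out.sequence = mol.sequence[r:] + mol.sequence[:r]
    for f in out.features:
        length = f.end - f.start
        f.start = (f.start - r) % n
        f.end = f.start + length
    for s in out.sites:
        s.start = (s.start - r) % n
    out.features.sort(key=lambda f: (f.start, f.end, f.name))
    out.sites.sort(key=lambda s: s.start)
    return out


def molecules_equal(a: DnaMolecule, b: DnaMolecule) -> bool:
    """Canonical-form equality: same topology/sequence/annotation content."""
    ca, cb = canonicalize(a), canonicalize(b)
    if ca.topology != cb.topology or ca.sequence != cb.sequence:
        return False
    fa = [(f.kind, f.name, f.start, f.end, f.strand) for f in ca.features]
    fb = [(f.kind, f.name, f.start, f.end, f.strand) for f in cb.features]
    sa = [
        (s.family, s.state, s.orientation, s.start, s.left_arm, s.core, s.right_arm)
        for s in ca.sites
    ]
    sb = [
        (s.family, s.state, s.orientation, s.start, s.left_arm, s.core, s.right_arm)
        for s in cb.sites
    ]
    return fa == fb and sa == sb


def find_sites(
    mol: DnaMolecule,
    family: SiteFamily | None = None,
    state: str | None = None,
    system: str | None = None,
) -> list[RecombSite]:
    """Sites of ``mol`` filtered by family/system/state, ordered by start."""
    out = []
    for s in sorted(mol.sites, key=lambda s: s.start):
        if family is not None and s.family != family:
            continue
        if system is not None and s.family.system != system:
            continue
        if state is not None and s.state != state:
            continue
        out.append(s)
    return out
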