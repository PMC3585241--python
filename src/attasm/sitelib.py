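"""Site library: full recombination-site sequences for each system.

The shipped library (``data/sites.tsv``) pins the published attB core
sequences for the lambda (variants 1 and 2) and HK022 attachment systems and
uses deterministic synthetic placeholders for every arm and for the Phi80
core, since full att site sequences are not part of the published design.
Users can supply their own library file with wild-type arms; the
recombination algebra itself only requires that partner sites share a core.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

from .seqmodel import RecombSite, SiteFamily

__all__ = ["SiteSpec", "SiteLibrary", "load_library", "default_library"]


@dataclass(frozen=True)
class SiteSpec:
    family: SiteFamily
    core: str
    b_left: str
    b_right: str
    p_left: str
    p_right: str

    def arms(self, state: str) -> tuple[str, str]:
        """(left_arm, right_arm) for a site in the given state.

        attL carries the B left arm and the P right arm; attR the converse.
        Symmetric sites reuse the B columns.
        """
        return {
            "B": (self.b_left, self.b_right),
            "P": (self.p_left, self.p_right),
            "L": (self.b_left, self.p_right),
            "R": (self.p_left, self.b_right),
            "symmetric": (self.b_left, self.b_right),
        }[state]


class SiteLibrary:
    def __init__(self, specs: dict[tuple[str, str], SiteSpec]):
        self._specs = specs

    def spec(self, system: str, variant: str = "") -> SiteSpec:
        try:
            return self._specs[(system, variant)]
        except KeyError:
            raise KeyError(f"no site library entry for {system!r} variant {variant!r}")

    def site(
        self,
        system: str,
        variant: str = "",
        state: str = "B",
        start: int = 0,
        orientation: int = 1,
    ) -> RecombSite:
        """Construct a RecombSite of the requested state at ``start``."""
        sp = self.spec(system, variant)
        if sp.family.symmetric:
            state = "symmetric"
        left, right = sp.arms(state)
        return RecombSite(
            family=sp.family,
            state=state,
            orientation=orientation,
            start=start,
            left_arm=left,
            core=sp.core,
            right_arm=right,
        )

    def core(self, system: str, variant: str = "") -> str:
        return self.spec(system, variant).core


def load_library(path: str | Path | None = None) -> SiteLibrary:
    """Load a site library TSV (defaults to the shipped library)."""
    if path is None:
        text = (
            resources.files("attasm").joinpath("data/sites.tsv").read_text("utf-8")
        )
    else:
        text = Path(path).read_text("utf-8")
    specs: dict[tuple[str, str], SiteSpec] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 7:
            raise ValueError(f"site library line {lineno}: expected 7 columns")
        system, variant, core, bl, br, pl, pr = parts
        variant = "" if variant == "-" else variant
        fam = SiteFamily(system, variant)
        if fam.symmetric:
            pl, pr = bl, br
        specs[(system, variant)] = SiteSpec(fam, core, bl, br, pl, pr)
    return SiteLibrary(specs)


_default: SiteLibrary | None = None


def default_library() -> SiteLibrary:
    global _default
    if _default is None:
        _default = load_library()
    return _default
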