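"""Amino-acid substitution records shared by the allele screen and the
structure-proximity analysis."""

from __future__ import annotations

from dataclasses import dataclass

AA_CODES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True, order=True)
class MutationRecord:
    """A single amino-acid substitution, e.g. R201C.

    ``position`` is 1-based in the reference (E. coli) numbering. ``origin``
    tags the species in which the substitution was observed.
    """

    wt_aa: str
    position: int
    var_aa: str
    origin: str | None = None

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_CODES or self.var_aa not in AA_CODES:
            raise ValueError(f"invalid amino-acid code in {self.wt_aa}/{self.var_aa}")
        if self.wt_aa == self.var_aa:
            raise ValueError("wild-type and variant residues are identical")
        if self.position < 1:
            raise ValueError("positions are 1-based")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.var_aa}"

    @classmethod
    def parse(cls, text: str, origin: str | None = None) -> "MutationRecord":
        """Parse a wt-pos-var string like ``"R201C"``."""
        text = text.strip()
        if len(text) < 3:
            raise ValueError(f"cannot parse substitution {text!r}")
        return cls(wt_aa=text[0], position=int(text[1:-1]), var_aa=text[-1],
                   origin=origin)
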