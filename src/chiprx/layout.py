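"""Combined two-organism genome layout.

Quantitative ChIP-seq with exogenous spike-in chromatin (ChIP-Rx) aligns
reads against a single reference built by concatenating the primary genome
(e.g. hg19 or mm9) with the spike-in genome (e.g. dm6 or sf9).  Chromosomes
of the combined reference live in one namespace; each organism contributes
names carrying a distinguishing prefix (``hs_chr1``, ``dm_chr2L``).  A
:class:`GenomeLayout` records that namespace rule together with chromosome
lengths, and is the authority every downstream stage uses to resolve a
chromosome name to its organism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

PRIMARY = "primary"
SPIKEIN = "spikein"


@dataclass(frozen=True)
class Organism:
    """One organism of the combined reference.

    Parameters
    ----------
    name
        Organism label (e.g. ``"human"``).
    role
        Either ``"primary"`` or ``"spikein"``.
    prefix
        Prefix prepended to this organism's chromosome names in the
        combined namespace.
    chromosomes
        Mapping of bare chromosome name -> length in bp.
    """

    name: str
    role: str
    prefix: str
    chromosomes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in (PRIMARY, SPIKEIN):
            raise ValueError(f"organism role must be 'primary' or 'spikein', got {self.role!r}")
        for chrom, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} of {self.name!r} has non-positive length {length}")

    def combined_names(self) -> list[str]:
        return [self.prefix + c for c in self.chromosomes]


class GenomeLayout:
    """Two-organism chromosome namespace with prefix-based resolution.

    Exactly one organism is flagged primary and one spike-in.  Every
    combined chromosome name must resolve to exactly one organism via its
    prefix; ambiguous prefixes are rejected at construction.
    """

    def __init__(self, organisms: list[Organism]):
        if len(organisms) != 2:
            raise ValueError(f"layout requires exactly two organisms, got {len(organisms)}")
        roles = sorted(o.role for o in organisms)
        if roles != [PRIMARY, SPIKEIN]:
            raise ValueError("layout requires exactly one primary and one spikein organism")
        if organisms[0].name == organisms[1].name:
            raise ValueError("organism labels must be distinct")
        self.organisms = list(organisms)
        self._by_name = {o.name: o for o in organisms}
        # combined name -> (organism name, length); prefixes may not collide
        self._resolve: dict[str, tuple[str, int]] = {}
        for org in organisms:
            for chrom, length in org.chromosomes.items():
                combined = org.prefix + chrom
                if combined in self._resolve:
                    raise ValueError(f"combined chromosome name {combined!r} is ambiguous")
                self._resolve[combined] = (org.name, length)

    @property
    def primary(self) -> Organism:
        return next(o for o in self.organisms if o.role == PRIMARY)

    @property
    def spikein(self) -> Organism:
        return next(o for o in self.organisms if o.role == SPIKEIN)

    def organism_of(self, chrom: str) -> str:
        """Resolve a combined chromosome name to its organism label."""
        try:
            return self._resolve[chrom][0]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} does not resolve to any organism in the layout") from None

    def chrom_length(self, chrom: str) -> int:
        try:
            return self._resolve[chrom][1]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} does not resolve to any organism in the layout") from None

    def chromosomes(self, organism: str | None = None) -> dict[str, int]:
        """Combined-name -> length map, optionally restricted to one organism."""
        if organism is None:
            return {c: l for c, (_, l) in self._resolve.items()}
        return {c: l for c, (o, l) in self._resolve.items() if o == organism}

    def primary_chromosomes(self) -> dict[str, int]:
        return self.chromosomes(self.primary.name)

    def spikein_chromosomes(self) -> dict[str, int]:
        return self.chromosomes(self.spikein.name)

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "organisms": [
                {
                    "name": o.name,
                    "role": o.role,
                    "prefix": o.prefix,
                    "chromosomes": dict(o.chromosomes),
                }
                for o in self.organisms
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenomeLayout":
        orgs = [
            Organism(
                name=e["name"],
                role=e["role"],
                prefix=e["prefix"],
                chromosomes={str(k): int(v) for k, v in e["chromosomes"].items()},
            )
            for e in d["organisms"]
        ]
        return cls(orgs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GenomeLayout":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        p, s = self.primary, self.spikein
        return (
            f"GenomeLayout(primary={p.name!r} [{len(p.chromosomes)} chroms], "
            f"spikein={s.name!r} [{len(s.chromosomes)} chroms])"
        )
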