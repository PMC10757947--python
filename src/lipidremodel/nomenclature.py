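"""Lipid shorthand nomenclature: parsing, formatting, and the headgroup taxonomy.

Species names follow the shorthand used in plant leaf lipidomics:

* sum composition: ``"DGDG 36:6"`` — headgroup class plus total acyl
  carbons : total double-bond equivalents;
* acyl-resolved: ``"TG 18:3_18:3_18:2"`` — underscore-separated chains
  (order preserved as given; no sn-position semantics implied);
* oxidized chains: ``"DGDG 16:0_18:3;O"`` — ``;O`` (or ``;O2`` ...) appends
  oxygens beyond the carbonyl oxygen to the chain it follows;
* sterol lipids: ``"sitosterol 18:2"`` (sterol ester, SE),
  ``"Sitosterol-Glc"`` (sterol glycoside, SG), and
  ``"Sitosterol-Glc 16:0"`` (acylated sterol glycoside, ASG).

The headgroup taxonomy (acyl positions per class, plastidic vs
extra-plastidic compartment, membrane-diacyl status) ships as a TSV in
``lipidremodel/data`` and can be overridden by the user.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "AcylChain",
    "HeadgroupClass",
    "LipidSpecies",
    "LipidNameError",
    "UnresolvedSpeciesError",
    "load_taxonomy",
    "DEFAULT_TAXONOMY",
    "STEROL_MOIETIES",
    "parse_species",
    "format_species",
    "count_acyl_occurrences",
    "contains_chain",
]


class LipidNameError(ValueError):
    """A species name could not be parsed or failed validation."""


class UnresolvedSpeciesError(ValueError):
    """The operation needs acyl-resolved chains but the species has only a
    sum composition."""


_CHAIN_RE = re.compile(r"^(\d+):(\d+)(?:;O(\d*))?$")

STEROL_MOIETIES = ("sitosterol", "stigmasterol", "campesterol")


@dataclass(frozen=True, order=True)
class AcylChain:
    """One fatty acyl chain: carbons, double-bond equivalents, and oxygens
    beyond the carbonyl oxygen (the ``;O`` notation)."""

    carbons: int
    double_bonds: int
    extra_oxygens: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise LipidNameError(f"acyl chain needs >= 1 carbon, got {self.carbons}")
        if self.double_bonds < 0 or self.extra_oxygens < 0:
            raise LipidNameError("double bonds and extra oxygens must be >= 0")
        if self.double_bonds > self.carbons // 2:
            raise LipidNameError(
                f"chain {self.carbons}:{self.double_bonds} has more double-bond "
                f"equivalents than chemically possible"
            )

    @classmethod
    def parse(cls, token: str) -> "AcylChain":
        m = _CHAIN_RE.match(token.strip())
        if m is None:
            raise LipidNameError(f"malformed acyl chain token {token!r}")
        ox = 0
        if m.group(3) is not None:
            ox = int(m.group(3)) if m.group(3) else 1
        return cls(int(m.group(1)), int(m.group(2)), ox)

    def __str__(self) -> str:
        base = f"{self.carbons}:{self.double_bonds}"
        if self.extra_oxygens == 0:
            return base
        if self.extra_oxygens == 1:
            return base + ";O"
        return f"{base};O{self.extra_oxygens}"


@dataclass(frozen=True)
class HeadgroupClass:
    """A headgroup family (DGDG, PC, TG, ...) and what is known about it."""

    name: str
    n_acyl_positions: Optional[int]  # None when unknown (e.g. GSL)
    compartment: str
    is_membrane_diacyl: bool

    def __post_init__(self) -> None:
        if self.is_membrane_diacyl and self.n_acyl_positions != 2:
            raise ValueError(f"{self.name}: membrane-diacyl classes carry 2 chains")


def load_taxonomy(path=None) -> dict[str, HeadgroupClass]:
    """Load the headgroup taxonomy from a TSV (name, positions, compartment,
    membrane_diacyl). Defaults to the packaged table."""
    if path is None:
        src = resources.files("lipidremodel").joinpath("data/headgroup_classes.tsv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, sep="\t", dtype={"positions": "object"})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"positions": "object"})
    out: dict[str, HeadgroupClass] = {}
    for row in df.itertuples(index=False):
        pos = None if pd.isna(row.positions) or row.positions == "NA" else int(row.positions)
        out[row.name] = HeadgroupClass(
            name=row.name,
            n_acyl_positions=pos,
            compartment=row.compartment,
            is_membrane_diacyl=bool(int(row.membrane_diacyl)),
        )
    return out


DEFAULT_TAXONOMY: dict[str, HeadgroupClass] = load_taxonomy()

#: plastidic membrane-diacyl classes (thylakoid/envelope lipids)
PLASTIDIC_DIACYL = ("DGDG", "MGDG", "SQDG", "PG")
#: extra-plastidic membrane-diacyl classes (ER/plasma-membrane phospholipids)
EXTRAPLASTIDIC_DIACYL = ("PC", "PE", "PI", "PS", "PA")


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid analyte: headgroup class plus either a sum composition
    (total C : total DB) or a resolved acyl-chain list."""

    headgroup: HeadgroupClass
    total_carbons: int
    total_double_bonds: int
    total_extra_oxygens: int = 0
    chains: Optional[tuple[AcylChain, ...]] = None
    sterol_moiety: Optional[str] = None
    acyl_resolved: bool = False

    def __post_init__(self) -> None:
        if self.chains is not None and len(self.chains) > 0:
            if sum(c.carbons for c in self.chains) != self.total_carbons:
                raise LipidNameError("chain carbons do not sum to total carbons")
            if sum(c.double_bonds for c in self.chains) != self.total_double_bonds:
                raise LipidNameError("chain double bonds do not sum to total")
            if sum(c.extra_oxygens for c in self.chains) != self.total_extra_oxygens:
                raise LipidNameError("chain extra oxygens do not sum to total")
            npos = self.headgroup.n_acyl_positions
            if npos is not None and len(self.chains) != npos:
                raise LipidNameError(
                    f"{self.headgroup.name} carries {npos} acyl position(s), "
                    f"got {len(self.chains)} chains"
                )

    @property
    def name(self) -> str:
        return format_species(self)

    def __str__(self) -> str:
        return self.name


def _sterol_head(token: str) -> tuple[Optional[str], bool]:
    """Return (moiety, has_glc) if the token is a sterol head, else (None, False)."""
    t = token.lower()
    for m in STEROL_MOIETIES:
        if t == m:
            return m, False
        if t == f"{m}-glc":
            return m, True
    return None, False


def parse_species(name: str, taxonomy: Mapping[str, HeadgroupClass] | None = None) -> LipidSpecies:
    """Parse a shorthand species name into a validated :class:`LipidSpecies`.

    Raises :class:`LipidNameError` for unknown headgroup codes, malformed
    C:DB compositions, or chain counts inconsistent with the headgroup.
    """
    taxonomy = taxonomy if taxonomy is not None else DEFAULT_TAXONOMY
    if not name or not name.strip():
        raise LipidNameError("empty species name")
    parts = name.strip().split()
    head, comp = parts[0], " ".join(parts[1:]) if len(parts) > 1 else ""

    moiety, has_glc = _sterol_head(head)
    if moiety is not None:
        if has_glc and not comp:  # sterol glycoside, no acyl chain
            hg = taxonomy["SG"]
            return LipidSpecies(hg, 0, 0, 0, chains=(), sterol_moiety=moiety,
                                acyl_resolved=True)
        if not comp:
            raise LipidNameError(f"sterol ester {head!r} needs an acyl chain")
        chain = AcylChain.parse(comp)
        hg = taxonomy["ASG" if has_glc else "SE"]
        return LipidSpecies(hg, chain.carbons, chain.double_bonds, chain.extra_oxygens,
                            chains=(chain,), sterol_moiety=moiety, acyl_resolved=True)

    if head not in taxonomy:
        raise LipidNameError(f"unknown headgroup code {head!r} in {name!r}")
    hg = taxonomy[head]
    npos = hg.n_acyl_positions
    if npos == 0:
        if comp:
            raise LipidNameError(f"{head} carries no acyl chains, got {comp!r}")
        return LipidSpecies(hg, 0, 0, 0, chains=(), acyl_resolved=True)
    if not comp:
        raise LipidNameError(f"{head!r} needs an acyl composition")

    if "_" in comp:
        chains = tuple(AcylChain.parse(tok) for tok in comp.split("_"))
        if npos is None:
            raise LipidNameError(
                f"{head} has unknown chain count; acyl-resolved name {name!r} invalid")
        return LipidSpecies(
            hg,
            sum(c.carbons for c in chains),
            sum(c.double_bonds for c in chains),
            sum(c.extra_oxygens for c in chains),
            chains=chains,
            acyl_resolved=True,
        )

    tot = AcylChain.parse(comp)  # sum composition reuses the chain grammar
    if npos == 1:
        # a single-position class: the sum composition IS the one chain
        return LipidSpecies(hg, tot.carbons, tot.double_bonds, tot.extra_oxygens,
                            chains=(tot,), acyl_resolved=True)
    return LipidSpecies(hg, tot.carbons, tot.double_bonds, tot.extra_oxygens,
                        chains=None, acyl_resolved=False)


def format_species(species: LipidSpecies) -> str:
    """Canonical shorthand for a species; ``parse_species(format_species(s))``
    is structurally equal to ``s``."""
    hg = species.headgroup
    if species.sterol_moiety is not None:
        if hg.name == "SG":
            return f"{species.sterol_moiety.capitalize()}-Glc"
        chain = str(species.chains[0])
        if hg.name == "ASG":
            return f"{species.sterol_moiety.capitalize()}-Glc {chain}"
        return f"{species.sterol_moiety} {chain}"  # SE, lowercase per convention
    if hg.n_acyl_positions == 0:
        return hg.name
    if species.acyl_resolved and hg.n_acyl_positions == 1:
        return f"{hg.name} {species.chains[0]}"
    if species.acyl_resolved:
        return f"{hg.name} " + "_".join(str(c) for c in species.chains)
    base = f"{species.total_carbons}:{species.total_double_bonds}"
    if species.total_extra_oxygens == 1:
        base += ";O"
    elif species.total_extra_oxygens > 1:
        base += f";O{species.total_extra_oxygens}"
    return f"{hg.name} {base}"


def count_acyl_occurrences(species: LipidSpecies) -> dict[AcylChain, int]:
    """Multiplicity of each acyl chain in an acyl-resolved species.

    Oxidized chains are distinct keys from their unoxidized forms.
    Raises :class:`UnresolvedSpeciesError` for sum-composition species.
    """
    if not species.acyl_resolved or species.chains is None:
        raise UnresolvedSpeciesError(
            f"{species.name}: fatty acyl composition is ambiguous; only "
            f"acyl-resolved species can be counted")
    counts: dict[AcylChain, int] = {}
    for c in species.chains:
        counts[c] = counts.get(c, 0) + 1
    return counts


def contains_chain(
    species: LipidSpecies,
    chain: AcylChain,
    inference: Mapping[str, Sequence[AcylChain]] | None = None,
) -> bool:
    """True iff ``chain`` occurs at least once in ``species``.

    For unresolved diacyl species the question is answerable only through an
    explicit, user-supplied ``inference`` lookup mapping sum compositions
    (e.g. ``"36:6"``) to chain lists; nothing is ever guessed. Without it an
    :class:`UnresolvedSpeciesError` is raised.
    """
    if species.acyl_resolved and species.chains is not None:
        return chain in species.chains
    if inference is not None and species.headgroup.n_acyl_positions == 2:
        key = f"{species.total_carbons}:{species.total_double_bonds}"
        if key in inference:
            return chain in tuple(inference[key])
    raise UnresolvedSpeciesError(
        f"{species.name}: chain content unknown for unresolved species")
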