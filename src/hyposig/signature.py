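"""Gene signatures: intersection, gene mapping, and overlap counting.

A signature is an ordered, de-duplicated list of probeset ids with an
optional list of gene symbols.  The in vitro derivation produces two
lists (regularized selection and differential expression); their
intersection is the hypoxia signature that is carried to the tumor
cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io import AnnotationTable

__all__ = [
    "Signature",
    "intersect_signatures",
    "map_probesets_to_genes",
    "overlap_count",
    "read_signature",
    "write_signature",
    "read_gmt",
]


def _norm_gene(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class Signature:
    name: str
    probesets: list[str]
    genes: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("signature name must be non-empty")
        if len(set(self.probesets)) != len(self.probesets):
            raise ValueError("duplicate probesets in signature")
        if self.genes is not None and len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate genes in signature")

    def __len__(self) -> int:
        return len(self.probesets)

    @property
    def gene_set(self) -> set[str]:
        return {_norm_gene(g) for g in (self.genes or [])}


def intersect_signatures(A: Signature, B: Signature, name: str | None = None) -> Signature:
    """Set intersection of the probeset lists, ordered by A's order."""
    b = set(B.probesets)
    common = [p for p in A.probesets if p in b]
    if not common:
        warnings.warn(f"signatures {A.name!r} and {B.name!r} have empty intersection")
    return Signature(name or f"{A.name}&{B.name}", common)


def map_probesets_to_genes(S: Signature, ann: AnnotationTable) -> Signature:
    """Attach the unique gene symbols of the mapped probesets.

    Unmapped probesets are listed in a warning and excluded from the gene
    set; the probeset list itself is unchanged.
    """
    genes: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for pid in S.probesets:
        sym = ann.gene_symbol(pid)
        if sym is None:
            unmapped.append(pid)
            continue
        key = _norm_gene(sym)
        if key not in seen:
            seen.add(key)
            genes.append(sym.strip())
    if unmapped:
        warnings.warn(f"{len(unmapped)} probesets without annotation: {unmapped}")
    return Signature(S.name, list(S.probesets), genes)


def overlap_count(genes_a: Iterable[str], genes_b: Iterable[str]) -> int:
    """|A ∩ B| on whitespace-stripped, case-insensitive symbols."""
    a = {_norm_gene(g) for g in genes_a}
    b = {_norm_gene(g) for g in genes_b}
    return len(a & b)


def read_signature(path: str | Path, name: str | None = None) -> Signature:
    """Plain text, one probeset id per line; blank lines ignored."""
    path = Path(path)
    ids = [line.strip() for line in path.read_text().splitlines() if line.strip()]
    return Signature(name or path.stem, ids)


def write_signature(S: Signature, path: str | Path) -> None:
    Path(path).write_text("".join(f"{p}\n" for p in S.probesets))


def read_gmt(path: str | Path) -> dict[str, Signature]:
    """GMT format: name <tab> description <tab> member ids."""
    out: dict[str, Signature] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *members = parts
        members = [m for m in members if m]
        out[name] = Signature(name, list(dict.fromkeys(members)))
    return out
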