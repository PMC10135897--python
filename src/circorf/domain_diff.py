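"""Domain-architecture comparison between circORF proteins and cognate isoforms.

Architectures are ordered domain-id sequences (ordered by start coordinate).
"Overlap" is defined on domain identities via subsequence containment, not
coordinate intervals; repeated domains are handled by sequence containment.
The six pairwise classes are exhaustive and mutually exclusive:

    conservedStructure   identical ordered sequences
    differentOrder       same multiset, different order
    extraDomain          parent is a proper subsequence of the circ protein
    lackingDomain        circ protein is a proper subsequence of the parent
    lackingPlusExtra     shared domains but neither contains the other
    novelDomainStructure no shared domain identity at all
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

DIFF_CLASSES = (
    "conservedStructure",
    "differentOrder",
    "extraDomain",
    "lackingDomain",
    "lackingPlusExtra",
    "novelDomainStructure",
)

# precedence used when several isoforms share the maximal domain overlap
_PRECEDENCE = {
    "conservedStructure": 0,
    "extraDomain": 1,
    "lackingDomain": 2,
    "differentOrder": 3,
    "lackingPlusExtra": 4,
    "novelDomainStructure": 5,
}


@dataclass
class DomainArchitecture:
    protein_id: str
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.domains = sorted(self.domains, key=lambda d: (d[1], d[2], d[0]))
        for _, start, end in self.domains:
            if start > end or start < 1:
                raise ValueError(f"{self.protein_id}: bad domain span [{start},{end}]")

    @property
    def ids(self) -> list[str]:
        return [d[0] for d in self.domains]


@dataclass(frozen=True)
class DomainDiffClass:
    diff_class: str
    vs_isoform: str


def _is_subsequence(short: Sequence[str], long: Sequence[str]) -> bool:
    it = iter(long)
    return all(x in it for x in short)


def compare_pair(circ: DomainArchitecture, linear: DomainArchitecture) -> str:
    """Pairwise class between one circ architecture and one cognate isoform."""
    c, p = circ.ids, linear.ids
    if c == p:
        return "conservedStructure"
    if Counter(c) == Counter(p):
        return "differentOrder"
    if _is_subsequence(p, c):
        return "extraDomain"
    if _is_subsequence(c, p):
        return "lackingDomain"
    if set(c) & set(p):
        return "lackingPlusExtra"
    return "novelDomainStructure"


def _shared_count(a: Sequence[str], b: Sequence[str]) -> int:
    return sum((Counter(a) & Counter(b)).values())


def classify_vs_all(
    circ: DomainArchitecture, isoforms: Sequence[DomainArchitecture]
) -> DomainDiffClass:
    """Single class per circ protein against all cognate isoforms.

    novelDomainStructure only when every pairwise comparison is novel;
    otherwise the call is made against the isoform sharing the most domains
    (ties: class precedence, then lexicographic isoform id).
    """
    if not isoforms:
        raise ValueError("empty isoform list")
    pairwise = [(iso, compare_pair(circ, iso)) for iso in isoforms]
    if all(cls == "novelDomainStructure" for _, cls in pairwise):
        best = min(pairwise, key=lambda x: x[0].protein_id)
        return DomainDiffClass("novelDomainStructure", best[0].protein_id)
    best = min(
        pairwise,
        key=lambda x: (
            -_shared_count(circ.ids, x[0].ids),
            _PRECEDENCE[x[1]],
            x[0].protein_id,
        ),
    )
    return DomainDiffClass(best[1], best[0].protein_id)


def read_domain_table(path: str | Path) -> dict[str, DomainArchitecture]:
    """Domain table TSV (protein_id, domain_id, start, end) -> architectures."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "domain_id": str})
    required = {"protein_id", "domain_id", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"domain table missing columns: {sorted(required - set(df.columns))}")
    archs: dict[str, DomainArchitecture] = {}
    for pid, group in df.groupby("protein_id", sort=True):
        archs[pid] = DomainArchitecture(
            protein_id=pid,
            domains=[(r.domain_id, int(r.start), int(r.end)) for r in group.itertuples()],
        )
    return archs


def write_domain_table(archs: Sequence[DomainArchitecture], path: str | Path) -> None:
    rows = [
        (a.protein_id, d_id, start, end)
        for a in archs
        for d_id, start, end in a.domains
    ]
    pd.DataFrame(rows, columns=["protein_id", "domain_id", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )
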