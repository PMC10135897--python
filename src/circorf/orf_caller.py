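"""Circular ORF enumeration.

A circularized spliced sequence is scanned for ORFs starting at any ATG,
translating around the circle for up to ``cycle_cap`` full traversals.  A
frame with no stop codon within the cap is a rolling-circle event: its
protein is truncated at the cap and flagged rather than reported as a
regular ORF.  With ``cycle_cap = 3`` every distinct codon phase of the
circle is provably visited (a circle of length L not divisible by 3 returns
to its starting phase after at most 3 traversals), so stop-free frames
beyond the cap are rolling-circle by definition.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.CodonTable import unambiguous_dna_by_id

_VALID = set("ACGTN")


@dataclass(frozen=True)
class CircOrf:
    start_nt: int  # 0-based offset on the spliced sequence
    frame: int  # start_nt % 3
    protein: str
    crosses_junction: bool
    cycles: int  # full circle traversals consumed (incl. the stop codon)
    rolling_circle: bool

    @property
    def length_aa(self) -> int:
        return len(self.protein)


@dataclass
class OrfParams:
    min_orf_aa: int = 50
    cycle_cap: int = 3
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.cycle_cap < 1:
            raise ValueError("cycle_cap must be >= 1")
        if self.min_orf_aa < 1:
            raise ValueError("min_orf_aa must be >= 1")


def _codon_maps(table_id: int) -> tuple[dict[str, str], frozenset[str]]:
    table = unambiguous_dna_by_id[table_id]
    return dict(table.forward_table), frozenset(table.stop_codons)


def _translate_codon(codon: str, fwd: dict[str, str], stops: frozenset[str]) -> str | None:
    """Amino acid for a codon, '*' for stop, None when ambiguous.

    N-containing codons are expanded over ACGT; if every expansion agrees on
    a single non-stop residue that residue is used, otherwise the codon is
    ambiguous.  N-containing codons never act as stops.
    """
    if "N" not in codon:
        if codon in stops:
            return "*"
        return fwd[codon]

    def expand(c: str) -> list[str]:
        if "N" not in c:
            return [c]
        out = []
        for b in "ACGT":
            out.extend(expand(c.replace("N", b, 1)))
        return out

    aas = {("*" if c in stops else fwd[c]) for c in expand(codon)}
    if len(aas) == 1 and "*" not in aas:
        return aas.pop()
    return None


def enumerate_circorfs(seq: str, params: OrfParams) -> list[CircOrf]:
    """All qualifying ORFs reachable from any ATG on the circle.

    Starts are deduplicated by position mod L.  ORFs shorter than
    ``params.min_orf_aa`` and ORFs terminated by an ambiguous codon are
    excluded; stop-free frames are reported as rolling-circle ORFs truncated
    at ``cycle_cap`` traversals.
    """
    seq = seq.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    if not set(seq) <= _VALID:
        raise ValueError(f"invalid characters in sequence: {sorted(set(seq) - _VALID)}")
    fwd, stops = _codon_maps(params.genetic_code)
    L = len(seq)
    extended = seq * (params.cycle_cap + 1)
    max_nt = params.cycle_cap * L  # translation may consume at most this many nt
    orfs: list[CircOrf] = []
    for start in range(L):
        if extended[start : start + 3] != "ATG":
            continue
        protein: list[str] = []
        consumed = 0
        stopped = False
        ambiguous = False
        while consumed + 3 <= max_nt:
            codon = extended[start + consumed : start + consumed + 3]
            aa = _translate_codon(codon, fwd, stops)
            consumed += 3
            if aa is None:
                ambiguous = True
                break
            if aa == "*":
                stopped = True
                break
            protein.append(aa)
        if ambiguous:
            continue  # ambiguity terminates extension without a stop: rejected
        rolling = not stopped
        if rolling:
            # truncate to whole codons within cycle_cap traversals (already is)
            consumed = len(protein) * 3
        if len(protein) < params.min_orf_aa:
            continue
        end_nt = start + consumed  # exclusive, on the unrolled sequence
        orfs.append(
            CircOrf(
                start_nt=start,
                frame=start % 3,
                protein="".join(protein),
                crosses_junction=end_nt > L,
                cycles=(end_nt - 1) // L + 1,
                rolling_circle=rolling,
            )
        )
    orfs.sort(key=lambda o: (o.start_nt, o.frame))
    return orfs


def longest_circorf(orfs: list[CircOrf]) -> CircOrf | None:
    """Longest non-rolling ORF; ties by smallest start, then smallest frame."""
    candidates = [o for o in orfs if not o.rolling_circle]
    if not candidates:
        return None
    return min(candidates, key=lambda o: (-o.length_aa, o.start_nt, o.frame))


def rolling_circle_events(orfs: list[CircOrf]) -> list[CircOrf]:
    return [o for o in orfs if o.rolling_circle]
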