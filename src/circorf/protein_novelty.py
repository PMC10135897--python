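"""Terminus-novelty classification of circORF proteins.

Each circORF protein is locally aligned (Smith-Waterman, BLOSUM62, affine
gaps 11/1) against the cognate linear proteins of its host gene; the best
cognate is the one with the lowest Karlin-Altschul E-value.  Alignment span
boundaries alone then determine the N-/C-terminus classes:

    N: canonicalMet (q_start=1, s_start=1), internalMet (q_start=1,
       s_start>1), N-term (q_start>1, novel prefix = n_ext)
    C: canonicalSTOP (q_end=|q|, s_end=|s|), prematureTerm (q_end=|q|,
       s_end<|s|), C-term (q_end<|q|, novel suffix = c_ext)

Records whose best E-value exceeds the threshold have no usable cognate
correspondence and are classified separately ("no cognate match").
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

# gapped BLASTP defaults for BLOSUM62 with gap open 11 / extend 1
KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041
DEFAULT_EVALUE_THRESHOLD = 1.0e-10

N_CLASSES = ("canonicalMet", "internalMet", "N-term")
C_CLASSES = ("canonicalSTOP", "prematureTerm", "C-term")


@dataclass(frozen=True)
class LocalAlignment:
    score: float
    q_start: int  # 1-based inclusive span on the query (circORF protein)
    q_end: int
    s_start: int  # span on the subject (cognate protein)
    s_end: int
    evalue: float = math.nan

    def __post_init__(self) -> None:
        if not (1 <= self.q_start <= self.q_end):
            raise ValueError("inconsistent query span")
        if not (1 <= self.s_start <= self.s_end):
            raise ValueError("inconsistent subject span")


@dataclass(frozen=True)
class TerminusAnnotation:
    n_class: str
    c_class: str
    n_ext: str
    c_ext: str
    cognate_id: str = ""

    @property
    def annotation_string(self) -> str:
        """Table-style label, novel termini first (e.g. 'C-term|canonicalMet')."""
        parts = []
        if self.c_class == "C-term":
            parts.append("C-term")
        if self.n_class == "N-term":
            parts.append("N-term")
        if self.n_class != "N-term":
            parts.append(self.n_class)
        if self.c_class != "C-term":
            parts.append(self.c_class)
        return "|".join(parts)

    @property
    def is_novel(self) -> bool:
        """True when at least one terminus differs from the cognate protein."""
        return not (self.n_class == "canonicalMet" and self.c_class == "canonicalSTOP")


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # BLAST convention: a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_local(
    query: str,
    subject: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> LocalAlignment:
    """Optimal Smith-Waterman alignment; ties broken by smallest q_start then s_start."""
    if not query or not subject:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alignments = aligner.align(query, subject)
    if len(alignments) == 0 or alignments.score <= 0:
        # no positive-scoring local alignment; degenerate single-cell span
        return LocalAlignment(score=0.0, q_start=1, q_end=1, s_start=1, s_end=1)
    best = None
    best_key = None
    # all alignments share the optimal score; pick the deterministic tie-break
    for i, aln in enumerate(alignments):
        if len(aln.aligned[0]) == 0:
            continue
        q0, q1 = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
        s0, s1 = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
        key = (q0, s0)
        if best_key is None or key < best_key:
            best_key = key
            best = (q0 + 1, q1, s0 + 1, s1)
        if i >= 200:  # degenerate inputs can have huge co-optimal sets
            break
    if best is None:
        return LocalAlignment(score=0.0, q_start=1, q_end=1, s_start=1, s_end=1)
    q_start, q_end, s_start, s_end = best
    return LocalAlignment(
        score=float(alignments.score),
        q_start=q_start, q_end=q_end, s_start=s_start, s_end=s_end,
    )


def evalue(
    score: float,
    query_len: int,
    db_len: int,
    lam: float = KARLIN_LAMBDA,
    k: float = KARLIN_K,
) -> float:
    """Karlin-Altschul expectation: E = K * m * n * exp(-lambda * score)."""
    if lam <= 0 or k <= 0:
        raise ValueError("lambda and K must be positive")
    if query_len < 1 or db_len < 1:
        raise ValueError("sequence lengths must be >= 1")
    return k * query_len * db_len * math.exp(-lam * score)


def best_cognate(
    query: str,
    cognates: Mapping[str, str],
    db_len: int | None = None,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[str, LocalAlignment]:
    """Best-matching cognate isoform: lowest E-value, ties by score then id.

    *db_len* is the total cognate database length used in the E-value
    (defaults to the summed length of the supplied isoforms).
    """
    if not cognates:
        raise ValueError("no cognate isoforms supplied")
    if db_len is None:
        db_len = sum(len(s) for s in cognates.values())
    best_id, best_aln = None, None
    for iso_id in sorted(cognates):
        aln = align_local(query, cognates[iso_id], matrix, gap_open, gap_extend)
        e = evalue(aln.score, len(query), db_len)
        aln = LocalAlignment(
            score=aln.score, q_start=aln.q_start, q_end=aln.q_end,
            s_start=aln.s_start, s_end=aln.s_end, evalue=e,
        )
        if (
            best_aln is None
            or e < best_aln.evalue
            or (e == best_aln.evalue and aln.score > best_aln.score)
        ):
            best_id, best_aln = iso_id, aln
    return best_id, best_aln


def annotate_termini(
    query_len: int,
    cognate_len: int,
    aln: LocalAlignment,
    query: str,
    cognate_id: str = "",
) -> TerminusAnnotation:
    """Classify both termini from alignment span boundaries alone."""
    if len(query) != query_len:
        raise ValueError("query_len does not match query")
    if aln.q_end > query_len or aln.s_end > cognate_len:
        raise ValueError("alignment spans exceed sequence lengths")
    if aln.q_start > 1:
        n_class, n_ext = "N-term", query[: aln.q_start - 1]
    elif aln.s_start == 1:
        n_class, n_ext = "canonicalMet", ""
    else:
        n_class, n_ext = "internalMet", ""
    if aln.q_end < query_len:
        c_class, c_ext = "C-term", query[aln.q_end :]
    elif aln.s_end == cognate_len:
        c_class, c_ext = "canonicalSTOP", ""
    else:
        c_class, c_ext = "prematureTerm", ""
    return TerminusAnnotation(
        n_class=n_class, c_class=c_class, n_ext=n_ext, c_ext=c_ext,
        cognate_id=cognate_id,
    )


def classify_protein(
    query: str,
    cognates: Mapping[str, str],
    db_len: int | None = None,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
    **align_kwargs,
) -> tuple[TerminusAnnotation | None, LocalAlignment]:
    """Full classification against a gene's cognate isoforms.

    Returns (annotation, best_alignment); annotation is None when the best
    E-value misses the threshold ("no cognate match").
    """
    cog_id, aln = best_cognate(query, cognates, db_len=db_len, **align_kwargs)
    if aln.evalue > evalue_threshold:
        return None, aln
    ann = annotate_termini(len(query), len(cognates[cog_id]), aln, query, cognate_id=cog_id)
    return ann, aln


def extension_stats(annotations: Sequence[TerminusAnnotation]) -> dict:
    """Counts per (n_class, c_class) pair and extension-length summaries."""
    counts: dict[tuple[str, str], int] = {}
    n_lens, c_lens = [], []
    for ann in annotations:
        key = (ann.n_class, ann.c_class)
        counts[key] = counts.get(key, 0) + 1
        if ann.n_ext:
            n_lens.append(len(ann.n_ext))
        if ann.c_ext:
            c_lens.append(len(ann.c_ext))

    def _summary(lens: list[int]) -> dict | None:
        if not lens:
            return None
        lens = sorted(lens)
        n = len(lens)
        median = (lens[(n - 1) // 2] + lens[n // 2]) / 2
        return {"n": n, "mean": sum(lens) / n, "median": median}

    return {
        "class_counts": counts,
        "n_ext": _summary(n_lens),
        "c_ext": _summary(c_lens),
    }
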