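"""Overlap and over-representation statistics.

Four independent engines: a two-tailed Fisher exact test on 2x2 tables
(point-probability method), generic category over-representation with BH
FDR, genomic-interval intersection against m6A peaks (0-based half-open),
and exact-substring peptide matching of novel termini against a peptide
database.  Also ships the machine-readable CN-AML prognostic circRNA table
used by the overlap test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PROGNOSTIC_TABLE_RESOURCE = "cnaml_prognostic_circrnas.tsv"


@dataclass(frozen=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def rows(self) -> tuple[tuple[int, int], tuple[int, int]]:
        return ((self.a, self.b), (self.c, self.d))


@dataclass(frozen=True)
class CategoryResult:
    category: str
    obs: int
    exp: float
    fold: float
    p: float
    fdr: float


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval."""

    chrom: str
    start: int
    end: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")


def _norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def fisher_two_tailed(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p (sum of tables at most as probable as observed)."""
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        warnings.warn("degenerate margins: p = 1")
        return 1.0
    return float(stats.fisher_exact(table.rows, alternative="two-sided")[1])


def fisher_one_tailed_greater(table: ContingencyTable) -> float:
    if (table.a + table.b == 0) or (table.c + table.d == 0) or \
       (table.a + table.c == 0) or (table.b + table.d == 0):
        warnings.warn("degenerate margins: p = 1")
        return 1.0
    return float(stats.fisher_exact(table.rows, alternative="greater")[1])


def overrepresentation(
    gene_list: Iterable[str],
    background: Iterable[str],
    category_map: Mapping[str, Iterable[str]],
    two_sided: bool = False,
) -> list[CategoryResult]:
    """Per-category obs/exp/fold with Fisher p and BH FDR.

    exp = list_size * category_size / background_size; p is one-sided
    (greater) by default since enrichment is the question of interest.
    """
    genes = set(gene_list)
    bg = set(background)
    outside = genes - bg
    if outside:
        raise ValueError(f"genes outside background: {sorted(outside)}")
    n_list, n_bg = len(genes), len(bg)
    if n_list == 0:
        return []
    raw = []
    for cat in sorted(category_map):
        members = set(category_map[cat]) & bg
        obs = len(genes & members)
        exp = n_list * len(members) / n_bg
        fold = obs / exp if exp > 0 else float("nan")
        t = ContingencyTable(
            a=obs,
            b=len(members) - obs,
            c=n_list - obs,
            d=n_bg - len(members) - (n_list - obs),
        )
        p = fisher_two_tailed(t) if two_sided else fisher_one_tailed_greater(t)
        raw.append((cat, obs, exp, fold, p))
    from statsmodels.stats.multitest import multipletests

    fdrs = multipletests([r[4] for r in raw], method="fdr_bh")[1]
    return [
        CategoryResult(category=cat, obs=obs, exp=exp, fold=fold, p=p, fdr=float(fdr))
        for (cat, obs, exp, fold, p), fdr in zip(raw, fdrs)
    ]


def enriched(results: Sequence[CategoryResult], fdr_max: float = 0.05) -> list[CategoryResult]:
    """Categories passing the FDR threshold with at least one observed gene."""
    return [r for r in results if r.obs > 0 and r.fdr < fdr_max]


def read_bed(path: str | Path, source: str = "") -> list[GenomicInterval]:
    """3-column BED (0-based half-open); malformed lines are logged and skipped."""
    peaks: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                peaks.append(
                    GenomicInterval(parts[0], int(parts[1]), int(parts[2]), source=source)
                )
            except (IndexError, ValueError) as exc:
                logger.warning("%s line %d rejected: %s", path, ln, exc)
    return peaks


def m6a_overlap(
    circ_intervals: Mapping[str, GenomicInterval],
    peaks: Sequence[GenomicInterval],
) -> tuple[dict[str, bool], int]:
    """Per-circRNA flag: shares >= 1 base with any peak. Half-open on both sides."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for p in peaks:
        by_chrom.setdefault(_norm_chrom(p.chrom), []).append((p.start, p.end))
    starts_ends: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        starts_ends[chrom] = (
            np.array([s for s, _ in ivs]),
            np.maximum.accumulate(np.array([e for _, e in ivs])),
        )
    flags: dict[str, bool] = {}
    for circ_id, iv in circ_intervals.items():
        chrom = _norm_chrom(iv.chrom)
        hit = False
        if chrom in starts_ends:
            starts, cummax_ends = starts_ends[chrom]
            # peaks with start < circ.end; overlap iff any such peak ends > circ.start
            idx = np.searchsorted(starts, iv.end, side="left")
            hit = bool(idx > 0 and cummax_ends[idx - 1] > iv.start)
        flags[circ_id] = hit
    return flags, sum(flags.values())


@dataclass(frozen=True)
class PeptideMatch:
    extension_id: str
    db_entry: str
    offset: int  # 0-based offset of the contained sequence in its container
    direction: str  # "db_in_extension" or "extension_in_db"


def match_peptides(
    extensions: Mapping[str, str],
    db: Mapping[str, str],
) -> list[PeptideMatch]:
    """Exact containment in either direction counts as a perfect overlap."""
    matches: list[PeptideMatch] = []
    for ext_id, ext in extensions.items():
        if not ext:
            continue
        for db_id, pep in db.items():
            if not pep:
                continue
            off = ext.find(pep)
            if off >= 0:
                matches.append(PeptideMatch(ext_id, db_id, off, "db_in_extension"))
                continue
            off = pep.find(ext)
            if off >= 0:
                matches.append(PeptideMatch(ext_id, db_id, off, "extension_in_db"))
    return matches


def load_prognostic_table() -> pd.DataFrame:
    """The packaged CN-AML prognostic coding-circRNA table.

    Columns: gene, chr, start, end, annotation, de_flag (bool; the published
    asterisk marking pan-cancer differential expression).
    """
    ref = resources.files("circorf.data").joinpath(PROGNOSTIC_TABLE_RESOURCE)
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["de_flag"] = df["de_flag"].astype(bool)
    return df


def prognostic_overlap_test(
    coding_ids: set[str],
    de_ids: set[str],
    prognostic_ids: set[str],
    background_size: int,
) -> tuple[ContingencyTable, float]:
    """2x2 Fisher test: prognostic membership vs differential expression,
    within a configurable background of coding circRNAs."""
    prog = prognostic_ids & coding_ids
    a = len(prog & de_ids)
    b = len(prog - de_ids)
    c = len(de_ids - prog)
    d = background_size - a - b - c
    table = ContingencyTable(a=a, b=b, c=c, d=max(d, 0))
    return table, fisher_two_tailed(table)
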