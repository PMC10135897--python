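"""Self-consistent synthetic fixtures with planted, machine-readable truth.

Every downstream stage is testable offline: the generator emits a toy genome
(FASTA), annotation (GTF), cognate proteins (FASTA), a domain table, a
backsplice TSV with per-sample reads, a sample sheet, m6A peaks (BED), a
peptide database (FASTA) and a truth table.

Construction guarantees recovery of the planted classes.  Cognate proteins
use a polar "core" alphabet (DENKRST) and novel terminus extensions use
WFY, whose BLOSUM62 cross-scores against the core are all negative, so the
optimal local alignment ends exactly at the planted boundaries.  Circular
spliced sequences carry exactly one ATG (checked circularly), so the only
ORF is the planted one; padding is built from 'TAGA' repeats, which place a
stop codon in every reading frame without introducing ATGs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_diff import DIFF_CLASSES

CORE_AA = "DENKRST"
EXT_AA = "WFY"
DECOY_AA = "HILV"  # decoy db peptides; never appear in extensions

# synonymous codons restricted to unambiguous sense codons
CODONS = {
    "M": ["ATG"],
    "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"],
    "N": ["AAT", "AAC"],
    "K": ["AAA", "AAG"],
    "R": ["CGT", "CGC", "CGA", "CGG"],
    "S": ["TCT", "TCC", "TCA", "TCG"],
    "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"],
    "F": ["TTT", "TTC"],
    "Y": ["TAT", "TAC"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC", "ATA"],
    "L": ["CTT", "CTC", "CTA", "CTG"],
    "V": ["GTT", "GTC", "GTA", "GTG"],
}
STOP = "TAA"
PAD_UNIT = "TAGA"  # stops in all 3 frames, no ATG

N_SCENARIOS = ("canonicalMet", "internalMet", "N-term")
C_SCENARIOS = ("canonicalSTOP", "prematureTerm", "C-term")
ROLLING = "rolling"
DEFAULT_CLASSES = [f"{n}+{c}" for n in N_SCENARIOS for c in C_SCENARIOS] + [ROLLING]

INTERNAL_MET_POS = 20  # 0-based index of the planted internal Met in cognates
CORE_MATCH_AA = 60  # length of the exact circ/cognate match


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 10
    exons_per_gene: tuple[int, int] = (2, 4)
    exon_len: tuple[int, int] = (130, 260)
    n_circ: int = 10
    n_samples: int = 12
    frac_cancer: float = 0.5
    planted_classes: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))
    de_effect: float = 2.0
    noise_sd: float = 0.5
    min_samples_expressed: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.frac_cancer < 1:
            raise ValueError("frac_cancer must be in (0, 1)")
        if self.de_effect < 0:
            raise ValueError("de_effect must be >= 0")
        for label in self.planted_classes:
            if label != ROLLING:
                n, _, c = label.partition("+")
                if n not in N_SCENARIOS or c not in C_SCENARIOS:
                    raise ValueError(f"unknown planted class {label!r}")
        if self.n_circ < len(self.planted_classes):
            raise ValueError(
                f"n_circ={self.n_circ} cannot realize all "
                f"{len(self.planted_classes)} planted classes"
            )
        # a 50-aa ORF plus stop needs 153 nt of exon; the two circ exons
        # must be able to host it
        if 2 * self.exon_len[1] < 3 * 51:
            raise ValueError(
                "impossible scenario: exon lengths too short to host a 50-aa ORF"
            )


TRUTH_COLUMNS = [
    "circ_id", "gene", "chrom", "start", "end", "scenario", "n_class",
    "c_class", "rolling", "domain_class", "de_status", "m6a_flag",
    "pep_n_in_db", "pep_c_in_db", "protein", "n_ext", "c_ext",
]


@dataclass
class SyntheticReference:
    config: SyntheticConfig
    out_dir: Path
    truth: pd.DataFrame
    genome_fa: Path
    annotation_gtf: Path
    proteins_fa: Path
    domains_tsv: Path
    truth_tsv: Path


def read_truth_table(path: str | Path) -> pd.DataFrame:
    """Load a truth TSV ('null' is a DE status, not missing data)."""
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    for col in ("rolling", "m6a_flag", "pep_n_in_db", "pep_c_in_db"):
        df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    for col in ("start", "end"):
        df[col] = df[col].astype(int)
    return df


def _encode(rng: np.random.Generator, protein: str) -> str:
    return "".join(CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein)


def _encode_unique_atg(rng: np.random.Generator, protein: str, tail: str) -> str:
    """Encode protein (leading M) + tail with no ATG beyond the planned Met codons.

    Codon choices are filtered against the two preceding bases (no ATG across
    a codon boundary) and against the following residue: a codon may not end
    in 'A' before Trp/Met (whose codons start 'TG'/'TG...') nor in 'AT'
    before Asp/Glu (whose codons all start 'G').  The circular closure is
    verified on the doubled string.
    """
    for _ in range(50):
        parts: list[str] = []
        ctx = ""
        ok = True
        for i, aa in enumerate(protein):
            nxt = protein[i + 1] if i + 1 < len(protein) else ""
            if aa == "M":
                choice = "ATG"
            else:
                cands = [
                    c for c in CODONS[aa]
                    if "ATG" not in ctx + c
                    and not (nxt in "WM" and c.endswith("A"))
                    and not (nxt in "DE" and c.endswith("AT"))
                ]
                if not cands:
                    ok = False
                    break
                choice = cands[int(rng.integers(len(cands)))]
            parts.append(choice)
            ctx = choice[-2:]
        if not ok:
            continue
        seq = "".join(parts) + tail
        if (seq + seq).count("ATG") == 2 * protein.count("M") and seq.startswith("ATG"):
            return seq
    raise RuntimeError("could not encode sequence without spurious ATG")


def _random_core(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(CORE_AA), size=n))


def _build_circ_protein(
    rng: np.random.Generator, scenario: str, cognate: str
) -> tuple[str, str, str]:
    """(circ protein Q, n_ext, c_ext) realizing the scenario against *cognate*."""
    n_label, _, c_label = scenario.partition("+")
    k = CORE_MATCH_AA
    if n_label == "canonicalMet":
        prefix, n_ext, core_start = "", "", 0
    elif n_label == "internalMet":
        prefix, n_ext, core_start = "", "", INTERNAL_MET_POS
    else:  # N-term
        n_ext = "M" + "".join(rng.choice(list(EXT_AA), size=int(rng.integers(4, 30))))
        prefix, core_start = n_ext, 0
    if c_label == "canonicalSTOP":
        core = cognate[core_start:]
        c_ext = ""
    elif c_label == "prematureTerm":
        core = cognate[core_start : core_start + k]
        c_ext = ""
    else:  # C-term
        core = cognate[core_start : core_start + k]
        c_ext = "".join(rng.choice(list(EXT_AA), size=int(rng.integers(5, 30))))
    return prefix + core + c_ext, n_ext, c_ext


def _plant_domains(
    gene: str, cognate_len: int, circ_len: int, domain_class: str
) -> tuple[list[tuple[str, int, int]], list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """(cognate p1 arch, cognate p2 arch, circ arch) realizing domain_class."""
    d = [f"{gene}:D{i}" for i in range(1, 4)]
    x = [f"{gene}:X{i}" for i in range(1, 3)]
    z = f"{gene}:Z"
    p1 = [(d[0], 3, 12), (d[1], 20, 32), (d[2], 40, min(52, cognate_len))]
    p2 = [(z, 3, min(15, cognate_len))]
    spans = [(2, 8), (12, 18), (22, 28), (32, 38)]
    circ_ids = {
        "conservedStructure": [d[0], d[1], d[2]],
        "differentOrder": [d[1], d[0], d[2]],
        "lackingDomain": [d[0], d[2]],
        "extraDomain": [d[0], d[1], d[2], x[0]],
        "lackingPlusExtra": [d[0], d[2], x[0]],
        "novelDomainStructure": [x[0], x[1]],
    }[domain_class]
    hi = max(6, circ_len - 2)
    circ = []
    for (s, e), did in zip(spans, circ_ids):
        circ.append((did, min(s, hi - 1), min(e, hi)))
    return p1, p2, circ


def _write_fasta(path: Path, entries: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_reference(config: SyntheticConfig, out_dir: str | Path) -> SyntheticReference:
    """Toy genome + GTF + cognate proteins + domain table + truth table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    n_genes = max(config.n_genes, config.n_circ)
    scenarios = [
        config.planted_classes[i % len(config.planted_classes)]
        for i in range(config.n_circ)
    ]
    coding_idx = [i for i, s in enumerate(scenarios) if s != ROLLING]
    domain_cycle = {
        idx: DIFF_CLASSES[j % len(DIFF_CLASSES)] for j, idx in enumerate(coding_idx)
    }

    chrom = "chr1"
    chrom_parts: list[str] = []
    cursor = 1  # 1-based genomic coordinate of the next free base
    gtf_lines: list[str] = []
    proteins: list[tuple[str, str]] = []
    domain_rows: list[tuple[str, str, int, int]] = []
    truth_rows: list[dict] = []

    def emit_junk(n: int) -> None:
        nonlocal cursor
        junk = "".join(rng.choice(list("ACGT"), size=n))
        chrom_parts.append(junk)
        cursor += n

    def emit_exon(seq: str) -> tuple[int, int]:
        nonlocal cursor
        start = cursor
        chrom_parts.append(seq)
        cursor += len(seq)
        return start, cursor - 1

    target_circ_len = int(np.mean(config.exon_len)) * 2

    for gi in range(n_genes):
        gene = f"G{gi + 1:03d}"
        has_circ = gi < config.n_circ
        scenario = scenarios[gi] if has_circ else None

        # cognate protein: M + polar core, with a planted internal Met when needed
        core = _random_core(rng, 110 + int(rng.integers(0, 30)))
        cognate = "M" + core
        if scenario is not None and scenario.startswith("internalMet"):
            cognate = cognate[:INTERNAL_MET_POS] + "M" + cognate[INTERNAL_MET_POS + 1 :]
        proteins.append((f"{gene}|p1", cognate))

        emit_junk(int(rng.integers(80, 150)))
        gene_start = cursor
        cds_seq = _encode(rng, cognate) + STOP
        e1 = emit_exon(cds_seq)
        exon_spans = [e1]
        cds_span = e1

        circ_window = None
        row: dict | None = None
        if has_circ:
            if scenario == ROLLING:
                # circle length 3*n_codons is divisible by 3, so the frame
                # from the single ATG repeats stop-free forever
                n_codons = max(52, target_circ_len // 3)
                q = "M" + _random_core(rng, n_codons - 1)
                circ_seq = _encode_unique_atg(rng, q, tail="")
                rotation = 0
                q_for_truth, n_ext, c_ext = q, "", ""
                n_class = c_class = ""
            else:
                q, n_ext, c_ext = _build_circ_protein(rng, scenario, cognate)
                orf_nt = 3 * (len(q) + 1)
                pad_n = max(0, math.ceil((target_circ_len - orf_nt - 3) / len(PAD_UNIT)))
                pad_n = max(pad_n, 2)
                circ_seq = _encode_unique_atg(rng, q, tail=STOP + PAD_UNIT * pad_n)
                # rotate C-term scenarios so the novel suffix crosses the junction
                if c_ext:
                    rotation = 3 * (len(q) - len(c_ext) + 2)
                else:
                    rotation = 0
                q_for_truth = q
                n_class, _, c_class = scenario.partition("+")
            if rotation:
                circ_seq = circ_seq[rotation:] + circ_seq[:rotation]
            half = len(circ_seq) // 2
            emit_junk(int(rng.integers(40, 90)))
            e2 = emit_exon(circ_seq[:half])
            emit_junk(int(rng.integers(40, 90)))
            e3 = emit_exon(circ_seq[half:])
            exon_spans += [e2, e3]
            circ_window = (e2[0], e3[1])

            domain_class = domain_cycle.get(gi, "")
            if scenario != ROLLING:
                p1_arch, p2_arch, circ_arch = _plant_domains(
                    gene, len(cognate), len(q_for_truth), domain_class
                )
                circ_id = f"{gene}|{chrom}:{circ_window[0]}-{circ_window[1]}"
                for did, s, e in p1_arch:
                    domain_rows.append((f"{gene}|p1", did, s, e))
                for did, s, e in p2_arch:
                    domain_rows.append((f"{gene}|p2", did, s, e))
                for did, s, e in circ_arch:
                    domain_rows.append((circ_id, did, s, e))
                # second cognate isoform: truncated protein, unrelated domain
                proteins.append((f"{gene}|p2", cognate[: len(cognate) // 2]))
            row = {
                "gene": gene,
                "chrom": chrom,
                "start": circ_window[0],
                "end": circ_window[1],
                "scenario": scenario,
                "n_class": n_class,
                "c_class": c_class,
                "rolling": scenario == ROLLING,
                "domain_class": domain_class if scenario != ROLLING else "",
                "protein": q_for_truth,
                "n_ext": n_ext,
                "c_ext": c_ext,
            }
            row["circ_id"] = f"{gene}|{chrom}:{circ_window[0]}-{circ_window[1]}"

        gene_end = cursor - 1
        tid = f"{gene}.t1"
        attrs = f'gene_id "{gene}"; transcript_id "{tid}";'
        gtf_lines.append(
            f"{chrom}\tcircorf_sim\tgene\t{gene_start}\t{gene_end}\t.\t+\t.\tgene_id \"{gene}\";"
        )
        gtf_lines.append(
            f"{chrom}\tcircorf_sim\ttranscript\t{gene_start}\t{gene_end}\t.\t+\t.\t{attrs}"
        )
        for s, e in exon_spans:
            gtf_lines.append(f"{chrom}\tcircorf_sim\texon\t{s}\t{e}\t.\t+\t.\t{attrs}")
        gtf_lines.append(
            f"{chrom}\tcircorf_sim\tCDS\t{cds_span[0]}\t{cds_span[1] - 3}\t.\t+\t0\t{attrs}"
        )
        if row is not None:
            truth_rows.append(row)
    emit_junk(100)

    # planted DE / m6A / peptide-db flags over circRNAs
    de_cycle = ["up", "down", "null"]
    for j, row in enumerate(truth_rows):
        row["de_status"] = (
            de_cycle[j % 3] if (config.de_effect > 0 and not row["rolling"]) else "null"
        )
        row["m6a_flag"] = j % 2 == 0
        row["pep_n_in_db"] = bool(row["n_ext"]) and j % 2 == 0
        row["pep_c_in_db"] = bool(row["c_ext"]) and j % 2 == 0

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)

    genome_fa = out_dir / "genome.fa"
    _write_fasta(genome_fa, [(chrom, "".join(chrom_parts))])
    annotation_gtf = out_dir / "annotation.gtf"
    annotation_gtf.write_text("\n".join(gtf_lines) + "\n")
    proteins_fa = out_dir / "cognate_proteins.fa"
    _write_fasta(proteins_fa, proteins)
    domains_tsv = out_dir / "domains.tsv"
    pd.DataFrame(
        domain_rows, columns=["protein_id", "domain_id", "start", "end"]
    ).to_csv(domains_tsv, sep="\t", index=False)
    truth_tsv = out_dir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return SyntheticReference(
        config=config, out_dir=out_dir, truth=truth, genome_fa=genome_fa,
        annotation_gtf=annotation_gtf, proteins_fa=proteins_fa,
        domains_tsv=domains_tsv, truth_tsv=truth_tsv,
    )


def make_expression(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> tuple[Path, Path, pd.DataFrame]:
    """Backsplice TSV with per-sample reads + sample sheet.

    Returns (backsplice_path, samples_path, latent log2 matrix).  Planted DE
    rows have group-mean log2 difference exactly ``de_effect`` before noise;
    library sizes vary across samples.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.n_samples < 4:
        raise ValueError("n_samples < 4: differential expression undefined")
    rng = np.random.default_rng(config.seed + 1)
    n_cancer = int(round(config.n_samples * config.frac_cancer))
    n_cancer = min(max(n_cancer, 2), config.n_samples - 2)
    samples = [f"C{i + 1:03d}" for i in range(n_cancer)] + [
        f"N{i + 1:03d}" for i in range(config.n_samples - n_cancer)
    ]
    groups = ["cancer"] * n_cancer + ["normal"] * (config.n_samples - n_cancer)
    lib_sizes = rng.integers(500_000, 2_000_000, size=config.n_samples)

    latent = np.zeros((len(truth), config.n_samples))
    for i, row in enumerate(truth.itertuples(index=False)):
        base = rng.uniform(3.0, 6.0)
        sign = {"up": 1.0, "down": -1.0, "null": 0.0}[row.de_status]
        mean_by_group = {
            "cancer": base + sign * config.de_effect / 2,
            "normal": base - sign * config.de_effect / 2,
        }
        for j, g in enumerate(groups):
            latent[i, j] = mean_by_group[g] + (
                rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
            )
    latent_df = pd.DataFrame(latent, index=truth["circ_id"], columns=samples)

    rows = []
    for i, row in enumerate(truth.itertuples(index=False)):
        for j, sample in enumerate(samples):
            count = int(round(2 ** latent[i, j] * lib_sizes[j] / 1e6))
            rows.append((row.chrom, row.start, row.end, max(count, 1), row.gene, sample))
    backsplice = out_dir / "backsplice.tsv"
    pd.DataFrame(
        rows, columns=["chr", "start", "end", "reads", "symbol", "sample"]
    ).to_csv(backsplice, sep="\t", index=False)
    sheet = out_dir / "samples.tsv"
    pd.DataFrame(
        {"sample": samples, "group": groups, "library_size": lib_sizes}
    ).to_csv(sheet, sep="\t", index=False)
    return backsplice, sheet, latent_df


def make_annotation_tracks(
    config: SyntheticConfig,
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """m6A peak BED (0-based half-open) + peptide FASTA database."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 2)
    bed_lines = []
    for row in truth.itertuples(index=False):
        if row.m6a_flag:
            s0 = row.start - 1  # 1-based inclusive -> 0-based half-open
            peak_start = s0 + 5
            peak_end = min(peak_start + 50, row.end)
            bed_lines.append(f"{row.chrom}\t{peak_start}\t{peak_end}\tm6A_{row.circ_id}")
    bed_path = out_dir / "m6a_peaks.bed"
    bed_path.write_text("\n".join(bed_lines) + ("\n" if bed_lines else ""))

    peptides: list[tuple[str, str]] = []
    for row in truth.itertuples(index=False):
        if row.pep_n_in_db and row.n_ext:
            peptides.append((f"pep_n_{row.circ_id}", row.n_ext))
        if row.pep_c_in_db and row.c_ext:
            peptides.append((f"pep_c_{row.circ_id}", row.c_ext))
    for i in range(10):  # decoys from an alphabet disjoint from extensions
        peptides.append(
            (f"decoy_{i + 1}", "".join(rng.choice(list(DECOY_AA), size=12)))
        )
    pep_path = out_dir / "peptides.fa"
    _write_fasta(pep_path, peptides)
    return bed_path, pep_path


def simulate(config: SyntheticConfig, out_dir: str | Path) -> SyntheticReference:
    """Generate the complete fixture set into *out_dir*."""
    ref = make_reference(config, out_dir)
    make_expression(config, ref.truth, out_dir)
    make_annotation_tracks(config, ref.truth, out_dir)
    return ref


def simulate_de_benchmark(
    n_planted: int,
    n_null: int,
    n_cancer: int,
    n_normal: int,
    de_effect: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Standalone count matrix for DE power/type-I studies.

    Returns (counts, groups, planted) where planted is a boolean Series over
    rows.  Planted rows alternate up/down so library totals stay balanced.
    """
    rng = np.random.default_rng(seed)
    n_rows = n_planted + n_null
    samples = [f"C{i + 1:03d}" for i in range(n_cancer)] + [
        f"N{i + 1:03d}" for i in range(n_normal)
    ]
    groups = pd.Series(
        ["cancer"] * n_cancer + ["normal"] * n_normal, index=samples, name="group"
    )
    lib = rng.integers(500_000, 2_000_000, size=len(samples))
    latent = rng.uniform(3.0, 6.0, size=n_rows)[:, None] + rng.normal(
        0.0, noise_sd, size=(n_rows, len(samples))
    )
    signs = np.zeros(n_rows)
    signs[:n_planted] = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    is_cancer = (groups == "cancer").to_numpy()
    latent += np.outer(signs, np.where(is_cancer, de_effect / 2, -de_effect / 2))
    counts = np.maximum(np.round(2**latent * lib / 1e6), 1).astype(int)
    index = [f"row{i + 1:05d}" for i in range(n_rows)]
    planted = pd.Series([i < n_planted for i in range(n_rows)], index=index)
    return pd.DataFrame(counts, index=index, columns=samples), groups, planted
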