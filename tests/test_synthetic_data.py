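from __future__ import annotations

import filecmp

import numpy as np
import pandas as pd
import pytest
from Bio import SeqIO
from Bio.Seq import Seq

from circorf import synthetic_data as sd
from circorf.circ_assembly import Annotation
from circorf.orf_caller import OrfParams, enumerate_circorfs


def small_config(**kw) -> sd.SyntheticConfig:
    defaults = dict(seed=3, n_genes=10, n_circ=10, n_samples=8, noise_sd=0.0)
    defaults.update(kw)
    return sd.SyntheticConfig(**defaults)


class TestConfigValidation:
    def test_frac_cancer_bounds(self):
        with pytest.raises(ValueError):
            small_config(frac_cancer=0.0)
        with pytest.raises(ValueError):
            small_config(frac_cancer=1.5)

    def test_negative_de_effect(self):
        with pytest.raises(ValueError):
            small_config(de_effect=-1.0)

    def test_unknown_class_label(self):
        with pytest.raises(ValueError, match="unknown planted class"):
            small_config(planted_classes=["bogus+C-term"], n_circ=1)

    def test_impossible_exon_lengths(self):
        with pytest.raises(ValueError, match="50-aa ORF"):
            small_config(exon_len=(20, 40))

    def test_too_few_circ_for_classes(self):
        with pytest.raises(ValueError, match="cannot realize"):
            small_config(n_circ=2)


class TestMakeReference:
    def test_every_planted_class_realized(self, tmp_path):
        ref = sd.make_reference(small_config(), tmp_path)
        assert set(ref.truth["scenario"]) == set(sd.DEFAULT_CLASSES)

    def test_determinism_byte_identical(self, tmp_path):
        cfg = small_config()
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.simulate(cfg, d1)
        sd.simulate(cfg, d2)
        for name in ["genome.fa", "annotation.gtf", "cognate_proteins.fa",
                     "domains.tsv", "truth.tsv", "backsplice.tsv",
                     "samples.tsv", "m6a_peaks.bed", "peptides.fa"]:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_circ_count_and_gene_conservation(self, tmp_path):
        ref = sd.make_reference(small_config(), tmp_path)
        bs, _, _ = sd.make_expression(ref.config, ref.truth, tmp_path)
        df = pd.read_csv(bs, sep="\t")
        circ_keys = df[["symbol", "chr", "start", "end"]].drop_duplicates()
        assert len(circ_keys) == ref.config.n_circ
        ann = Annotation(ref.annotation_gtf)
        assert set(circ_keys["symbol"]) <= set(ann.gene_ids)

    def test_cognates_translate_from_annotated_cds(self, tmp_path):
        ref = sd.make_reference(small_config(), tmp_path)
        proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(ref.proteins_fa), "fasta")}
        genome = {r.id: str(r.seq) for r in SeqIO.parse(str(ref.genome_fa), "fasta")}
        cds_by_gene: dict[str, list[tuple[int, int]]] = {}
        for line in open(ref.annotation_gtf):
            f = line.rstrip("\n").split("\t")
            if f[2] == "CDS":
                gene = f[8].split('"')[1]
                cds_by_gene.setdefault(gene, []).append((int(f[3]), int(f[4])))
        for gene, spans in cds_by_gene.items():
            seq = "".join(genome["chr1"][s - 1 : e] for s, e in sorted(spans))
            assert str(Seq(seq).translate()) == proteins[f"{gene}|p1"]

    def test_rolling_scenario_divisible_stop_free(self, tmp_path):
        ref = sd.make_reference(small_config(), tmp_path)
        row = ref.truth[ref.truth["rolling"]].iloc[0]
        genome = {r.id: str(r.seq) for r in SeqIO.parse(str(ref.genome_fa), "fasta")}
        ann = Annotation(ref.annotation_gtf)
        segs = []
        for tid in ann.transcripts_of(row["gene"]):
            for s, e in ann.exons_of(tid):
                cs, ce = max(s, row["start"]), min(e, row["end"])
                if cs <= ce:
                    segs.append(genome["chr1"][cs - 1 : ce])
        circle = "".join(segs)
        assert len(circle) % 3 == 0
        atg = circle.find("ATG")
        assert atg == (circle + circle).find("ATG")
        # scan all codons of the planted frame around the circle: no stop
        frame_seq = circle[atg:] + circle[:atg]
        codons = [frame_seq[i : i + 3] for i in range(0, len(frame_seq), 3)]
        assert all(c not in ("TAA", "TAG", "TGA") for c in codons)

    def test_canonical_met_cterm_crosses_junction(self, tmp_path):
        cfg = small_config(planted_classes=["canonicalMet+C-term"], n_circ=1, n_genes=1)
        ref = sd.make_reference(cfg, tmp_path)
        row = ref.truth.iloc[0]
        assert row["n_class"] == "canonicalMet" and row["c_class"] == "C-term"
        genome = {r.id: str(r.seq) for r in SeqIO.parse(str(ref.genome_fa), "fasta")}
        ann = Annotation(ref.annotation_gtf)
        segs = []
        for tid in ann.transcripts_of(row["gene"]):
            for s, e in ann.exons_of(tid):
                cs, ce = max(s, row["start"]), min(e, row["end"])
                if cs <= ce:
                    segs.append(genome["chr1"][cs - 1 : ce])
        circle = "".join(segs)
        orfs = enumerate_circorfs(circle, OrfParams(min_orf_aa=50))
        assert any(o.crosses_junction and o.protein == row["protein"] for o in orfs)


class TestMakeExpression:
    def test_refuses_tiny_cohort(self, tmp_path):
        cfg = small_config()
        ref = sd.make_reference(cfg, tmp_path)
        cfg2 = small_config(n_samples=3)
        with pytest.raises(ValueError, match="n_samples"):
            sd.make_expression(cfg2, ref.truth, tmp_path)

    def test_zero_effect_all_null(self, tmp_path):
        cfg = small_config(de_effect=0.0)
        ref = sd.make_reference(cfg, tmp_path)
        assert set(ref.truth["de_status"]) == {"null"}

    def test_noiseless_group_means_exact(self, tmp_path):
        cfg = small_config(de_effect=2.0, noise_sd=0.0)
        ref = sd.make_reference(cfg, tmp_path)
        _, sheet_path, latent = sd.make_expression(cfg, ref.truth, tmp_path)
        sheet = pd.read_csv(sheet_path, sep="\t")
        cancer = sheet[sheet["group"] == "cancer"]["sample"]
        normal = sheet[sheet["group"] == "normal"]["sample"]
        for _, row in ref.truth.iterrows():
            diff = (
                latent.loc[row["circ_id"], cancer].mean()
                - latent.loc[row["circ_id"], normal].mean()
            )
            expected = {"up": 2.0, "down": -2.0, "null": 0.0}[row["de_status"]]
            assert diff == pytest.approx(expected, abs=1e-9)

    def test_library_sizes_vary(self, tmp_path):
        cfg = small_config()
        ref = sd.make_reference(cfg, tmp_path)
        _, sheet_path, _ = sd.make_expression(cfg, ref.truth, tmp_path)
        sheet = pd.read_csv(sheet_path, sep="\t")
        assert sheet["library_size"].nunique() > 1

    def test_min_samples_expressed(self, tmp_path):
        cfg = small_config()
        ref = sd.make_reference(cfg, tmp_path)
        bs, _, _ = sd.make_expression(cfg, ref.truth, tmp_path)
        df = pd.read_csv(bs, sep="\t")
        per_circ = df[df["reads"] > 0].groupby(["symbol"])["sample"].nunique()
        assert (per_circ >= cfg.min_samples_expressed).all()


class TestAnnotationTracks:
    def test_empty_bed_when_no_flags(self, tmp_path):
        cfg = small_config()
        ref = sd.make_reference(cfg, tmp_path)
        truth = ref.truth.copy()
        truth["m6a_flag"] = False
        bed, _ = sd.make_annotation_tracks(cfg, truth, tmp_path / "t")
        assert bed.read_text() == ""

    def test_flagged_circ_has_internal_peak(self, tmp_path):
        cfg = small_config()
        ref = sd.make_reference(cfg, tmp_path)
        bed, _ = sd.make_annotation_tracks(cfg, ref.truth, tmp_path / "t")
        peaks = [line.split("\t") for line in bed.read_text().splitlines()]
        flagged = ref.truth[ref.truth["m6a_flag"]]
        for _, row in flagged.iterrows():
            inside = [
                p for p in peaks
                if p[0] == row["chrom"]
                and int(p[1]) >= row["start"] - 1
                and int(p[2]) <= row["end"]
            ]
            assert inside, row["circ_id"]

    def test_flagged_extension_in_peptide_db(self, tmp_path):
        cfg = small_config()
        ref = sd.make_reference(cfg, tmp_path)
        _, pep = sd.make_annotation_tracks(cfg, ref.truth, tmp_path / "t")
        db = [str(r.seq) for r in SeqIO.parse(str(pep), "fasta")]
        for _, row in ref.truth.iterrows():
            if row["pep_c_in_db"]:
                assert any(row["c_ext"] in p or p in row["c_ext"] for p in db)
            if row["pep_n_in_db"]:
                assert any(row["n_ext"] in p or p in row["n_ext"] for p in db)


def test_truth_roundtrip_preserves_null(tmp_path):
    cfg = small_config()
    ref = sd.make_reference(cfg, tmp_path)
    back = sd.read_truth_table(ref.truth_tsv)
    assert list(back["de_status"]) == list(ref.truth["de_status"])
    assert list(back["rolling"]) == list(ref.truth["rolling"])
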