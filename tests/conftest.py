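from __future__ import annotations

from pathlib import Path

import pytest

from circorf import pipeline_cli, synthetic_data


@pytest.fixture(scope="session")
def noiseless_config() -> synthetic_data.SyntheticConfig:
    return synthetic_data.SyntheticConfig(
        seed=7, n_genes=10, n_circ=10, n_samples=12, noise_sd=0.0, de_effect=2.0
    )


@pytest.fixture(scope="session")
def noiseless_sim(tmp_path_factory, noiseless_config):
    out = tmp_path_factory.mktemp("sim_noiseless")
    ref = synthetic_data.simulate(noiseless_config, out)
    return ref


@pytest.fixture(scope="session")
def pipeline_output(noiseless_sim):
    d = noiseless_sim.out_dir
    conf = pipeline_cli.PipelineConfig(
        genome_fa=str(d / "genome.fa"),
        annotation_gtf=str(d / "annotation.gtf"),
        backsplice_tsv=str(d / "backsplice.tsv"),
        proteins_fa=str(d / "cognate_proteins.fa"),
        domains_tsv=str(d / "domains.tsv"),
        samples_tsv=str(d / "samples.tsv"),
        m6a_bed=str(d / "m6a_peaks.bed"),
        peptides_fa=str(d / "peptides.fa"),
        out_dir=str(d / "out"),
        min_samples=4,
        apply_sample_filter=False,
    )
    summary = pipeline_cli.run(conf)
    return conf, summary


def write_toy_reference(tmp_path: Path, strand: str = "+") -> tuple[Path, Path, str]:
    """Tiny single-gene genome/GTF pair with known exon coordinates.

    Gene GENE1 on chr1 with exons [100,199], [300,399], [500,599]
    (1-based inclusive).  Returns (genome_fa, gtf, chrom_seq).
    """
    import numpy as np

    rng = np.random.default_rng(123)
    chrom_seq = "".join(rng.choice(list("ACGT"), size=700))
    genome_fa = tmp_path / "genome.fa"
    genome_fa.write_text(">chr1\n" + chrom_seq + "\n")
    attrs = 'gene_id "GENE1"; transcript_id "GENE1.t1";'
    lines = [
        f'chr1\ttest\tgene\t100\t599\t.\t{strand}\t.\tgene_id "GENE1";',
        f"chr1\ttest\ttranscript\t100\t599\t.\t{strand}\t.\t{attrs}",
        f"chr1\ttest\texon\t100\t199\t.\t{strand}\t.\t{attrs}",
        f"chr1\ttest\texon\t300\t399\t.\t{strand}\t.\t{attrs}",
        f"chr1\ttest\texon\t500\t599\t.\t{strand}\t.\t{attrs}",
    ]
    gtf = tmp_path / "annotation.gtf"
    gtf.write_text("\n".join(lines) + "\n")
    return genome_fa, gtf, chrom_seq
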