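import pytest

from circlandscape import SimulationConfig, build_dataset, simulate_landscape


@pytest.fixture(scope="session")
def small_sim():
    """A small but structurally complete simulated panel (60 cell lines)."""
    return simulate_landscape(SimulationConfig(seed=42, n_genes=60))


@pytest.fixture(scope="session")
def small_dataset(small_sim):
    return build_dataset(
        small_sim.junctions_by_sample, small_sim.meta, small_sim.linear_fpkm
    )


@pytest.fixture()
def toy_gtf(tmp_path):
    """Two genes: gA (+, transcripts of 2 and 3 exons), gB (-, 2 exons)."""
    lines = []

    def exon(chrom, start1, end1, strand, gene, tx):
        lines.append(
            f"{chrom}\tsrc\texon\t{start1}\t{end1}\t.\t{strand}\t.\t"
            f'gene_id "{gene}"; transcript_id "{tx}";'
        )

    # gA.t1: 2 exons; gA.t2: 3 exons (canonical)
    exon("chr1", 101, 200, "+", "gA", "gA.t1")
    exon("chr1", 301, 400, "+", "gA", "gA.t1")
    exon("chr1", 101, 200, "+", "gA", "gA.t2")
    exon("chr1", 301, 400, "+", "gA", "gA.t2")
    exon("chr1", 501, 600, "+", "gA", "gA.t2")
    # gB on the minus strand: exon 1 is genomically last
    exon("chr2", 1001, 1100, "-", "gB", "gB.t1")
    exon("chr2", 1301, 1400, "-", "gB", "gB.t1")
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
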