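"""Shared fixtures: tiny hand-built genome bundles and the synthetic smoke dataset."""

from __future__ import annotations

import pytest

from sorfpipe import consensus_screen, genome_io, synthetic


def make_record(aa_seq: str, rid_tag: str, species: str = "spX",
                nt_seq: str = "", source: str = consensus_screen.SOURCE_AB_INITIO,
                start: int = 0) -> consensus_screen.SorfRecord:
    """A minimal SorfRecord for clustering/homology tests."""
    return consensus_screen.SorfRecord(
        species_id=species, seq_id=rid_tag, region_label="intergenic",
        strand="+", frame=0, start=start, end=start + 3 * (len(aa_seq) + 1),
        nt_seq=nt_seq, aa_seq=aa_seq, source=source)


@pytest.fixture
def records_factory():
    return make_record


@pytest.fixture
def tiny_bundle() -> genome_io.GenomeBundle:
    """100-bp sequence with one 2-exon gene at [10,90), exons [10,30)+[60,90)."""
    seq = ("ACGT" * 25)
    features = [
        genome_io.Feature("s1", 10, 90, "+", "gene", "g1"),
        genome_io.Feature("s1", 10, 90, "+", "mRNA", "m1", parent_id="g1"),
        genome_io.Feature("s1", 10, 30, "+", "exon", "e1", parent_id="m1"),
        genome_io.Feature("s1", 60, 90, "+", "exon", "e2", parent_id="m1"),
    ]
    return genome_io.GenomeBundle("spA", {"s1": seq}, features)


@pytest.fixture(scope="session")
def smoke_data(tmp_path_factory):
    """Smoke dataset (3 species, 200 kb, 10 planted families) written to disk."""
    outdir = tmp_path_factory.mktemp("smoke") / "data"
    spec = synthetic.PlantSpec(seed=1)
    bundles, truth = synthetic.generate(spec)
    synthetic.write_dataset(bundles, truth, outdir)
    return {"dir": outdir, "bundles": bundles, "truth": truth, "spec": spec}
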