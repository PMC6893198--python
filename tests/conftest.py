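import numpy as np
import pysam
import pytest

from hafkit.founders import SNPTable, impute
from hafkit.simulate import PanelSpec, generate_panel


def make_table(genotypes, positions=None, chrom="chr", ref="A", alt="T"):
    """Toy SNPTable from a founders x sites genotype array (0/1/-1)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_f, n_s = g.shape
    if positions is None:
        positions = np.arange(1, n_s + 1) * 100
    return SNPTable(
        chrom, np.asarray(positions),
        np.full(n_s, ref), np.full(n_s, alt), g,
        [f"f{i}" for i in range(n_f)],
    )


def write_sam(path, reads, L=100_000, chrom="chr"):
    """Write a toy SAM. Each read: dict with qname, pos (0-based), seq,
    qual (int or list), optional cigar, flag, mpos, tlen."""
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": int(L)}]})
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r["qname"]
            a.reference_id = 0
            a.reference_start = r["pos"]
            a.query_sequence = r["seq"]
            q = r.get("qual", 30)
            a.query_qualities = [q] * len(r["seq"]) if isinstance(q, int) else q
            a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
            a.mapping_quality = 60
            a.flag = r.get("flag", 0)
            if "mpos" in r:
                a.next_reference_id = 0
                a.next_reference_start = r["mpos"]
                a.template_length = r.get("tlen", 0)
            out.write(a)
    return path


@pytest.fixture(scope="session")
def small_panel():
    """20 founders on 300 kb at default SNP density, no missing calls."""
    spec = PanelSpec(n_founders=20, L=300_000, seed=11)
    table, ref_codes = generate_panel(spec)
    return spec, table, ref_codes


@pytest.fixture(scope="session")
def small_imputed(small_panel):
    _, table, _ = small_panel
    return impute(table, "major_allele")
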