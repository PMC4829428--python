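import numpy as np
import pytest

import mztseq as m


def bh_stepup_reference(pvals):
    """Independent Benjamini-Hochberg step-up oracle: sort ascending,
    adj_(i) = min_{j>=i} p_(j) * m / j, capped at 1, back in input order."""
    p = np.asarray(pvals, dtype=float)
    mtot = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(mtot)
    running = 1.0
    for rank in range(mtot, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * mtot / rank)
        adj_sorted[rank - 1] = running
    adj = np.empty(mtot)
    adj[order] = adj_sorted
    return adj


@pytest.fixture(scope="session")
def mzt_scenario():
    """Default synthetic MZT scenario: truth table and simulated counts."""
    truth = m.make_truth(seed=0)
    design = m.SimDesign(seed=0)
    matrix = m.simulate_count_matrix(truth, design)
    return truth, design, matrix


@pytest.fixture(scope="session")
def mzt_de(mzt_scenario):
    """Wild-type 2C vs oocyte differential expression on the default scenario."""
    _, _, matrix = mzt_scenario
    records = m.run_differential_expression(matrix, m.OOCYTE, m.WT2C, m.DEConfig(seed=0))
    return records


@pytest.fixture()
def gtf_file(tmp_path):
    def write(lines):
        p = tmp_path / "anno.gtf"
        p.write_text("\n".join(lines) + "\n")
        return p

    return write


def gtf_exon(chrom, start, end, strand, gene, tx, ftype="exon"):
    return (
        f"{chrom}\tsrc\t{ftype}\t{start}\t{end}\t.\t{strand}\t.\t"
        f'gene_id "{gene}"; transcript_id "{tx}";'
    )
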