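import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from refstab import CtTable, SampleAnnotation

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_ct(genes, ct, samples=None, **kwargs):
    """Build a CtTable from a gene list and a row-per-gene matrix."""
    ct = np.asarray(ct, dtype=float)
    if samples is None:
        samples = [SampleAnnotation(f"s{j + 1}") for j in range(ct.shape[1])]
    return CtTable(genes=list(genes), samples=samples, ct=ct, **kwargs)


@pytest.fixture
def three_gene_table():
    """Two proportional genes (constant 1-cycle offset) plus one constant gene.

    On the 2^-dCt scale, rows A and B are proportional (pairwise V = 0) and
    row C is constant while A/B vary: V(A,C) = V(B,C) = sd of {0,1,2,3} in
    log2 units = sqrt(5/3).
    """
    return make_ct(
        ["A", "B", "C"],
        [[18.0, 19.0, 20.0, 21.0],
         [19.0, 20.0, 21.0, 22.0],
         [20.0, 20.0, 20.0, 20.0]],
    )


@pytest.fixture
def time_course_table():
    """12-sample time course (4 time points x 3 bio replicates), constant genes."""
    samples = [
        SampleAnnotation(f"t{t:g}_b{b}", subset="treat", time_point=float(t), bio_replicate=b)
        for t in (0, 1, 6, 24)
        for b in (1, 2, 3)
    ]
    ct = np.tile([[20.0], [22.0], [18.0]], (1, 12))
    return make_ct(["TGT", "R1", "R2"], ct, samples=samples)
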