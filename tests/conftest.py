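import numpy as np
import pytest

from metabomr import HarmonizedPanel, SummaryRecord


def make_panel(gamma, big_gamma, se_y, se_x=None, ids=None) -> HarmonizedPanel:
    gamma = np.asarray(gamma, dtype=float)
    big_gamma = np.asarray(big_gamma, dtype=float)
    se_y = np.broadcast_to(np.asarray(se_y, dtype=float), gamma.shape).copy()
    se_x = (np.full_like(gamma, 1e-3) if se_x is None
            else np.broadcast_to(np.asarray(se_x, dtype=float), gamma.shape).copy())
    ids = ids or tuple(f"rs{i + 1}" for i in range(len(gamma)))
    return HarmonizedPanel(
        snp_ids=tuple(ids), gamma=gamma, se_x=se_x,
        big_gamma=big_gamma, se_y=se_y,
        flipped=np.zeros(len(gamma), dtype=bool),
    )


@pytest.fixture
def worked_panel() -> HarmonizedPanel:
    """Three-instrument panel whose IVW numbers are known in closed form."""
    return make_panel([0.1, 0.2, 0.4], [0.06, 0.10, 0.18], 0.01)


@pytest.fixture
def homogeneous_panel() -> HarmonizedPanel:
    """All Wald ratios equal 0.5 exactly, so Q = 0."""
    return make_panel([0.1, 0.2, 0.4], [0.05, 0.10, 0.20], 0.01)


def make_record(snp_id="rs1", chrom="1", pos=100, ea="A", oa="G", eaf=0.3,
                beta=0.1, se=0.02, pval=1e-6, info=1.0, n=None) -> SummaryRecord:
    return SummaryRecord(snp_id=snp_id, chrom=chrom, pos=pos,
                         effect_allele=ea, other_allele=oa, eaf=eaf,
                         beta=beta, se=se, pval=pval, info=info, n=n)
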