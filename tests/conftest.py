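import numpy as np
import pytest

from admixmeth.containers import AncestryPanel, MethCountMatrix


def make_counts(meth, total, chrom="chr1", start_pos=100, individuals=None):
    """Small MethCountMatrix from explicit arrays (sites x individuals)."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    ns, ni = meth.shape
    return MethCountMatrix(
        chrom=np.full(ns, chrom),
        pos=np.arange(start_pos, start_pos + ns * 10, 10),
        individuals=individuals or [f"i{k}" for k in range(ni)],
        meth=meth,
        total=total,
    )


def make_panel(dosage, chrom="chr1", start_pos=100, individuals=None,
               global_ancestry=None):
    """AncestryPanel from an explicit (individuals x loci) dosage array.

    Pass ``global_ancestry`` explicitly when testing few loci, otherwise
    the derived genome-wide mean is collinear with the local dosage.
    """
    dosage = np.atleast_2d(np.asarray(dosage))
    ni, nl = dosage.shape
    return AncestryPanel(
        chrom=np.full(nl, chrom),
        pos=np.arange(start_pos, start_pos + nl * 10, 10),
        individuals=individuals or [f"i{k}" for k in range(ni)],
        dosage=dosage,
        global_ancestry=global_ancestry,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
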