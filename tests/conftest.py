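import numpy as np
import pytest

from axistrace import GenomicBins, TraceDataset, center_traces
from axistrace.synthetic import SimulationSpec, simulate_planted


@pytest.fixture
def bins25() -> GenomicBins:
    """60 consecutive 25-Kb bins."""
    return GenomicBins(chrom="chr1", starts=np.arange(60, dtype=np.int64) * 25_000, resolution=25_000)


@pytest.fixture
def toy_fofct(tmp_path):
    """A 6-row FOF-CT core file: 2 traces x 3 bins, all spots present."""
    path = tmp_path / "toy.fofct.csv"
    path.write_text(
        "##FOF-CT_version=v0.1\n"
        "##XYZ_unit=nm\n"
        "##columns=(Trace_ID,X,Y,Z,Chrom,Chrom_Start,Chrom_End)\n"
        "T1,0.0,10.0,20.0,chr1,0,25000\n"
        "T1,100.0,110.0,120.0,chr1,25000,50000\n"
        "T1,200.0,210.0,220.0,chr1,50000,75000\n"
        "T2,5.0,15.0,25.0,chr1,0,25000\n"
        "T2,105.0,115.0,125.0,chr1,25000,50000\n"
        "T2,205.0,215.0,225.0,chr1,50000,75000\n"
    )
    return path


@pytest.fixture
def small_centered_dataset() -> TraceDataset:
    """A small structureless Gaussian dataset, centered, with missing spots."""
    ds, _ = simulate_planted(SimulationSpec(n=50, p=20, scale=1e-6, missing_rate=0.1, seed=11))
    return center_traces(ds)


def make_dataset(coords, resolution=25_000, chrom="chr1", centered=False) -> TraceDataset:
    """TraceDataset from a raw (n, p, 3) array with consecutive bins."""
    coords = np.asarray(coords, dtype=float)
    n, p, _ = coords.shape
    bins = GenomicBins(chrom=chrom, starts=np.arange(p, dtype=np.int64) * resolution, resolution=resolution)
    return TraceDataset(
        coords=coords,
        trace_ids=np.array([f"T{i}" for i in range(n)]),
        bins=bins,
        centered=centered,
    )
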