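import numpy as np
import pandas as pd
import pytest

from subtelocnv.regions import GenomicInterval, ProbeManifest, RegionSet, builtin_regions


@pytest.fixture(scope="session")
def target_regions() -> RegionSet:
    return builtin_regions()


@pytest.fixture()
def toy_manifest() -> ProbeManifest:
    """Ten evenly spaced probes on one chromosome for hand-checked calls."""
    starts = 1000 + 100 * np.arange(10)
    df = pd.DataFrame(
        {
            "chrom": "chr1",
            "start": starts,
            "end": starts + 59,
            "probe_id": [f"p{i}" for i in range(10)],
            "gc_fraction": 0.5,
        }
    )
    return ProbeManifest(df, platform="tiling")


@pytest.fixture()
def toy_regions() -> RegionSet:
    """One small region covering probes p2..p7 of the toy manifest."""
    return RegionSet({"toy": GenomicInterval("chr1", 1200, 1759)})


def manifest_of_length(n: int, chrom: str = "chr1") -> ProbeManifest:
    starts = 100 + 10 * np.arange(n)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + 9,
            "probe_id": [f"m{i}" for i in range(n)],
            "gc_fraction": 0.5,
        }
    )
    return ProbeManifest(df, platform="tiling")
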