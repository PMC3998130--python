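import numpy as np
import pytest

from kdepeaks import BinGeometry, ChromSizes


@pytest.fixture
def geometry():
    return BinGeometry(central_size=300, background_size=3000)


@pytest.fixture
def small_sizes():
    return ChromSizes({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def bed_file(tmp_path):
    """Write BED lines to a temp file and return its path."""

    def _write(lines, name="reads.bed"):
        path = tmp_path / name
        path.write_text("".join(line + "\n" for line in lines))
        return path

    return _write


def brute_force_count(positions, start, end):
    """Linear-scan oracle for read-start counting in [start, end)."""
    return sum(1 for p in positions if start <= p < end)


def brute_force_corrected(positions, center, geometry):
    """Oracle corrected density at one centre via linear scans."""
    c_lo = center - geometry.central_size // 2
    b_lo = center - geometry.background_size // 2
    cc = brute_force_count(positions, c_lo, c_lo + geometry.central_size)
    bc = brute_force_count(positions, b_lo, b_lo + geometry.background_size)
    return cc - bc * (geometry.central_size / geometry.background_size)
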