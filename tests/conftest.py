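"""Shared fixtures: deterministic synthetic BAMs at several scales.

All fixtures are generated in-process by the package's simulator; nothing is
downloaded or stored in the repository.
"""

from __future__ import annotations

import pytest

from scatterbam.index import write_bai
from scatterbam.reader import BamFile
from scatterbam.simulate import SimConfig, simulate

SMALL_SITES = tuple(
    ("chr1", 10001 + i * 900, "ACGT"[i % 4], "ACGT"[(i + 1) % 4], (0.0, 0.25, 0.5, 1.0)[i % 4])
    for i in range(40)
)


@pytest.fixture(scope="session")
def small_sites():
    return SMALL_SITES


@pytest.fixture(scope="session")
def big_sites():
    return BIG_SITES


@pytest.fixture(scope="session")
def small_sim():
    """~2k records on 3 references with 40 variant sites."""
    cfg = SimConfig(seed=7, n_read_pairs=1000, variant_sites=SMALL_SITES)
    return simulate(cfg)


@pytest.fixture(scope="session")
def small_bam_path(small_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("small")
    p = d / "small.bam"
    p.write_bytes(small_sim.bam)
    write_bai(small_sim.bai, str(p) + ".bai")
    (d / "sites.vcf").write_text(small_sim.vcf)
    return p


@pytest.fixture(scope="session")
def small_bamfile(small_bam_path):
    return BamFile(str(small_bam_path))


BIG_SITES = tuple(
    ("chr1", 10000 + i * 5000, "ACGT"[i % 4], "ACGT"[(i + 2) % 4], (0.0, 0.25, 0.5, 1.0)[i % 4])
    for i in range(110)
)


@pytest.fixture(scope="session")
def big_sim():
    """≥ 50k records across 3 references; ~110 variant sites."""
    cfg = SimConfig(
        seed=11,
        n_read_pairs=25000,
        references=(("chr1", 600000), ("chr2", 400000), ("chr3", 200000)),
        variant_sites=BIG_SITES,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def big_bam_path(big_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("big")
    p = d / "big.bam"
    p.write_bytes(big_sim.bam)
    write_bai(big_sim.bai, str(p) + ".bai")
    (d / "sites.vcf").write_text(big_sim.vcf)
    return p


@pytest.fixture(scope="session")
def big_bamfile(big_bam_path):
    return BamFile(str(big_bam_path))


@pytest.fixture(scope="session")
def unsorted_sim():
    """Generation-order (unsorted) fixture with no index, for scanner paths."""
    cfg = SimConfig(seed=19, n_read_pairs=800, coordinate_sort=False)
    return simulate(cfg)


@pytest.fixture(scope="session")
def deep_sim():
    """High depth (~550x) on a tiny reference: VAF recovery conditions."""
    cfg = SimConfig(
        seed=23,
        references=(("chr1", 8000),),
        n_read_pairs=22000,
        fragment_mean=250.0,
        fragment_sd=30.0,
        variant_sites=(
            ("chr1", 2001, "A", "C", 0.0),
            ("chr1", 3501, "G", "T", 0.25),
            ("chr1", 5001, "C", "A", 0.5),
            ("chr1", 6501, "T", "G", 1.0),
        ),
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def deep_bam_path(deep_sim, tmp_path_factory):
    d = tmp_path_factory.mktemp("deep")
    p = d / "deep.bam"
    p.write_bytes(deep_sim.bam)
    write_bai(deep_sim.bai, str(p) + ".bai")
    (d / "sites.vcf").write_text(deep_sim.vcf)
    return p
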