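import numpy as np
import pytest

from sdrkit.synthetic_data import ScenarioConfig, simulate_scenario
from sdrkit.tree_share import run_treeshare
from sdrkit.variant_io import SampleSheet

# Shared scenario-simulation settings sized so each history yields well over
# 2000 topologically informative sites (enough for tight binomial checks)
# while keeping a single simulation under ~10 s.
RECOVERY_KW = dict(
    chrom_length=3_000_000,
    sdr_start=100_000,
    sdr_end=2_900_000,
    snp_density=0.02,
    autosomes={"chr1": 200_000},
)


def treeshare_on_sex_chrom(sim, **kwargs):
    gt = sim.genotype_table
    mask = (gt.sites["chrom"] == sim.config.sex_chrom).to_numpy()
    return run_treeshare(gt.subset_sites(mask), sim.sample_sheet, **kwargs)


@pytest.fixture(scope="session")
def homologous_sim():
    return simulate_scenario(ScenarioConfig("homologous", seed=101, **RECOVERY_KW))


@pytest.fixture(scope="session")
def independent_sim():
    return simulate_scenario(ScenarioConfig("independent", seed=102, **RECOVERY_KW))


@pytest.fixture(scope="session")
def turnover_sim():
    return simulate_scenario(ScenarioConfig("turnover_wingei", seed=103, **RECOVERY_KW))


@pytest.fixture(scope="session")
def deletion_sim():
    # Same seed and geometry as homologous_sim; only the Yp deletion differs.
    return simulate_scenario(ScenarioConfig("homologous", seed=101, d_p=0.9, **RECOVERY_KW))


@pytest.fixture(scope="session")
def alpha_sims():
    """Independent-history simulations with homoplasy on, α = 1 vs α = 3."""
    out = {}
    for alpha in (1.0, 3.0):
        cfg = ScenarioConfig(
            "independent",
            seed=104,
            alpha=alpha,
            homoplasy=True,
            mu=0.15,
            autosomes={"chr1": 200_000},
        )
        out[alpha] = treeshare_on_sex_chrom(simulate_scenario(cfg))
    return out


@pytest.fixture(scope="session")
def autosome_sim():
    return simulate_scenario(
        ScenarioConfig(
            "autosome",
            seed=105,
            autosomes={"chr1": 2_000_000, "chr2": 2_000_000},
        )
    )


@pytest.fixture(scope="session")
def depth_deletion_sim():
    """Fully deleted Yp SDR at λ=30: the degeneration depth signal."""
    return simulate_scenario(
        ScenarioConfig(
            "homologous",
            seed=106,
            d_p=1.0,
            snp_density=0.001,
            autosomes={"chr1": 1_000_000},
        )
    )


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tm1\tm2\tf1\tf2
chr1\t100\t.\tA\tT\t60\t.\t.\tGT:DP\t0/1:30\t0/0:30\t0/0:30\t0/1:30
chr1\t200\t.\tC\tG\t19.5\t.\t.\tGT:DP\t0/1:30\t0/1:30\t0/0:30\t0/0:30
chr1\t300\t.\tA\tAT\t60\t.\t.\tGT:DP\t0/1:30\t0/0:30\t0/0:30\t0/1:30
chr1\t400\t.\tCT\tC\t60\t.\t.\tGT:DP\t0/1:30\t0/1:30\t0/0:30\t0/0:30
chr1\t500\t.\tA\tT,G\t60\t.\t.\tGT:DP\t0/1:30\t1/1:30\t0/0:30\t0/1:30
chr1\t600\t.\tG\tA\t60\t.\t.\tGT:DP\t0/1:30\t0/0:30\t0/0:30\t0/0:30
chr1\t700\t.\tT\tC\t60\t.\t.\tGT:DP\t1/0:30\t0/1:30\t0/0:30\t0/0:30
chr1\t800\t.\tA\tG\t60\t.\t.\tGT:DP\t1/1:30\t0/0:30\t0/0:30\t1/1:30
chr1\t900\t.\tC\tT\t60\t.\t.\tGT:DP\t0/1:30\t0/1:30\t0/1:30\t0/1:30
chr1\t1000\t.\tG\tC\t60\t.\t.\tGT:DP\t./.:0\t0/1:30\t0/1:30\t0/0:30
"""


@pytest.fixture()
def toy_vcf(tmp_path):
    path = tmp_path / "toy.vcf"
    path.write_text(TOY_VCF)
    return path


@pytest.fixture()
def toy_sheet():
    return SampleSheet.from_records(
        [("m1", "other", "M"), ("m2", "other", "M"), ("f1", "other", "F"), ("f2", "other", "F")]
    )
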