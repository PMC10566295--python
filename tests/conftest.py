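import numpy as np
import pandas as pd
import pytest

from husk_gs import (
    GenotypeMatrix,
    SimulationConfig,
    simulate_structured_genotypes,
    simulate_trait,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        subgroup_sizes={"NSS": 60, "SS": 30, "TST": 80, "MIXED": 40},
        n_markers=400, seed=17)


@pytest.fixture(scope="session")
def small_panel(small_cfg):
    """A modest structured panel shared across tests (read-only)."""
    g, panel, truth = simulate_structured_genotypes(small_cfg)
    return g, panel, truth


@pytest.fixture(scope="session")
def small_trait(small_cfg, small_panel):
    g, panel, truth0 = small_panel
    pheno, truth = simulate_trait(g, panel, small_cfg, "polygenic", truth0)
    return pheno, truth


@pytest.fixture
def toy_matrix():
    """Hand-set 4-line x 3-marker matrix with one missing call."""
    return GenotypeMatrix(
        line_ids=["A", "B", "C", "D"],
        marker_ids=["m1", "m2", "m3"],
        dosages=np.array([[0, 2, 1],
                          [1, 0, 1],
                          [2, np.nan, 0],
                          [0, 2, 2]], dtype=float),
        chrom=["1", "1", "2"],
        pos=[100, 200, 50],
        ref=["A", "G", "C"],
        alt=["T", "C", "G"],
    )


@pytest.fixture
def vcf_file(tmp_path):
    """3-line, 3-record VCF: one missing call, one triallelic record."""
    text = "\n".join([
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL1\tL2\tL3",
        "1\t100\ts1\tA\tT\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
        "1\t200\ts2\tG\tC\t.\t.\t.\tGT\t./.\t0/0\t1/1",
        "1\t300\ts3\tA\tT,G\t.\t.\t.\tGT\t0/0\t0/1\t1/1",
    ]) + "\n"
    p = tmp_path / "toy.vcf"
    p.write_text(text)
    return p


@pytest.fixture
def balanced_pheno():
    """Balanced 3 env x 2 rep records for 30 lines with known effects."""
    rng = np.random.default_rng(12)
    lines = [f"L{i}" for i in range(30)]
    f = rng.normal(0, 1, 30)
    rows = []
    for e in range(3):
        for r in range(2):
            eps = rng.normal(0, 1, 30)
            rows.append(pd.DataFrame({
                "line_id": lines, "environment": f"E{e}", "replicate": f"R{r}",
                "value": 10 + 0.5 * e + f + eps}))
    return pd.concat(rows, ignore_index=True), pd.Series(f, index=lines)
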