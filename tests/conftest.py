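import numpy as np
import pytest

from mrbma import StandardizedData, SummaryData


def random_standardized(n, d, seed, signal_idx=(), theta=0.4, noise_sd=1.0):
    """Random association data with an optional planted causal signal."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, d))
    y = rng.normal(0.0, noise_sd, size=n)
    for j in signal_idx:
        y = y + theta * X[:, j]
    return StandardizedData(
        variant_ids=[f"rs{i}" for i in range(n)],
        rf_names=[f"rf{j}" for j in range(d)],
        beta_x=X,
        beta_y=y,
    )


@pytest.fixture
def small_data():
    """n=40, d=4 with factors 0 and 2 causal — strong, easily detected signal."""
    return random_standardized(40, 4, seed=7, signal_idx=(0, 2), theta=1.0,
                               noise_sd=0.5)


@pytest.fixture
def null_data():
    """n=60, d=5, outcome independent of every risk factor."""
    return random_standardized(60, 5, seed=11)


@pytest.fixture
def raw_summary():
    rng = np.random.default_rng(3)
    n, d = 30, 3
    se_y = rng.uniform(0.05, 0.3, size=n)
    return SummaryData(
        variant_ids=[f"rs{i}" for i in range(n)],
        rf_names=["ldl", "hdl", "tg"],
        beta_x_raw=rng.standard_normal((n, d)) * 0.1,
        beta_y_raw=rng.standard_normal(n) * 0.1,
        se_y_raw=se_y,
    )


@pytest.fixture
def summary_files(tmp_path):
    """Paired exposure/outcome TSVs sharing 4 of 5 variants, one allele flip."""
    fx = tmp_path / "exposure.tsv"
    fy = tmp_path / "outcome.tsv"
    fx.write_text(
        "rsid\tea\toa\tbeta_ldl\tbeta_hdl\tse_ldl\tse_hdl\n"
        "rs1\tA\tG\t0.10\t0.05\t0.01\t0.01\n"
        "rs2\tC\tT\t0.20\t-0.04\t0.02\t0.01\n"
        "rs3\tG\tA\t-0.15\t0.02\t0.01\t0.02\n"
        "rs4\tT\tC\t0.08\t0.01\t0.01\t0.01\n"
        "rs5\tA\tC\t0.12\t0.03\t0.02\t0.01\n"
    )
    fy.write_text(
        "rsid\tea\toa\tbeta_out\tse_out\n"
        "rs1\tA\tG\t0.30\t0.10\n"
        "rs2\tT\tC\t0.25\t0.08\n"  # flipped alleles: beta negated on load
        "rs3\tG\tA\t-0.10\t0.05\n"
        "rs4\tT\tC\t0.05\t0.04\n"
        "rs6\tA\tC\t0.02\t0.03\n"  # absent from exposure file
    )
    return str(fx), str(fy)
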