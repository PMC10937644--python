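import numpy as np
import pandas as pd
import pytest

from netmr import DagConfig, LdMatrix, ld_matrix, simulate_sumstats


def make_sumstats(rows):
    """Build a canonical sumstats DataFrame from (variant_id, chr, pos, ea,
    oa, eaf, beta, se, pval, n) tuples."""
    cols = ["variant_id", "chr", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval", "n"]
    df = pd.DataFrame(rows, columns=cols)
    df["chr"] = df["chr"].astype(str)
    return df


def identity_ld(table: pd.DataFrame) -> LdMatrix:
    """LD matrix with all off-diagonal r = 0 for the variants of a table."""
    ids = table["variant_id"].tolist()
    pos = table.set_index("variant_id")[["chr", "pos"]].copy()
    pos["chr"] = pos["chr"].astype(str)
    return LdMatrix(variant_ids=ids, r=np.eye(len(ids)), positions=pos)


def block_ld(table: pd.DataFrame, rho: float, block_size: int) -> LdMatrix:
    """Block-constant LD over consecutive variants of a table."""
    ids = table["variant_id"].tolist()
    m = len(ids)
    block = np.arange(m) // block_size
    r = np.where(block[:, None] == block[None, :], rho, 0.0)
    np.fill_diagonal(r, 1.0)
    pos = table.set_index("variant_id")[["chr", "pos"]].copy()
    pos["chr"] = pos["chr"].astype(str)
    return LdMatrix(variant_ids=ids, r=r, positions=pos)


def small_dag(seed: int, **overrides) -> DagConfig:
    """One-mediator, one-outcome DAG at the headline mediation scale:
    a = -0.22, b = log(31.4), direct chosen for proportion mediated 0.80."""
    ab = -0.22 * np.log(31.4)
    kwargs = dict(
        n_snps_per_trait=100,
        theta_exp_to_med=np.array([-0.22]),
        theta_med_to_outcome=np.array([[np.log(31.4)]]),
        theta_direct=np.array([ab * 0.25]),
        prevalence=np.array([0.007]),
        n_individuals=50_000,
        seed=seed,
    )
    kwargs.update(overrides)
    return DagConfig(**kwargs)


def own_snp_harmonized(tables, cfg: DagConfig, outcome: str):
    """HarmonizedSet of the exposure's own SNPs against one other trait,
    bypassing selection (for estimator calibration tests)."""
    from netmr import HarmonizedSet

    exp = tables["education"]
    own = exp[exp["variant_id"].str.startswith("rs1_")]
    out = tables[outcome].set_index("variant_id").loc[own["variant_id"]]
    return HarmonizedSet(
        variant_ids=own["variant_id"].tolist(),
        beta_exposures=own["beta"].to_numpy(),
        se_exposures=own["se"].to_numpy(),
        beta_outcome=out["beta"].to_numpy(),
        se_outcome=out["se"].to_numpy(),
        exposure_names=["education"],
    )


@pytest.fixture(scope="session")
def default_tables():
    """Direct-mode sumstats for the full default DAG, shared across tests."""
    cfg = DagConfig(seed=2)
    return simulate_sumstats(cfg), ld_matrix(cfg), cfg


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full default pipeline run, shared by shape/report tests."""
    from netmr import PipelineConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("demo_run")
    cfg = PipelineConfig(seed=7)
    manifest = run_pipeline(cfg, outdir=outdir)
    return outdir, manifest
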