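import numpy as np
import pandas as pd
import pytest

from deaseq import chemistry, synthio


@pytest.fixture(scope="session")
def small_sim():
    """A small but fully featured synthetic study: 300 kb genome, 40 genes,
    dense enough 5gmC (300 ppm) that site-level analyses have material."""
    cfg = synthio.SimConfig(
        genome_length=300_000,
        n_chromosomes=2,
        n_genes=40,
        gmc_ppm=300.0,
    )
    genome, genes, intervals = synthio.simulate_reference(cfg, seed=11)
    truth = synthio.plant_modifications(genome, genes, intervals, cfg, seed=12)
    return {"cfg": cfg, "genome": genome, "genes": genes, "intervals": intervals, "truth": truth}


@pytest.fixture(scope="session")
def small_records(small_sim):
    """DEA / WGBS / KO conversion-count tables for the small study."""
    cfg, truth = small_sim["cfg"], small_sim["truth"]
    dea = synthio.simulate_counts(truth, chemistry.dea_profile(), cfg, seed=13)
    wgbs = synthio.simulate_counts(truth, chemistry.wgbs_profile(), cfg, seed=14)
    ko = synthio.simulate_counts(synthio.ko_truth(truth), chemistry.dea_profile(), cfg, seed=15)
    return {"dea": dea, "wgbs": wgbs, "ko": ko}


def make_records(rows) -> pd.DataFrame:
    """Build a cytosine-record table from (chrom, pos, strand, n_unc, n_conv,
    context) tuples."""
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "strand", "n_unconverted", "n_converted", "context"]
    )
    df["trinucleotide"] = "CNN"
    df["depth"] = df["n_unconverted"] + df["n_converted"]
    with np.errstate(invalid="ignore"):
        df["ratio"] = np.where(df["depth"] > 0, df["n_unconverted"] / df["depth"], np.nan)
    return df
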