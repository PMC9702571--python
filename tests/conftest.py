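import numpy as np
import pandas as pd
import pytest

from ripdiv import (
    CommunityMatrix, ConservationMap, Phylogeny, SimulationConfig, SiteTable,
    TraitTable, apply_occurrence_filter, generate_study,
)


@pytest.fixture(scope="session")
def synth_dataset():
    """Default synthetic study, occurrence-filtered, shared across tests."""
    return apply_occurrence_filter(generate_study(SimulationConfig(seed=1)), 3)


@pytest.fixture()
def toy_tree():
    return Phylogeny.from_newick_string("((A:1,B:1):1,C:2);")


@pytest.fixture()
def toy_files(tmp_path):
    """Three-site, three-species input files on disk."""
    paths = {
        "community": tmp_path / "community.csv",
        "traits": tmp_path / "traits.csv",
        "tree": tmp_path / "tree.nwk",
        "sites": tmp_path / "sites.csv",
        "status": tmp_path / "status.csv",
    }
    paths["community"].write_text(
        "site_id,A,B,C\ns1,2,1,0\ns2,0,3,1\ns3,1,1,1\n")
    paths["traits"].write_text(
        "species_id,mass,diet\n_type_,continuous,categorical\n"
        "A,10.0,insect\nB,12.5,seed\nC,30.0,insect\n")
    paths["tree"].write_text("((A:1,B:1):1,C:2);\n")
    paths["sites"].write_text(
        "site_id,elevation,river_id,river_direction,"
        "Forest,Shrub,Herb,Bared,Lnum,Bar,Width,Sinuosity,H_SD\n"
        "s1,500,R1,north,50,20,15,5,4,900,18,1.2,1.5\n"
        "s2,700,R1,north,60,18,12,6,7,700,15,1.4,2.4\n"
        "s3,900,R2,south,45,22,14,4,3,500,12,1.1,1.2\n")
    paths["status"].write_text("species_id,weight\nA,1\nB,4\nC,8\n")
    return paths


def random_community(rng: np.random.Generator, n_sites: int = 20,
                     n_species: int = 15, p: float = 0.4,
                     max_abundance: int = 9) -> CommunityMatrix:
    ab = rng.integers(1, max_abundance + 1, size=(n_sites, n_species))
    ab = np.where(rng.random((n_sites, n_species)) < p, ab, 0)
    df = pd.DataFrame(ab, index=[f"s{i}" for i in range(n_sites)],
                      columns=[f"sp{j}" for j in range(n_species)])
    return CommunityMatrix(df)
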