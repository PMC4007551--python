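import pytest

from lspscan import PanelConfig, SimConfig, simulate_panel


def small_panel_config(**overrides) -> PanelConfig:
    defaults = dict(
        lineage_a=["spA1", "spA2"],
        lineage_b=["spB1", "spB2"],
        outgroups=["og1"],
        seed_a="spA1",
        seed_b="spB1",
        seed=11,
    )
    defaults.update(overrides)
    return PanelConfig(**defaults)


@pytest.fixture
def panel_config() -> PanelConfig:
    return small_panel_config()


@pytest.fixture(scope="session")
def small_sim():
    """A small mixed-class simulated panel shared across tests."""
    panel = small_panel_config()
    cfg = SimConfig(
        species_panel=panel,
        n_families=40,
        peptide_length=200,
        wgd_retention_prob=0.7,
        loss_prob_a=0.3,
        loss_prob_b=0.3,
        per_species_loss_prob=0.0,
        divergence_pre_split=0.03,
        divergence_post_split=0.02,
        seed=7,
    )
    return simulate_panel(cfg)


def truth_family_of_gene(gene_id: str) -> str:
    """Simulated gene ids are '<family>c<copy>_<species>'."""
    return gene_id.split("c")[0]


def expected_call(true_class: str) -> str:
    return true_class if true_class in ("A_LSP", "B_LSP", "shared_duplicate") else "unresolved"
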