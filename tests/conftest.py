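import pytest

import thyromap as tm


@pytest.fixture(scope="session")
def small_annotation():
    """600 loci on 4 chromosomes, deterministic."""
    return tm.generate_annotation(600, 4, seed=11)


@pytest.fixture(scope="session")
def planted_study(small_annotation):
    """Two-condition study with one 20-fold 5-gene cluster and 20 housekeeping genes."""
    cfg = tm.TruthConfig(n_spiked_clusters=1, cluster_size=5, cluster_fold=20.0,
                         n_housekeeping=20, n_sex_biased=8,
                         n_tissue_fold_genes=20, tissue_fold=10.0)
    return tm.generate_study(small_annotation, cfg,
                             n_samples_a=10, n_samples_b=10, seed=42)


@pytest.fixture(scope="session")
def planted_maps(planted_study, small_annotation):
    """Reference maps for both pools of the planted study."""
    stats_a, _ = tm.build_reference_map(
        planted_study.samples_a, planted_study.probe_map, small_annotation)
    stats_b, _ = tm.build_reference_map(
        planted_study.samples_b, planted_study.probe_map, small_annotation)
    return stats_a, stats_b
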