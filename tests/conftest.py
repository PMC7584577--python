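import numpy as np
import pytest

from introquant import (
    IndividualSpec,
    PanelSpec,
    build_index,
    generate_panel,
    simulate_reads,
)


@pytest.fixture(scope="session")
def toy_panel():
    """3 species x 10 loci of ~120 bp at 12% divergence: small enough for
    exhaustive oracles, divergent enough for unique mapping."""
    spec = PanelSpec(
        genus_name="Toyus",
        n_species=3,
        n_loci=10,
        locus_length_mean=120,
        locus_length_sd=10,
        interspecific_divergence=0.12,
        locus_length_min=100,
        seed=11,
    )
    return generate_panel(spec)


@pytest.fixture(scope="session")
def toy_index(toy_panel):
    return build_index(toy_panel, k=21)


@pytest.fixture(scope="session")
def toy_reads(toy_panel):
    """Admixed reads on the toy panel with recorded true origins."""
    spec = IndividualSpec(
        sample_id="toy1",
        genus="Toyus",
        focal_species="Toyus_sp1",
        admixture={"Toyus_sp2": 0.2},
        depth=8,
        read_length=60,
        error_rate=0.005,
        seed=13,
    )
    return simulate_reads(toy_panel, spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def alpha_grid_scores(toy_panel, toy_index):
    """Replicate-mean introgression scores over an admixture grid on the toy
    panel; shared by the monotonicity and parameter-recovery checks."""
    from introquant import accumulate_coverage, filter_hits, introgression_score, map_reads

    means = {}
    for alpha in [0.0, 0.05, 0.1, 0.2]:
        vals = []
        for rep in range(3):
            admix = {"Toyus_sp3": alpha} if alpha > 0 else {}
            spec = IndividualSpec(
                f"a{alpha}r{rep}", "Toyus", "Toyus_sp1", admix,
                depth=8, read_length=60, error_rate=0.002, seed=100 + rep,
            )
            rs = simulate_reads(toy_panel, spec)
            hits = filter_hits(map_reads(rs.seqs, toy_index), min_margin=2)
            prof = accumulate_coverage(hits, toy_panel)
            vals.append(introgression_score(prof, "Toyus_sp1").score)
        means[alpha] = float(np.mean(vals))
    return means
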