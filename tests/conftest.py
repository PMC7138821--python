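"""Shared fixtures: the study-scale synthetic panel and its EM fit are
expensive, so they are built once per session and reused."""

from __future__ import annotations

import pytest

from panstruct import admixture_em, simdata

STUDY_SEED = 11
EM_SEED = 5
EM_MAX_ITER = 600  # desk-scale cap; recovery quality is asserted, not convergence


@pytest.fixture(scope="session")
def study_model() -> simdata.PopModel:
    """Three subpopulations (two XI, one GJ) plus a within-XI admixed block:
    n=200 samples, m=5000 SNPs, FST 0.15."""
    return simdata.PopModel(
        K_true=3, n_snps=5000, fst=0.15, pure_sizes=[60, 60, 60],
        admixed_specs=[(20, [0.5, 0.5, 0.0])],
        major_group_map=["XI", "XI", "GJ"],
    )


@pytest.fixture(scope="session")
def study_panel(study_model):
    return simdata.simulate_genotypes(study_model, seed=STUDY_SEED)


@pytest.fixture(scope="session")
def study_fit(study_panel):
    G, _ = study_panel
    return admixture_em.em_fit(G, 3, seed=EM_SEED, max_iter=EM_MAX_ITER)


@pytest.fixture(scope="session")
def toy_pair():
    """200-kb toy genome pair with 20 planted events >=200 bp, >=2 kb apart."""
    spec = simdata.random_sv_spec(200_000, 20, 42, min_len=200, max_len=2000,
                                  min_gap=2000)
    return simdata.simulate_toy_genome_pair(200_000, spec, seed=43)
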