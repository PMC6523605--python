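"""Shared fixtures: a desk-scale simulated gene pool and toy matrices."""
from __future__ import annotations

import pandas as pd
import pytest

import brassipool as bp


@pytest.fixture(scope="session")
def genome_model():
    return bp.default_genome_model(n_markers=150)


@pytest.fixture(scope="session")
def founder_panel(genome_model):
    return bp.make_founders(genome_model, bp.DiversityConfig(), seed=11)


@pytest.fixture(scope="session")
def small_scheme():
    return bp.BreedingScheme(n_rounds=3, round_size=80, n_dgms=10,
                             n_inbred_per_subpop=20, n_haplotypes_per_taxon=20)


@pytest.fixture(scope="session")
def sim_result(founder_panel, small_scheme, genome_model):
    return bp.simulate_recurrent_selection(founder_panel, small_scheme,
                                           genome_model, seed=11)


@pytest.fixture(scope="session")
def marker_panel(genome_model):
    return bp.make_marker_panel(genome_model, seed=11)


@pytest.fixture(scope="session")
def rs_genotypes(sim_result, marker_panel):
    return bp.genotype_markers(sim_result.final, marker_panel,
                               missing_rate=0.0, seed=12)


@pytest.fixture(scope="session")
def reference_genotypes(sim_result, marker_panel):
    refs = bp.make_taxon_reference_panel(sim_result.final, n_per_taxon=12,
                                         seed=13)
    return bp.genotype_markers(refs, marker_panel, missing_rate=0.0, seed=14)


@pytest.fixture(scope="session")
def combined_genotypes(rs_genotypes, reference_genotypes):
    return bp.GenotypeMatrix(
        pd.concat([rs_genotypes.data, reference_genotypes.data],
                  ignore_index=True),
        pd.concat([rs_genotypes.sample_info, reference_genotypes.sample_info]),
        rs_genotypes.locus_info)


def toy_matrix(cells, locus_info=None, taxa=None):
    """Build a GenotypeMatrix from (sample, marker, locus, a1, a2) tuples."""
    data = pd.DataFrame(cells, columns=["sample", "marker", "locus",
                                        "allele1", "allele2"])
    sample_info = None
    if taxa is not None:
        sample_info = pd.DataFrame(
            {"taxon": pd.Series(taxa)},
            index=pd.Index(list(taxa), name="sample"))
        sample_info["taxon"] = [taxa[s] for s in sample_info.index]
    return bp.GenotypeMatrix(data, sample_info, locus_info)


def toy_locus_info(rows):
    """locus_info frame from (locus, genome, chrom, pos) tuples."""
    df = pd.DataFrame(rows, columns=["locus", "genome", "chrom", "pos"])
    df["source_ref"] = ["nigra_B" if g == "B" else "napus_AC"
                       for g in df["genome"]]
    return df.set_index("locus")
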