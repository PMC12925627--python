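"""Shared fixtures: small motifs, backgrounds, and planted toy genomes."""

import numpy as np
import pytest

from cenkit.annotate import AnnotateConfig, annotate_genome
from cenkit.motifs import Background, build_pwm
from cenkit.synth import (PlantSpec, default_motifs,
                          make_point_centromere_genome, motif_sites)

CDEI = "GTCACGTG"
CDEIII = "TGTATTTGATTTCCGAAAGTTAAAAA"


@pytest.fixture(scope="session")
def uniform_bg():
    return Background.uniform()


@pytest.fixture(scope="session")
def cdei_pwm():
    return build_pwm(motif_sites(CDEI, n_sites=20, noise=0.05, seed=3),
                     pseudocount=0.1, name="CDEI")


@pytest.fixture(scope="session")
def cdeiii_pwm():
    return build_pwm(motif_sites(CDEIII, n_sites=20, noise=0.05, seed=4),
                     pseudocount=0.1, name="CDEIII")


@pytest.fixture(scope="session")
def toy_spec():
    """Small planted genome: 8 chromosomes x 80 kb, default decoy mix scaled
    down, single 85-bp CDEII class."""
    return PlantSpec(n_chromosomes=8, chrom_length=80_000, seed=5,
                     n_decoy_low_at=12, n_decoy_cdeiii_only=6, margin=2_000)


@pytest.fixture(scope="session")
def toy_genome(toy_spec):
    return make_point_centromere_genome(toy_spec)


@pytest.fixture(scope="session")
def toy_result(toy_spec, toy_genome):
    records, _ = toy_genome
    cdei, cdeiii = default_motifs(toy_spec)
    cfg = AnnotateConfig(cdei=cdei, cdeiii=cdeiii, species="toy",
                         assembly="TOY001")
    return annotate_genome(records, cfg, keep_removed=True)
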