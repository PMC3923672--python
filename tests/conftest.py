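"""Shared fixtures: simulated experiments at the default study conditions."""

from dataclasses import dataclass

import pytest

import embryocomp as ec


@dataclass
class SimBundle:
    cfg: ec.SimulationConfig
    expr: ec.ExpressionTable
    allele: ec.AlleleCountTable
    sheet: ec.SampleSheet
    ann: ec.GeneAnnotation
    truth: ec.SimulationTruth
    norm: ec.ExpressionTable = None
    fractions: object = None


def make_bundle(cfg: ec.SimulationConfig) -> SimBundle:
    expr, allele, sheet, ann, truth = ec.simulate_experiment(cfg)
    bundle = SimBundle(cfg, expr, allele, sheet, ann, truth)
    bundle.norm = ec.normalize_autosomal(expr, ann)
    bundle.fractions = ec.allele_fractions(allele)
    return bundle


@pytest.fixture(scope="session")
def pse_sim() -> SimBundle:
    return make_bundle(ec.default_config("pse_like", seed=7))


@pytest.fixture(scope="session")
def mir_sim() -> SimBundle:
    return make_bundle(ec.default_config("mir_like", seed=11))


@pytest.fixture(scope="session")
def mel_sim() -> SimBundle:
    return make_bundle(ec.default_config("mel_like", seed=5))
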